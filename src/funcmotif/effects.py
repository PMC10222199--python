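"""Post-fit statistics: group effects, route comparison, abundance check.

``group_anova_effects`` quantifies the linear part of each functional group's
contribution: per-sample binary presence factors enter a sequential (Type-I)
ANOVA in group order with all pairwise interactions after the main effects,
and each group's effect is expressed as a percentage of the median property
(e.g. "group A is associated with a priming effect 39% higher than the
median").  ``compare_key_families`` crosses the key-family sets retained by
the linear and clustering routes, and ``median_abundance_check`` asks — via a
Kruskal-Wallis test — whether being key is related to a family's total
abundance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import NamedTuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .containers import AbundanceTable, PropertyVector
from .clustering import FunctionalPartition, _check_aligned
from .discretize import ClassEncoding
from .exceptions import ParameterError, ValidationError
from .model import SelectionTrace

__all__ = [
    "GroupEffects",
    "group_anova_effects",
    "compare_key_families",
    "median_abundance_check",
    "KruskalResult",
]

#: the study-wide significance threshold
SIGNIFICANCE_THRESHOLD = 1e-3


@dataclass
class GroupEffects:
    """Percent effects of functional-group presence on the property.

    ``main_effects[g] = (effect_pct, p_value)`` where ``effect_pct`` is 100 x
    (mean property when g is present - median property) / |median|;
    interaction effects use the double difference of the four presence cells.
    When the median is zero, effects are reported in raw property units and
    ``percent_scale`` is False.
    """

    median_property: float
    main_effects: dict[str, tuple[float, float]]
    interaction_effects: dict[tuple[str, str], tuple[float, float]]
    dropped: list[str] = field(default_factory=list)
    percent_scale: bool = True
    anova_table: pd.DataFrame | None = None

    def significant_main(self, alpha: float = SIGNIFICANCE_THRESHOLD) -> list[str]:
        return [g for g, (_, p) in self.main_effects.items() if p < alpha]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"term": g, "effect": e, "p_value": p,
             "significant": p < SIGNIFICANCE_THRESHOLD}
            for g, (e, p) in self.main_effects.items()
        ]
        rows += [
            {"term": f"{a}:{b}", "effect": e, "p_value": p,
             "significant": p < SIGNIFICANCE_THRESHOLD}
            for (a, b), (e, p) in self.interaction_effects.items()
        ]
        return pd.DataFrame(rows)


def group_anova_effects(
    encoding: ClassEncoding, y, partition: FunctionalPartition
) -> GroupEffects:
    """Sequential ANOVA of the property on group-presence factors.

    Non-residual groups enter in partition order as binary presence factors,
    followed by all pairwise interactions; sums of squares are sequential
    (Type I), so the entry order is the explanatory order of the groups.
    Groups present in no or all samples carry no contrast and are dropped
    with a warning.
    """
    yv = _check_aligned(encoding, y)
    assign = partition.group_indices(encoding.class_names)
    groups = [g for g in partition.group_order if g != partition.residual]
    if not groups:
        raise ParameterError("partition has no non-residual groups")

    presence: dict[str, np.ndarray] = {}
    dropped: list[str] = []
    for g in groups:
        k = partition.group_order.index(g)
        pres = (encoding.indicators[:, assign == k] > 0).any(axis=1)
        if pres.all() or not pres.any():
            dropped.append(g)
            warnings.warn(
                f"group {g} present in {'all' if pres.all() else 'no'} samples; "
                "factor dropped",
                stacklevel=2,
            )
        else:
            presence[g] = pres
    kept = [g for g in groups if g in presence]

    median = float(np.median(yv))
    percent_scale = median != 0.0
    if not percent_scale:
        warnings.warn(
            "median property is zero; effects reported in raw units", stacklevel=2
        )
    scale = 100.0 / abs(median) if percent_scale else 1.0

    def main_effect(g: str) -> float:
        return float(scale * (yv[presence[g]].mean() - median))

    def interaction_effect(a: str, b: str) -> float:
        pa, pb = presence[a], presence[b]
        cells = [pa & pb, pa & ~pb, ~pa & pb, ~pa & ~pb]
        if any(not c.any() for c in cells):
            return float("nan")
        both, only_a, only_b, neither = (yv[c].mean() for c in cells)
        return float(scale * (both - only_a - only_b + neither))

    main_p: dict[str, float] = {}
    inter_p: dict[tuple[str, str], float] = {}
    anova = None
    if kept:
        data = pd.DataFrame({f"g_{g}": presence[g].astype(int) for g in kept})
        data["y"] = yv
        terms = [f"g_{g}" for g in kept] + [
            f"g_{a}:g_{b}" for a, b in combinations(kept, 2)
        ]
        formula = "y ~ " + " + ".join(terms)
        fit = smf.ols(formula, data=data).fit()
        anova = sm.stats.anova_lm(fit, typ=1)
        for g in kept:
            main_p[g] = float(anova.loc[f"g_{g}", "PR(>F)"])
        for a, b in combinations(kept, 2):
            term = f"g_{a}:g_{b}"
            if term in anova.index and np.isfinite(anova.loc[term, "PR(>F)"]):
                inter_p[(a, b)] = float(anova.loc[term, "PR(>F)"])

    main_effects = {g: (main_effect(g), main_p[g]) for g in kept}
    interaction_effects = {
        (a, b): (interaction_effect(a, b), inter_p[(a, b)])
        for a, b in combinations(kept, 2)
        if (a, b) in inter_p
    }
    return GroupEffects(
        median_property=median,
        main_effects=main_effects,
        interaction_effects=interaction_effects,
        dropped=dropped,
        percent_scale=percent_scale,
        anova_table=anova,
    )


def compare_key_families(
    lm_trace: SelectionTrace,
    fclust_trace: SelectionTrace,
    effects: GroupEffects | None = None,
) -> pd.DataFrame:
    """Cross the key-family sets identified by the two routes.

    Each family of the shared universe is categorized as key to ``both``
    routes, ``linear_only``, ``clustering_only`` or ``neither``; linear-route
    keys carry the sign of their coefficient (and significance of its t-test
    at p < 0.001), clustering-route keys the letter of the most explanatory
    group holding one of their classes (significance from the group's ANOVA
    main effect when ``effects`` is given).  Category percentages over the
    universe are attached as ``result.attrs["category_percentages"]``.
    """
    lm_universe = set(lm_trace.initial_ids) | set(lm_trace.predropped)
    fc_universe = set(fclust_trace.initial_ids)
    if lm_universe != fc_universe:
        diff = sorted(lm_universe ^ fc_universe)
        raise ValidationError(f"family universes differ: {diff}")

    lm_kept = set(lm_trace.final.kept)
    fc_kept = set(fclust_trace.final.kept)
    partition: FunctionalPartition = fclust_trace.final.extras["partition"]
    enc: ClassEncoding = fclust_trace.final.extras["encoding"]
    order = {lab: i for i, lab in enumerate(partition.group_order)}

    rows = []
    for fam in fclust_trace.initial_ids:
        in_lm = fam in lm_kept
        in_fc = fam in fc_kept
        category = (
            "both" if in_lm and in_fc
            else "linear_only" if in_lm
            else "clustering_only" if in_fc
            else "neither"
        )
        sign = ""
        lm_sig = False
        if in_lm and lm_trace.final.coefficients is not None:
            coef = lm_trace.final.coefficients.get(fam, np.nan)
            sign = "+" if coef > 0 else "-" if coef < 0 else ""
            if lm_trace.final.coef_pvalues is not None:
                lm_sig = bool(
                    lm_trace.final.coef_pvalues.get(fam, 1.0) < SIGNIFICANCE_THRESHOLD
                )
        letter = ""
        fc_sig = False
        if in_fc:
            labs = {
                partition.assignment[enc.classes[i].name]
                for i in enc.columns_of_family(fam)
            }
            letter = min(labs, key=lambda l: order[l])
            if effects is not None and letter in effects.main_effects:
                fc_sig = bool(
                    effects.main_effects[letter][1] < SIGNIFICANCE_THRESHOLD
                )
        rows.append(
            {
                "family": fam,
                "category": category,
                "lm_sign": sign,
                "lm_significant": lm_sig,
                "fclust_group": letter,
                "fclust_significant": fc_sig,
            }
        )
    result = pd.DataFrame(rows).set_index("family")
    total = len(result)
    result.attrs["category_percentages"] = {
        cat: float(100.0 * (result["category"] == cat).sum() / total)
        for cat in ("both", "linear_only", "clustering_only", "neither")
    }
    return result


class KruskalResult(NamedTuple):
    statistic: float
    p_value: float


def median_abundance_check(
    table: AbundanceTable, key_families: set[str], nonkey_families: set[str]
) -> KruskalResult:
    """Kruskal-Wallis comparison of total abundance between key and non-key families.

    Tests whether families identified as key differ in median total read
    count from the remaining families (tie-corrected H, chi-square p-value
    with k - 1 df).  Identical groups return H = 0, p = 1.
    """
    if not key_families or not nonkey_families:
        raise ParameterError("both family sets must be nonempty")
    unknown = (set(key_families) | set(nonkey_families)) - set(table.family_ids)
    if unknown:
        raise ParameterError(f"families not in table: {sorted(unknown)}")
    totals = table.family_totals()
    key_tot = totals[sorted(key_families)].to_numpy(dtype=float)
    non_tot = totals[sorted(nonkey_families)].to_numpy(dtype=float)
    pooled = np.concatenate([key_tot, non_tot])
    if np.all(pooled == pooled[0]):  # no rank information at all
        return KruskalResult(0.0, 1.0)
    res = stats.kruskal(key_tot, non_tot)
    return KruskalResult(float(res.statistic), float(res.pvalue))
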