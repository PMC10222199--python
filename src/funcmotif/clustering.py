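"""The non-linear route: functional clustering of abundance classes.

Relative-abundance classes are partitioned into functional groups; a group is
"present" in a sample when at least one of its classes is present, and the set
of present groups is the sample's assembly motif.  The model predicts every
sample by the mean property of its motif, so the explained variance is the
inter-motif variance fraction.  The partition is searched greedily, level by
level (one group, two groups, ...): each new level seeds a new group with the
single class whose relocation most increases R^2, then applies
first-improvement single-class moves until no move strictly increases R^2.
An exhaustive set-partition oracle is provided for auditing the greedy search
on small instances.

Groups are ordered by their explanatory contribution (R^2 drop when merged
into the residual group), with the residual group — the default cluster of
least-significant classes — labeled last.  Family-level backward selection
removes families whose classes all sit in the residual group, provided the
removal changes neither the functional groups nor any sample's assembly
motif, under an AICc whose variable count is the number of remaining
families.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import PropertyVector
from .discretize import ClassEncoding
from .exceptions import (
    DegeneratePropertyError,
    ParameterError,
    ValidationError,
)
from .model import ModelFit, SelectionStep, SelectionTrace, aicc_or_inf

__all__ = [
    "FunctionalPartition",
    "ClusterLevel",
    "ClusterTree",
    "OracleResult",
    "motif_of_sample",
    "fit_motif_means",
    "fit_tree",
    "exhaustive_oracle",
    "order_groups",
    "backward_select_families",
]

#: strictness margin for "strictly increases R^2" in the greedy search
_R2_TOL = 1e-12


@dataclass
class FunctionalPartition:
    """Assignment of abundance classes to ordered functional groups.

    ``group_order`` lists the labels from most to least explanatory once the
    partition has been ordered; ``residual``, when set, must be the last
    label.  ``member_order`` optionally records the explanatory ordering of
    classes inside each group.
    """

    assignment: dict[str, str]
    group_order: list[str]
    residual: str | None = None
    member_order: dict[str, list[str]] | None = None

    def __post_init__(self) -> None:
        labels = set(self.group_order)
        if len(labels) != len(self.group_order):
            raise ValidationError("duplicate group labels")
        for cls, lab in self.assignment.items():
            if lab not in labels:
                raise ValidationError(f"class {cls!r} assigned to unknown group {lab!r}")
        if self.residual is not None and (
            not self.group_order or self.group_order[-1] != self.residual
        ):
            raise ValidationError("residual group must be last in group_order")

    @property
    def n_groups(self) -> int:
        return len(self.group_order)

    @property
    def class_names(self) -> list[str]:
        return list(self.assignment)

    def members(self, label: str) -> list[str]:
        if self.member_order is not None and label in self.member_order:
            return list(self.member_order[label])
        return [c for c, lab in self.assignment.items() if lab == label]

    def group_indices(self, class_names: list[str]) -> np.ndarray:
        """Assignment as integer indices into ``group_order`` for given classes."""
        pos = {lab: i for i, lab in enumerate(self.group_order)}
        try:
            return np.array([pos[self.assignment[c]] for c in class_names], dtype=np.int64)
        except KeyError as err:
            raise ValidationError(f"class not covered by partition: {err}") from err

    def drop_classes(self, names: set[str]) -> "FunctionalPartition":
        assignment = {c: g for c, g in self.assignment.items() if c not in names}
        member_order = None
        if self.member_order is not None:
            member_order = {
                g: [c for c in cs if c not in names]
                for g, cs in self.member_order.items()
            }
        return FunctionalPartition(
            assignment=assignment,
            group_order=list(self.group_order),
            residual=self.residual,
            member_order=member_order,
        )


@dataclass
class ClusterLevel:
    partition: FunctionalPartition
    r2: float
    n_motifs: int
    aicc: float


@dataclass
class ClusterTree:
    """Greedy hierarchy of partitions, one level per group count."""

    levels: list[ClusterLevel]
    selected_index: int

    @property
    def selected(self) -> ClusterLevel:
        return self.levels[self.selected_index]


@dataclass
class OracleResult:
    partition: FunctionalPartition
    r2: float
    n_examined: int


# ---------------------------------------------------------------------------
# internal engine on integer arrays


def _check_aligned(encoding: ClassEncoding, y: np.ndarray) -> np.ndarray:
    if isinstance(y, PropertyVector):
        if y.sample_ids != encoding.sample_ids:
            y = y.align_to(encoding.sample_ids)
        y = y.values
    y = np.asarray(y, dtype=float).ravel()
    if len(y) != encoding.n_samples:
        raise ValidationError("property length does not match encoding samples")
    return y


def _codes_of(Z: np.ndarray, assign: np.ndarray, g: int) -> np.ndarray:
    pres = np.zeros((Z.shape[0], g), dtype=bool)
    for k in range(g):
        cols = assign == k
        if cols.any():
            pres[:, k] = Z[:, cols].any(axis=1)
    return pres @ (1 << np.arange(g, dtype=np.int64))


def _r2_of_codes(codes: np.ndarray, y: np.ndarray, tss: float, y2: float) -> float:
    _, inv = np.unique(codes, return_inverse=True)
    sums = np.bincount(inv, weights=y)
    cnt = np.bincount(inv)
    rss = y2 - float((sums * sums / cnt).sum())
    if rss < 0:  # numerical round-off
        rss = 0.0
    return 1.0 - rss / tss


class _Engine:
    """Fast inter-motif R^2 evaluation with incremental group-presence counts."""

    def __init__(self, Z: np.ndarray, y: np.ndarray):
        self.Z = Z.astype(np.int32)
        self.y = y
        ybar = y.mean()
        self.tss = float(((y - ybar) ** 2).sum())
        self.y2 = float(y @ y)
        if self.tss == 0.0:
            raise DegeneratePropertyError("property is constant; R^2 undefined")

    def r2(self, assign: np.ndarray, g: int) -> float:
        codes = _codes_of(self.Z > 0, assign, g)
        return _r2_of_codes(codes, self.y, self.tss, self.y2)

    def r2_from_counts(self, C: np.ndarray) -> float:
        codes = (C > 0) @ (1 << np.arange(C.shape[1], dtype=np.int64))
        return _r2_of_codes(codes, self.y, self.tss, self.y2)


def _provisional_partition(
    class_names: list[str], assign: np.ndarray, g: int
) -> FunctionalPartition:
    labels = list(string.ascii_uppercase[:g])
    return FunctionalPartition(
        assignment={c: labels[a] for c, a in zip(class_names, assign)},
        group_order=labels,
    )


def _motif_stats(codes: np.ndarray, y: np.ndarray):
    """Per-motif means: fitted values, exact RSS, motif count."""
    _, inv = np.unique(codes, return_inverse=True)
    sums = np.bincount(inv, weights=y)
    cnt = np.bincount(inv)
    fitted = (sums / cnt)[inv]
    resid = y - fitted
    return fitted, float(resid @ resid), len(cnt)


# ---------------------------------------------------------------------------
# public operations


def motif_of_sample(
    indicators: np.ndarray,
    partition: FunctionalPartition,
    class_names: list[str] | None = None,
) -> frozenset[str]:
    """Assembly motif of one sample: groups with at least one present class."""
    if class_names is None:
        class_names = partition.class_names
    row = np.asarray(indicators).ravel()
    if len(row) != len(class_names):
        raise ValidationError("indicator row length does not match class set")
    present = {
        partition.assignment[c] for c, v in zip(class_names, row) if v
    }
    return frozenset(present)


def fit_motif_means(encoding: ClassEncoding, y, partition: FunctionalPartition) -> ModelFit:
    """Fit the motif-mean model: each sample predicted by its motif's mean.

    R^2 is the inter-motif variance fraction; the F-ratio is the one-way
    ANOVA F across observed motifs.  The AICc is computed with k = number of
    observed motifs (the level-selection convention).
    """
    yv = _check_aligned(encoding, y)
    tss = float(((yv - yv.mean()) ** 2).sum())
    if tss == 0.0:
        raise DegeneratePropertyError("property is constant; R^2 undefined")
    assign = partition.group_indices(encoding.class_names)
    g = partition.n_groups
    codes = _codes_of(encoding.indicators > 0, assign, g)
    fitted, rss, n_motifs = _motif_stats(codes, yv)
    n = len(yv)
    if n_motifs == 1:
        warnings.warn("single observed motif: model explains no variance", stacklevel=2)
        f_ratio = 0.0
    elif rss == 0.0:
        f_ratio = float("inf")
    elif n - n_motifs <= 0:
        f_ratio = float("inf")
    else:
        f_ratio = ((tss - rss) / (n_motifs - 1)) / (rss / (n - n_motifs))
    labels = np.array(partition.group_order)
    motifs = [
        frozenset(labels[np.flatnonzero((code >> np.arange(g)) & 1)])
        for code in codes
    ]
    return ModelFit(
        route="clustering",
        kept=encoding.family_ids,
        fitted=fitted,
        r2=1.0 - rss / tss if rss > 0 else 1.0,
        f_ratio=f_ratio,
        aicc=aicc_or_inf(rss, n, n_motifs),
        k=n_motifs,
        df_resid=n - n_motifs,
        extras={
            "rss": rss,
            "tss": tss,
            "n_motifs": n_motifs,
            "motifs": motifs,
            "partition": partition,
        },
    )


def _refine(
    Z: np.ndarray,
    assign: np.ndarray,
    g: int,
    engine: "_Engine",
    use_swaps: bool,
) -> float:
    """First-improvement local search on ``assign`` (modified in place).

    Scans single-class relocations (any class to any group, input order;
    moves that would empty their source group are skipped) and, optionally,
    pairwise swaps of classes between groups, until no move strictly
    increases R^2.  Returns the final R^2.
    """
    n, m = Z.shape
    C = np.zeros((n, g), dtype=np.int32)
    for k in range(g):
        C[:, k] = Z[:, assign == k].sum(axis=1)
    sizes = np.bincount(assign, minlength=g)
    current = engine.r2_from_counts(C)
    improved = True
    while improved:
        improved = False
        for x in range(m):
            src = assign[x]
            if sizes[src] <= 1:
                continue
            zx = Z[:, x]
            for k in range(g):
                if k == src:
                    continue
                C[:, src] -= zx
                C[:, k] += zx
                r2 = engine.r2_from_counts(C)
                if r2 > current + _R2_TOL:
                    assign[x] = k
                    sizes[src] -= 1
                    sizes[k] += 1
                    current = r2
                    src = k
                    improved = True
                    if sizes[src] <= 1:
                        break
                else:
                    C[:, src] += zx
                    C[:, k] -= zx
        if not use_swaps:
            continue
        for x in range(m):
            for w in range(x + 1, m):
                a, b = assign[x], assign[w]
                if a == b:
                    continue
                delta = Z[:, w] - Z[:, x]
                C[:, a] += delta
                C[:, b] -= delta
                r2 = engine.r2_from_counts(C)
                if r2 > current + _R2_TOL:
                    assign[x], assign[w] = b, a
                    current = r2
                    improved = True
                else:
                    C[:, a] -= delta
                    C[:, b] += delta
    return current


def fit_tree(
    encoding: ClassEncoding,
    y,
    max_groups: int,
    n_seed_restarts: int = 5,
    n_random_restarts: int = 10,
    use_swaps: bool = True,
) -> ClusterTree:
    """Greedy divisive hierarchy of functional-group partitions.

    Level 1 puts all classes in one group.  Level g+1 is built from level g
    by seeding a new group with a single relocated class and refining by
    first-improvement moves (any class to any group, input order, repeated
    until no move strictly increases R^2), keeping the best refined result
    over the ``n_seed_restarts`` best-scoring seed classes plus
    ``n_random_restarts`` deterministic random initial partitions; the
    refinement also scans pairwise class swaps when ``use_swaps`` is set.
    The search is deterministic under fixed class order.  The selected level
    minimizes the AICc computed with k = number of observed motifs.
    """
    yv = _check_aligned(encoding, y)
    m = encoding.n_classes
    if m < 2:
        raise ParameterError("need at least 2 classes to cluster")
    if max_groups < 2:
        raise ParameterError("max_groups must be >= 2")
    if max_groups > m:
        raise ParameterError(f"max_groups={max_groups} exceeds {m} classes")

    Z = encoding.indicators.astype(np.int32)
    names = encoding.class_names
    engine = _Engine(Z, yv)
    n = len(yv)

    def record(assign: np.ndarray, g: int) -> ClusterLevel:
        codes = _codes_of(Z > 0, assign, g)
        _, rss, n_motifs = _motif_stats(codes, yv)
        r2 = 1.0 - rss / engine.tss if rss > 0 else 1.0
        return ClusterLevel(
            partition=_provisional_partition(names, assign.copy(), g),
            r2=r2,
            n_motifs=n_motifs,
            aicc=aicc_or_inf(rss, n, n_motifs),
        )

    assign = np.zeros(m, dtype=np.int64)
    g = 1
    levels = [record(assign, g)]
    restart_rng = np.random.default_rng(0)  # fixed stream: search is deterministic

    while g < max_groups:
        sizes = np.bincount(assign, minlength=g)
        seeds: list[tuple[float, int]] = []
        for x in range(m):
            if sizes[assign[x]] <= 1:
                continue
            old = assign[x]
            assign[x] = g
            seeds.append((engine.r2(assign, g + 1), x))
            assign[x] = old
        if not seeds:
            break
        seeds.sort(key=lambda t: (-t[0], t[1]))
        starts: list[np.ndarray] = []
        for _, x in seeds[: max(1, n_seed_restarts)]:
            a = assign.copy()
            a[x] = g
            starts.append(a)
        for _ in range(n_random_restarts):
            a = restart_rng.integers(0, g + 1, size=m)
            keep = restart_rng.permutation(m)[: g + 1]
            a[keep] = np.arange(g + 1)  # guarantee every group nonempty
            starts.append(a.astype(np.int64))
        best_r2, best_assign = -np.inf, None
        for a in starts:
            r2 = _refine(Z, a, g + 1, engine, use_swaps)
            if r2 > best_r2 + _R2_TOL:
                best_r2, best_assign = r2, a
        assign = best_assign
        g += 1
        levels.append(record(assign, g))

    selected = int(np.argmin([lv.aicc for lv in levels]))
    return ClusterTree(levels=levels, selected_index=selected)


def _stirling2(m: int, g: int) -> int:
    """Stirling number of the second kind S(m, g)."""
    if g == 0:
        return 1 if m == 0 else 0
    row = [1] + [0] * g
    for i in range(1, m + 1):
        new = [0] * (g + 1)
        for j in range(1, min(i, g) + 1):
            new[j] = j * row[j] + row[j - 1]
        if i == 0:
            new[0] = 1
        row = new
    return row[g]


def exhaustive_oracle(encoding: ClassEncoding, y, n_groups: int) -> OracleResult:
    """Brute-force best partition into exactly ``n_groups`` nonempty groups.

    Enumerates set partitions via restricted growth strings (one
    representative per group-label permutation) and returns the partition
    with maximal inter-motif R^2 (ties: first in enumeration order).  Refuses
    when S(m, n_groups) exceeds 10^6.
    """
    yv = _check_aligned(encoding, y)
    m = encoding.n_classes
    if not 1 <= n_groups <= m:
        raise ParameterError(f"n_groups must be in 1..{m}")
    count = _stirling2(m, n_groups)
    if count > 1_000_000:
        raise ParameterError(
            f"S({m},{n_groups}) = {count} set partitions exceeds the 10^6 guard"
        )
    Z = encoding.indicators.astype(np.int32)
    engine = _Engine(Z, yv)

    best_r2 = -np.inf
    best_assign: np.ndarray | None = None
    n_examined = 0
    assign = np.zeros(m, dtype=np.int64)

    def recurse(i: int, used: int) -> None:
        nonlocal best_r2, best_assign, n_examined
        if i == m:
            if used == n_groups:
                nonlocal_r2 = engine.r2(assign, n_groups)
                n_examined += 1
                if nonlocal_r2 > best_r2:
                    best_r2 = nonlocal_r2
                    best_assign = assign.copy()
            return
        if used + (m - i) < n_groups:  # cannot reach n_groups anymore
            return
        top = min(used + 1, n_groups)
        for lab in range(top):
            assign[i] = lab
            recurse(i + 1, max(used, lab + 1))
        assign[i] = 0

    recurse(0, 0)
    assert best_assign is not None
    return OracleResult(
        partition=_provisional_partition(encoding.class_names, best_assign, n_groups),
        r2=float(best_r2),
        n_examined=n_examined,
    )


def order_groups(
    partition: FunctionalPartition, encoding: ClassEncoding, y
) -> FunctionalPartition:
    """Order groups by explanatory contribution and identify the residual.

    The residual group is the one whose dissolution (merging its classes into
    the best-absorbing other group) costs the least R^2.  Remaining groups are
    sorted by decreasing R^2 drop when merged into the residual; classes
    within each non-residual group are sorted by the R^2 drop when the single
    class is moved to the residual.  Groups are relabeled A, B, ... with the
    residual last.
    """
    yv = _check_aligned(encoding, y)
    names = encoding.class_names
    assign = partition.group_indices(names)
    g = partition.n_groups
    Z = encoding.indicators.astype(np.int32)
    engine = _Engine(Z, yv)
    base_r2 = engine.r2(assign, g)

    if g == 1:
        lab = partition.group_order[0]
        return FunctionalPartition(
            assignment=dict(partition.assignment),
            group_order=[lab],
            residual=lab,
            member_order={lab: [c for c in names if c in partition.assignment]},
        )

    def merged_r2(src: int, dst: int) -> float:
        merged = assign.copy()
        merged[merged == src] = dst
        return engine.r2(merged, g)

    # residual = cheapest group to dissolve; dissolving G into H and H into G
    # give the same partition, so such drops tie — break ties by the variance
    # explained by the group's own presence/absence split, lowest first
    drops = []
    solo = []
    for k in range(g):
        best = max(merged_r2(k, h) for h in range(g) if h != k)
        drops.append(base_r2 - best)
        pres = (Z[:, assign == k] > 0).any(axis=1).astype(np.int64)
        solo.append(_r2_of_codes(pres, yv, engine.tss, engine.y2))
    residual_idx = min(range(g), key=lambda k: (drops[k], solo[k], k))

    # contribution of each other group = R^2 drop when merged into residual
    contrib = {
        k: base_r2 - merged_r2(k, residual_idx)
        for k in range(g)
        if k != residual_idx
    }
    ordered = sorted(contrib, key=lambda k: (-contrib[k], k)) + [residual_idx]

    labels = list(string.ascii_uppercase[:g])
    relabel = {old: labels[i] for i, old in enumerate(ordered)}
    assignment = {c: relabel[int(a)] for c, a in zip(names, assign)}

    # class order inside groups: drop in R^2 when the class moves to residual
    member_order: dict[str, list[str]] = {}
    for i, old in enumerate(ordered):
        members = [j for j in range(len(names)) if assign[j] == old]
        if old == residual_idx:
            member_order[labels[i]] = [names[j] for j in members]
            continue
        scores = {}
        for j in members:
            moved = assign.copy()
            moved[j] = residual_idx
            scores[j] = base_r2 - engine.r2(moved, g)
        members.sort(key=lambda j: (-scores[j], j))
        member_order[labels[i]] = [names[j] for j in members]

    return FunctionalPartition(
        assignment=assignment,
        group_order=labels,
        residual=labels[-1],
        member_order=member_order,
    )


def backward_select_families(encoding: ClassEncoding, y, tree) -> SelectionTrace:
    """Constrained family-level backward selection on the clustering route.

    Only families whose every abundance class sits in the residual group are
    candidates; a candidate is removed when dropping all its classes leaves
    every sample's assembly motif unchanged (which also leaves the
    non-residual groups' content unchanged) and the AICc — computed with
    k = number of remaining families — improves.  ``tree`` may be a
    :class:`ClusterTree` (its AICc-selected level is used, ordered first) or
    an ordered :class:`FunctionalPartition`.
    """
    yv = _check_aligned(encoding, y)
    if isinstance(tree, ClusterTree):
        partition = tree.selected.partition
    else:
        partition = tree
    if partition.residual is None:
        partition = order_groups(partition, encoding, yv)

    n = encoding.n_samples
    p_initial = len(encoding.family_ids)
    enc = encoding
    part = partition

    def motif_codes(e: ClassEncoding, p: FunctionalPartition) -> np.ndarray:
        assign = p.group_indices(e.class_names)
        return _codes_of(e.indicators > 0, assign, p.n_groups)

    codes = motif_codes(enc, part)
    _, rss, _ = _motif_stats(codes, yv)
    families = list(enc.family_ids)
    current_aicc = aicc_or_inf(rss, n, len(families))

    steps: list[SelectionStep] = []
    while True:
        residual_members = set(part.members(part.residual))
        candidates = [
            f
            for f in families
            if all(
                enc.classes[i].name in residual_members
                for i in enc.columns_of_family(f)
            )
        ]
        best = None  # (aicc_after, family, enc, part, codes)
        for fam in candidates:
            cls_names = {enc.classes[i].name for i in enc.columns_of_family(fam)}
            enc_try = enc.drop_families({fam})
            part_try = part.drop_classes(cls_names)
            codes_try = motif_codes(enc_try, part_try)
            if not np.array_equal(codes_try, codes):
                continue  # removal would change assembly motifs
            _, rss_try, _ = _motif_stats(codes_try, yv)
            a = aicc_or_inf(rss_try, n, len(families) - 1)
            if best is None or a < best[0]:
                best = (a, fam, enc_try, part_try, codes_try)
        if best is None:
            break
        # rss is unchanged by construction, so fewer families is strictly
        # better; when both AICc values sit in the undefined-correction
        # regime (k too close to n) the comparison is decided by k alone
        both_undefined = np.isinf(best[0]) and np.isinf(current_aicc)
        if not (best[0] < current_aicc or both_undefined):
            break
        a, fam, enc, part, codes = best
        families.remove(fam)
        steps.append(
            SelectionStep(
                removed=fam,
                aicc_before=current_aicc,
                aicc_after=a,
                n_kept=len(families),
            )
        )
        current_aicc = a

    final = fit_motif_means(enc, yv, part)
    final.k = len(families)
    final.aicc = aicc_or_inf(final.extras["rss"], n, len(families))
    final.reported_df = p_initial - len(families)
    final.extras["encoding"] = enc
    final.extras["partition"] = part
    return SelectionTrace(
        steps=steps, final=final, initial_ids=list(encoding.family_ids)
    )
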