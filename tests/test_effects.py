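"""Group-effect ANOVA, route comparison and the median-abundance check."""

import numpy as np
import pytest

import funcmotif as fm
from funcmotif.exceptions import ParameterError, ValidationError
from conftest import make_encoding


def one_group_partition(m, labels):
    return fm.FunctionalPartition(
        assignment={f"c{j}|1/1": labels[j] for j in range(m)},
        group_order=sorted(set(labels), key=labels.index)
        if labels.index is not None
        else labels,
        residual=None,
    )


class TestGroupAnovaEffects:
    def _setup(self, pres, y, extra_labels=None):
        """One group A carried by class c0; c1 is residual filler."""
        n = len(y)
        Z = np.zeros((n, 2), dtype=np.int8)
        Z[:, 0] = pres
        Z[:, 1] = 1  # residual class everywhere
        enc = make_encoding(Z)
        part = fm.FunctionalPartition(
            assignment={"c0|1/1": "A", "c1|1/1": "R"},
            group_order=["A", "R"],
            residual="R",
        )
        return enc, part

    def test_percent_effect_against_median(self):
        """Samples with the group average 13.9 against a median of 10 -> +39%."""
        y = np.array([13.8, 14.0, 13.9, 13.9, 4.0, 6.0, 8.0, 10.0, 10.0, 10.0])
        pres = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        assert np.median(y) == 10.0
        enc, part = self._setup(pres, y)
        eff = fm.group_anova_effects(enc, y, part)
        e, p = eff.main_effects["A"]
        assert e == pytest.approx(39.0)

    def test_group_present_everywhere_is_dropped(self):
        y = np.arange(10.0)
        enc, part = self._setup(np.ones(10, dtype=int), y)
        with pytest.warns(UserWarning, match="factor dropped"):
            eff = fm.group_anova_effects(enc, y, part)
        assert eff.dropped == ["A"]
        assert eff.main_effects == {}

    def test_effect_zero_when_group_mean_equals_median(self):
        y = np.array([4.0, 6.0, 5.0, 1.0, 9.0, 2.0, 8.0, 5.0])
        pres = np.array([1, 1, 0, 0, 0, 0, 0, 1])  # mean 5 = median
        enc, part = self._setup(pres, y)
        eff = fm.group_anova_effects(enc, y, part)
        assert eff.main_effects["A"][0] == pytest.approx(0.0, abs=1e-12)

    def test_interaction_double_difference(self):
        """Balanced 2x2 design with known cell means gives the exact contrast."""
        rng = np.random.default_rng(0)
        n = 400
        Z = np.zeros((n, 3), dtype=np.int8)
        Z[: n // 2, 0] = 1
        Z[:, 1] = np.tile([1, 0], n // 2)
        Z[:, 2] = 1
        enc = make_encoding(Z)
        part = fm.FunctionalPartition(
            assignment={"c0|1/1": "A", "c1|1/1": "B", "c2|1/1": "R"},
            group_order=["A", "B", "R"],
            residual="R",
        )
        pa, pb = Z[:, 0].astype(bool), Z[:, 1].astype(bool)
        cell_means = {  # interaction contrast = 12 - 6 - 4 + 2 = 4
            (True, True): 12.0, (True, False): 6.0,
            (False, True): 4.0, (False, False): 2.0,
        }
        y = np.array([cell_means[(a, b)] for a, b in zip(pa, pb)])
        eff = fm.group_anova_effects(enc, y, part)
        median = eff.median_property
        expected = 100.0 * 4.0 / abs(median)
        e, p = eff.interaction_effects[("A", "B")]
        assert e == pytest.approx(expected)
        assert p < 1e-6  # exact interaction, tiny residual noise absent

    def test_sequential_ss_decomposition(self):
        rng = np.random.default_rng(2)
        n = 300
        Z = (rng.random((n, 3)) < 0.5).astype(np.int8)
        enc = make_encoding(Z)
        part = fm.FunctionalPartition(
            assignment={"c0|1/1": "A", "c1|1/1": "B", "c2|1/1": "R"},
            group_order=["A", "B", "R"],
            residual="R",
        )
        y = 2.0 * Z[:, 0] + Z[:, 1] + rng.normal(size=n)
        eff = fm.group_anova_effects(enc, y, part)
        anova = eff.anova_table
        tss = float(((y - y.mean()) ** 2).sum())
        assert anova["sum_sq"].sum() == pytest.approx(tss, rel=1e-8)


class TestCompareKeyFamilies:
    def _traces(self, seed=0):
        """A small paired run of both routes over the same family universe."""
        rng = np.random.default_rng(seed)
        table, enc, truth, y = fm.simulate_study(
            n_samples=50, n_families=10, seed=seed
        )
        tree = fm.fit_tree(enc, y, max_groups=4)
        fc = fm.backward_select_families(enc, y, tree)
        lm = fm.backward_select_linear(
            table.relative_abundance(), y, predictor_ids=table.family_ids
        )
        return table, lm, fc

    def test_categories_partition_the_universe(self):
        table, lm, fc = self._traces()
        comp = fm.compare_key_families(lm, fc)
        assert len(comp) == table.n_families
        counts = comp["category"].value_counts()
        assert counts.sum() == table.n_families
        pct = comp.attrs["category_percentages"]
        assert sum(pct.values()) == pytest.approx(100.0)

    def test_family_kept_by_both_routes(self):
        table, lm, fc = self._traces()
        comp = fm.compare_key_families(lm, fc)
        for fam in set(lm.final.kept) & set(fc.final.kept):
            assert comp.loc[fam, "category"] == "both"
        for fam in set(table.family_ids) - set(lm.final.kept) - set(fc.final.kept):
            assert comp.loc[fam, "category"] == "neither"

    def test_universe_mismatch_is_an_error(self):
        table, lm, fc = self._traces()
        fc.initial_ids = fc.initial_ids[:-1]
        with pytest.raises(ValidationError, match="universes"):
            fm.compare_key_families(lm, fc)


class TestMedianAbundanceCheck:
    def _table(self, totals):
        counts = np.array([totals], dtype=int)  # one sample carries the totals
        counts = np.vstack([counts, np.ones_like(counts)])
        return fm.AbundanceTable(
            sample_ids=["s1", "s2"],
            family_ids=[f"f{j}" for j in range(len(totals))],
            counts=counts,
        )

    def test_identical_groups(self):
        table = self._table([5, 5, 5, 5])
        res = fm.median_abundance_check(table, {"f0", "f1"}, {"f2", "f3"})
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_hand_computed_rank_sums(self):
        # totals 1,2,3 vs 10,20,30 (+1 read per family in the filler row)
        table = self._table([0, 1, 2, 9, 19, 29])
        res = fm.median_abundance_check(
            table, {"f0", "f1", "f2"}, {"f3", "f4", "f5"}
        )
        assert res.statistic == pytest.approx(3.857, abs=5e-4)
        assert res.p_value == pytest.approx(0.0495, abs=5e-4)

    def test_empty_set_is_an_error(self):
        table = self._table([1, 2, 3])
        with pytest.raises(ParameterError):
            fm.median_abundance_check(table, set(), {"f0"})

    def test_random_key_sets_rarely_significant(self):
        """Under the null, key status is unrelated to abundance."""
        table = fm.simulate_abundance_table(n_samples=30, n_families=40, seed=6)
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(100):
            key = set(rng.choice(table.family_ids, size=12, replace=False))
            nonkey = set(table.family_ids) - key
            res = fm.median_abundance_check(table, key, nonkey)
            hits += res.p_value < 1e-3
        assert hits <= 1
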