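"""Functional clustering: motifs, motif-mean fits, tree search, ordering, selection."""

import numpy as np
import pytest

import funcmotif as fm
from funcmotif.clustering import _Engine, _codes_of
from funcmotif.exceptions import ParameterError
from conftest import make_encoding, random_instance


def two_group_partition():
    return fm.FunctionalPartition(
        assignment={"c0|1/1": "A", "c1|1/1": "A", "c2|1/1": "B"},
        group_order=["A", "B"],
    )


class TestMotifOfSample:
    def test_single_group_present(self):
        part = two_group_partition()
        assert fm.motif_of_sample([0, 1, 0], part) == frozenset({"A"})

    def test_empty_row_is_empty_motif(self):
        assert fm.motif_of_sample([0, 0, 0], two_group_partition()) == frozenset()

    def test_full_row_is_all_groups(self):
        assert fm.motif_of_sample([1, 1, 1], two_group_partition()) == {"A", "B"}


class TestFitMotifMeans:
    def test_worked_example(self):
        """Motifs {A}: y=2,4 and {A,B}: y=10 -> fitted [3,3,10], R^2=0.9423."""
        enc = make_encoding(np.array([[1, 0, 0], [0, 1, 0], [1, 0, 1]]))
        part = two_group_partition()
        fit = fm.fit_motif_means(enc, np.array([2.0, 4.0, 10.0]), part)
        assert fit.fitted.tolist() == [3.0, 3.0, 10.0]
        assert fit.extras["tss"] == pytest.approx(34.6667, abs=5e-4)
        assert fit.extras["rss"] == pytest.approx(2.0)
        assert fit.r2 == pytest.approx(0.9423, abs=5e-5)

    def test_all_motifs_distinct_gives_perfect_fit(self):
        enc = make_encoding(np.array([[1, 0], [0, 1], [1, 1], [0, 0]]))
        part = fm.FunctionalPartition(
            assignment={"c0|1/1": "A", "c1|1/1": "B"}, group_order=["A", "B"]
        )
        fit = fm.fit_motif_means(enc, np.array([1.0, 2.0, 3.0, 4.0]), part)
        assert fit.r2 == 1.0

    def test_single_motif_explains_nothing(self):
        enc = make_encoding(np.ones((4, 2), dtype=np.int8))
        part = fm.FunctionalPartition(
            assignment={"c0|1/1": "A", "c1|1/1": "A"}, group_order=["A"]
        )
        with pytest.warns(UserWarning, match="single observed motif"):
            fit = fm.fit_motif_means(enc, np.array([1.0, 2.0, 3.0, 4.0]), part)
        assert fit.r2 == pytest.approx(0.0)

    def test_per_motif_residuals_sum_to_zero(self):
        rng = np.random.default_rng(8)
        enc, y = random_instance(rng, n=40, m=5)
        part = fm.exhaustive_oracle(enc, y, 2).partition
        fit = fm.fit_motif_means(enc, y, part)
        resid = y - fit.fitted
        for motif in set(fit.extras["motifs"]):
            mask = [m == motif for m in fit.extras["motifs"]]
            assert abs(resid[mask].sum()) < 1e-9

    def test_r2_matches_independent_direct_formula(self):
        """Engine R^2 agrees with a from-scratch groupby computation."""
        rng = np.random.default_rng(15)
        for _ in range(10):
            enc, y = random_instance(rng, n=35, m=6)
            part = fm.exhaustive_oracle(enc, y, 3).partition
            fit = fm.fit_motif_means(enc, y, part)
            # independent route: dict-of-lists means
            motifs = [
                fm.motif_of_sample(row, part, enc.class_names)
                for row in enc.indicators
            ]
            cells: dict = {}
            for m, v in zip(motifs, y):
                cells.setdefault(m, []).append(v)
            rss = sum(
                sum((v - np.mean(vs)) ** 2 for v in vs) for vs in cells.values()
            )
            tss = float(((y - y.mean()) ** 2).sum())
            assert fit.r2 == pytest.approx(1 - rss / tss, abs=1e-10)


class TestFitTree:
    def test_zero_noise_planted_two_groups(self):
        rng = np.random.default_rng(1)
        Z = (rng.random((40, 6)) < 0.5).astype(np.int8)
        enc = make_encoding(Z)
        truth = fm.FunctionalPartition(
            assignment={
                "c0|1/1": "A", "c1|1/1": "A", "c2|1/1": "B",
                "c3|1/1": "B", "c4|1/1": "B", "c5|1/1": "B",
            },
            group_order=["A", "B"],
        )
        motifs = [fm.motif_of_sample(r, truth, enc.class_names) for r in Z]
        means = {frozenset(): 0.0, frozenset({"A"}): 1.0,
                 frozenset({"B"}): 5.0, frozenset({"A", "B"}): 9.0}
        y = np.array([means[m] for m in motifs])
        tree = fm.fit_tree(enc, y, max_groups=2)
        assert tree.levels[-1].r2 == 1.0
        # recovered grouping matches the planted one up to labels
        rec = tree.levels[-1].partition.assignment
        groups = {rec[c] for c in ["c0|1/1", "c1|1/1"]}
        assert len(groups) == 1
        assert {rec[c] for c in ["c2|1/1", "c3|1/1", "c4|1/1", "c5|1/1"]} != groups

    def test_r2_nondecreasing_over_levels(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            enc, y = random_instance(rng, n=25, m=7)
            tree = fm.fit_tree(enc, y, max_groups=4)
            r2s = [lv.r2 for lv in tree.levels]
            assert all(b >= a - 1e-12 for a, b in zip(r2s, r2s[1:]))

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        enc, y = random_instance(rng, n=30, m=8)
        t1 = fm.fit_tree(enc, y, max_groups=3)
        t2 = fm.fit_tree(enc, y, max_groups=3)
        assert [lv.partition.assignment for lv in t1.levels] == [
            lv.partition.assignment for lv in t2.levels
        ]

    def test_parameter_errors(self):
        enc = make_encoding(np.eye(3, dtype=np.int8))
        with pytest.raises(ParameterError):
            fm.fit_tree(enc, np.array([1.0, 2.0, 3.0]), max_groups=5)
        with pytest.raises(ParameterError):
            fm.fit_tree(enc, np.array([1.0, 2.0, 3.0]), max_groups=1)


class TestExhaustiveOracle:
    def test_enumeration_count_matches_stirling(self):
        enc = make_encoding(np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 0]]))
        res = fm.exhaustive_oracle(enc, np.array([1.0, 2.0, 3.0, 4.0]), 2)
        assert res.n_examined == 3  # S(3,2)

    def test_single_group_is_trivial_partition(self):
        enc = make_encoding(np.array([[1, 0], [0, 1], [1, 1]]))
        y = np.array([1.0, 2.0, 4.0])
        res = fm.exhaustive_oracle(enc, y, 1)
        assert res.n_examined == 1
        fit = fm.fit_motif_means(enc, y, res.partition)
        assert res.r2 == pytest.approx(fit.r2, abs=1e-12)

    def test_oracle_bounds_greedy(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            enc, y = random_instance(rng, n=25, m=6)
            g = int(rng.integers(2, 4))
            tree = fm.fit_tree(enc, y, max_groups=g)
            oracle = fm.exhaustive_oracle(enc, y, g)
            assert tree.levels[-1].r2 <= oracle.r2 + 1e-9

    def test_guard_refuses_huge_enumerations(self):
        rng = np.random.default_rng(5)
        enc, y = random_instance(rng, n=20, m=25)
        with pytest.raises(ParameterError, match="guard"):
            fm.exhaustive_oracle(enc, y, 8)


class TestOrderGroups:
    def test_dominant_group_labeled_a_and_residual_last(self):
        """The group explaining most variance comes first; weakest is residual."""
        rng = np.random.default_rng(6)
        Z = (rng.random((60, 6)) < 0.5).astype(np.int8)
        enc = make_encoding(Z)
        part = fm.FunctionalPartition(
            assignment={
                "c0|1/1": "X", "c1|1/1": "X",   # strong effect
                "c2|1/1": "Y", "c3|1/1": "Y",   # weak effect
                "c4|1/1": "Z", "c5|1/1": "Z",   # no effect
            },
            group_order=["X", "Y", "Z"],
        )
        pres_strong = Z[:, :2].any(axis=1)
        pres_weak = Z[:, 2:4].any(axis=1)
        y = 10.0 * pres_strong + 3.0 * pres_weak + 0.05 * rng.normal(size=60)
        ordered = fm.order_groups(part, enc, y)
        assert ordered.residual == ordered.group_order[-1]
        assert set(ordered.members("A")) == {"c0|1/1", "c1|1/1"}
        assert set(ordered.members("B")) == {"c2|1/1", "c3|1/1"}
        assert set(ordered.members(ordered.residual)) == {"c4|1/1", "c5|1/1"}

    def test_ordering_preserves_fit(self):
        rng = np.random.default_rng(7)
        enc, y = random_instance(rng, n=30, m=6)
        part = fm.exhaustive_oracle(enc, y, 3).partition
        ordered = fm.order_groups(part, enc, y)
        assert fm.fit_motif_means(enc, y, ordered).r2 == pytest.approx(
            fm.fit_motif_means(enc, y, part).r2, abs=1e-12
        )


class TestMotifLabelInvariance:
    def test_class_permutation_only_relabels_groups(self):
        """Permuting class input order changes labels, not the sample partition."""
        rng = np.random.default_rng(12)
        Z = (rng.random((40, 6)) < 0.5).astype(np.int8)
        enc = make_encoding(Z)
        pres = Z[:, :2].any(axis=1)
        y = 4.0 * pres + 0.1 * rng.normal(size=40)
        tree = fm.fit_tree(enc, y, max_groups=3)
        perm = [3, 0, 5, 1, 4, 2]
        enc_p = enc.subset_classes(perm)
        tree_p = fm.fit_tree(enc_p, y, max_groups=3)
        assert tree_p.levels[-1].r2 == pytest.approx(tree.levels[-1].r2, abs=1e-9)
        # sample partitions into motifs coincide
        for lvl, lvl_p in [(tree.levels[-1], tree_p.levels[-1])]:
            a = lvl.partition.group_indices(enc.class_names)
            ap = lvl_p.partition.group_indices(enc_p.class_names)
            codes = _codes_of(enc.indicators > 0, a, lvl.partition.n_groups)
            codes_p = _codes_of(enc_p.indicators > 0, ap, lvl_p.partition.n_groups)
            _, inv = np.unique(codes, return_inverse=True)
            _, inv_p = np.unique(codes_p, return_inverse=True)
            # same grouping of samples up to relabeling
            mapping = {}
            for i, j in zip(inv, inv_p):
                assert mapping.setdefault(i, j) == j


class TestBackwardSelectFamilies:
    def _planted_setup(self, rng, n=50):
        """Two signal families (one class each) + residual families."""
        Z = (rng.random((n, 6)) < 0.5).astype(np.int8)
        enc = make_encoding(Z)
        pres = Z[:, 0].astype(bool)
        y = 5.0 * pres + 0.1 * rng.normal(size=n)
        part = fm.FunctionalPartition(
            assignment={
                "c0|1/1": "A",
                **{f"c{j}|1/1": "B" for j in range(1, 6)},
            },
            group_order=["A", "B"],
            residual="B",
        )
        return enc, y, part

    def test_redundant_residual_families_removed(self):
        rng = np.random.default_rng(20)
        enc, y, part = self._planted_setup(rng)
        trace = fm.backward_select_families(enc, y, part)
        # residual stays present in every sample throughout, so removals
        # that keep motifs unchanged are accepted until that breaks
        assert "c0" in trace.final.kept
        assert len(trace.final.kept) < 6
        for step in trace.steps:
            assert step.removed != "c0"

    def test_family_with_non_residual_class_never_candidate(self):
        rng = np.random.default_rng(21)
        enc, y, part = self._planted_setup(rng)
        trace = fm.backward_select_families(enc, y, part)
        assert all(s.removed != "c0" for s in trace.steps)

    def test_no_residual_families_zero_steps(self):
        rng = np.random.default_rng(22)
        Z = (rng.random((30, 2)) < 0.5).astype(np.int8)
        enc = make_encoding(Z)
        y = 3.0 * Z[:, 0] + Z[:, 1] + 0.1 * rng.normal(size=30)
        part = fm.FunctionalPartition(
            assignment={"c0|1/1": "A", "c1|1/1": "B"},
            group_order=["A", "B"],
            residual="B",
        )
        # the only residual family (c1) changes motifs when removed
        trace = fm.backward_select_families(enc, y, part)
        assert trace.steps == []
        assert trace.final.kept == ["c0", "c1"]

    def test_motifs_unchanged_after_selection(self):
        rng = np.random.default_rng(23)
        enc, y, part = self._planted_setup(rng)
        before = fm.fit_motif_means(enc, y, part)
        trace = fm.backward_select_families(enc, y, part)
        after = trace.final
        assert after.extras["rss"] == pytest.approx(before.extras["rss"], abs=1e-12)
        assert after.r2 == pytest.approx(before.r2, abs=1e-12)
        assert after.reported_df == 6 - len(after.kept)
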