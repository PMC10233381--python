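import math

import numpy as np
import pytest
from scipy import stats

from rbpcoreg.interactome import (
    CallParams,
    LfqMatrix,
    anova_permutation_fdr,
    call_interactors,
    oneway_f,
    quantifiable_filter,
    region_overlap,
)
from rbpcoreg.synthetic import SimConfig, simulate_ip_lfq

from .conftest import make_lfq


class TestOnewayF:
    def test_matches_scipy_on_regular_data(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            groups = [rng.normal(size=rng.integers(3, 7)) for _ in range(rng.integers(2, 5))]
            expected = stats.f_oneway(*groups).statistic
            assert oneway_f(groups) == pytest.approx(expected, rel=1e-10)

    def test_degenerate_cases(self):
        assert oneway_f([np.array([5.0, 5, 5]), np.array([5.0, 5, 5])]) == 0.0
        assert math.isinf(oneway_f([np.array([1.0, 1, 1]), np.array([10.0, 10, 10])]))


class TestAnovaPermutation:
    def test_identical_groups_give_f0_p1(self):
        res = anova_permutation_fdr({"p": [np.array([5.0, 5, 5]), np.array([5.0, 5, 5])]})
        assert res["p"].f_stat == 0.0 and res["p"].p_value == 1.0

    def test_exhaustive_perfect_separation(self):
        # C(6,3)=20 label splits; only the two perfect ones reach F=inf
        res = anova_permutation_fdr(
            {"p": [np.array([1.0, 1, 1]), np.array([10.0, 10, 10])]}, n_permutations=1000
        )
        assert res["p"].p_value == pytest.approx(0.1)

    def test_all_missing_group_is_skipped_not_raised(self):
        res = anova_permutation_fdr(
            {"p": [np.array([np.nan, np.nan]), np.array([1.0, 2.0])]}
        )
        assert res["p"].skipped and res["p"].skip_reason == "group-all-missing"

    def test_three_group_exhaustive_enumeration(self):
        # 3 groups of 2: 6!/(2!2!2!) = 90 assignments, enumerated exactly
        groups = [np.array([1.0, 1.0]), np.array([5.0, 5.0]), np.array([9.0, 9.0])]
        res = anova_permutation_fdr({"p": groups}, n_permutations=200)
        # only assignments reproducing the 3-way split (3! orderings x ... )
        assert 0 < res["p"].p_value < 0.1

    def test_null_pvalues_superuniform(self):
        rng = np.random.default_rng(42)
        vals = {
            f"P{i}": [rng.normal(size=6), rng.normal(size=6)] for i in range(300)
        }
        res = anova_permutation_fdr(vals, n_permutations=1000, seed=9)
        p = np.array([r.p_value for r in res.values()])
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_qvalues_monotone_in_f(self):
        rng = np.random.default_rng(1)
        vals = {f"P{i}": [rng.normal(size=4), rng.normal(size=4)] for i in range(50)}
        res = anova_permutation_fdr(vals, n_permutations=200, seed=2)
        ordered = sorted(res.values(), key=lambda r: -r.f_stat)
        qs = [r.q_value for r in ordered]
        assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))


class TestCallInteractors:
    def toy_matrix(self):
        return make_lfq(
            {
                "p1": ([30] * 6, [10] * 6),
                "p2": ([20] * 6, [20] * 6),
                "p3": ([25, 25, None, None, None, None], [10] * 6),
            }
        )

    def test_toy_matrix_calls_exactly_p1(self):
        calls = call_interactors(self.toy_matrix(), CallParams(seed=0))
        called = {c.protein_id for c in calls if c.called}
        assert called == {"p1"}
        by_id = {c.protein_id: c for c in calls}
        assert "fold_change" in by_id["p2"].reasons
        assert "detection" in by_id["p3"].reasons

    def test_zero_bait_detections_tagged(self):
        m = make_lfq({"p1": ([None] * 6, [10] * 6)})
        (c,) = call_interactors(m, CallParams(seed=0))
        assert not c.called and "detection" in c.reasons
        assert math.isnan(c.fold_change)

    def test_absent_control_gives_infinite_fold_change(self):
        m = make_lfq({"p1": ([30] * 6, [None] * 6), "p2": ([20] * 6, [20] * 6)})
        calls = {c.protein_id: c for c in call_interactors(m, CallParams(seed=0))}
        assert math.isinf(calls["p1"].fold_change)
        assert "fold_change" not in calls["p1"].reasons

    def test_missing_bait_group_is_error(self):
        m = make_lfq({"p1": ([30] * 6, [10] * 6)})
        with pytest.raises(ValueError, match="bait"):
            call_interactors(m, CallParams(bait_group="nosuch"))

    def test_row_and_column_order_invariance(self):
        m = self.toy_matrix()
        perm_rows = [2, 0, 1]
        perm_cols = [5, 4, 3, 2, 1, 0, 11, 10, 9, 8, 7, 6]
        m2 = LfqMatrix(
            proteins=[m.proteins[i] for i in perm_rows],
            samples=[m.samples[j] for j in perm_cols],
            intensity=m.intensity[np.ix_(perm_rows, perm_cols)],
            peptides=m.peptides[np.ix_(perm_rows, perm_cols)],
        )
        c1 = {c.protein_id: (c.called, c.n_detected_bait) for c in
              call_interactors(m, CallParams(seed=0))}
        c2 = {c.protein_id: (c.called, c.n_detected_bait) for c in
              call_interactors(m2, CallParams(seed=0))}
        assert c1 == c2

    def test_planted_recovery(self):
        sens, fdp = [], []
        for seed in range(5):
            cfg = SimConfig(seed=seed, n_proteins=50, n_interactors=5,
                            interactor_fc=3.0, lfq_noise_cv=0.2)
            m, truth = simulate_ip_lfq(cfg)
            called = {c.protein_id for c in call_interactors(m, CallParams(seed=seed))
                      if c.called}
            tp = len(called & truth)
            sens.append(tp / len(truth))
            fdp.append((len(called) - tp) / max(len(called), 1))
        assert np.mean(sens) >= 0.9 and np.mean(fdp) <= 0.1


class TestRegionOverlap:
    def test_disjoint_sets(self):
        labels, counts = region_overlap({"A": {"p1"}, "B": {"p2"}})
        assert labels == {"p1": frozenset({"A"}), "p2": frozenset({"B"})}

    def test_hand_set_algebra(self):
        labels, counts = region_overlap({"A": {"p1", "p2"}, "B": {"p1"}, "C": {"p1", "p3"}})
        assert labels["p1"] == frozenset({"A", "B", "C"})
        assert labels["p2"] == frozenset({"A"})
        assert labels["p3"] == frozenset({"C"})
        assert counts[frozenset({"A", "B", "C"})] == 1

    def test_identical_sets_single_label(self):
        labels, counts = region_overlap({"A": {"p1", "p2"}, "B": {"p1", "p2"}})
        assert set(counts) == {frozenset({"A", "B"})}


class TestQuantifiableFilter:
    def test_group_membership_thresholds(self):
        proteins = {
            "two_groups": ([10] * 6, [10, None, None, None, None, None]),
            "one_group": ([10] * 6, [None] * 6),
        }
        m = make_lfq(proteins)
        kept = quantifiable_filter(m, CallParams())
        assert kept == {"two_groups"}
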