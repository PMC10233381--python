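import math

import numpy as np
import pandas as pd
import pytest

from rbpcoreg.io_formats import EdgeTable
from rbpcoreg.mirna import (
    cobinding_counts,
    differential_mirna,
    filter_read_lengths,
    normalize_cpm,
    prioritize_targets,
    select_dysregulated,
    sex_concordance,
)
from rbpcoreg.synthetic import SimConfig, simulate_mirna_counts


def single_sex_frame(wt, ko, sex="M"):
    cols = [f"KO_{sex}_{i}" for i in range(len(ko))] + [f"WT_{sex}_{i}" for i in range(len(wt))]
    design = {c: ("KO", sex) for c in cols[: len(ko)]}
    design.update({c: ("WT", sex) for c in cols[len(ko):]})
    cpm = pd.DataFrame([ko + wt], index=["m1"], columns=cols, dtype=float)
    return cpm, design


class TestNormalizeCpm:
    def test_simple_value(self):
        counts = pd.DataFrame({"s1": [10]}, index=["m1"])
        cpm = normalize_cpm(counts, pd.Series({"s1": 1e6}))
        assert cpm.loc["m1", "s1"] == 10.0

    def test_scale_invariance(self):
        counts = pd.DataFrame({"s1": [10, 30], "s2": [5, 25]}, index=["a", "b"])
        assert np.allclose(normalize_cpm(counts), normalize_cpm(counts * 2))

    def test_zero_library_is_error(self):
        counts = pd.DataFrame({"s1": [0]}, index=["m1"])
        with pytest.raises(ValueError, match="library"):
            normalize_cpm(counts)


class TestDifferentialMirna:
    def test_identical_groups_null_result(self):
        cpm, design = single_sex_frame([100.0, 100, 100], [100.0, 100, 100])
        t = differential_mirna(cpm, design, method="welch")
        row = t.iloc[0]
        assert row["linear_fc"] == 1.0 and row["pct_change"] == 0.0
        assert not row.divergent

    @pytest.mark.parametrize("method", ["welch", "moderated"])
    def test_clear_doubling_is_significant(self, method):
        cpm, design = single_sex_frame([100.0, 110, 90], [200.0, 220, 180])
        t = differential_mirna(cpm, design, method=method)
        row = t.iloc[0]
        assert row.log2_fc == pytest.approx(1.0, abs=0.05)
        assert row.p_value < 0.05

    def test_constant_groups_fall_back_to_exact_permutation(self):
        # perfect separation of 3v3 constants: 2 of C(6,3)=20 splits tie the obs
        cpm, design = single_sex_frame([5.0, 5, 5], [7.0, 7, 7])
        t = differential_mirna(cpm, design, method="welch")
        assert t.iloc[0].p_value == pytest.approx(0.1)

    def test_divergent_requires_opposite_signs(self):
        cols = {
            "KO_M_1": 200.0, "KO_M_2": 210.0, "KO_M_3": 190.0,
            "WT_M_1": 100.0, "WT_M_2": 105.0, "WT_M_3": 95.0,
            "KO_F_1": 50.0, "KO_F_2": 52.0, "KO_F_3": 48.0,
            "WT_F_1": 100.0, "WT_F_2": 98.0,
        }
        design = {c: (c[:2], c[3]) for c in cols}
        cpm = pd.DataFrame([list(cols.values())], index=["m1"], columns=list(cols))
        for divergence in ("per-sex", "interaction"):
            t = differential_mirna(cpm, design, method="welch", divergence=divergence)
            assert bool(t.divergent.iloc[0])
        # same direction in both sexes: never divergent
        cols_same = dict(cols, KO_F_1=200.0, KO_F_2=210.0, KO_F_3=195.0)
        cpm2 = pd.DataFrame([list(cols_same.values())], index=["m1"], columns=list(cols_same))
        t2 = differential_mirna(cpm2, design, method="welch")
        assert not bool(t2.divergent.iloc[0])

    def test_untestable_cell_flagged(self):
        cpm, design = single_sex_frame([100.0], [120.0, 130, 110])
        t = differential_mirna(cpm, design, method="welch")
        assert not t.iloc[0].testable and math.isnan(t.iloc[0].p_value)

    def test_moderated_matches_limma_oracle(self):
        # frozen p-values from limma (lmFit ~0+group, contrasts KO-WT per sex,
        # eBayes) on the seed-11 synthetic counts
        cfg = SimConfig(seed=11, n_mirnas=30, n_de_mirnas=5)
        counts, design, _ = simulate_mirna_counts(cfg)
        t = differential_mirna(normalize_cpm(counts), design, method="moderated")
        expected = {
            "miR-0001": (0.374588, 0.015560),
            "miR-0002": (0.411655, 0.546463),
            "miR-0003": (0.058689, 0.513712),
            "miR-0004": (0.022832, 0.633947),
            "miR-0005": (0.039280, 0.579383),
            "miR-0006": (0.846998, 0.312045),
            "miR-0007": (0.870669, 0.160932),
            "miR-0008": (0.355397, 0.902708),
        }
        for mirna, (p_m, p_f) in expected.items():
            got_m = t[(t.mirna == mirna) & (t.sex == "M")].p_value.iloc[0]
            got_f = t[(t.mirna == mirna) & (t.sex == "F")].p_value.iloc[0]
            assert got_m == pytest.approx(p_m, rel=1e-3)
            assert got_f == pytest.approx(p_f, rel=1e-3)

    def test_planted_divergence_recovery(self):
        sens = []
        for seed in range(5):
            cfg = SimConfig(seed=seed, n_mirnas=200, n_de_mirnas=20, de_effect=2.0)
            counts, design, truth = simulate_mirna_counts(cfg)
            t = differential_mirna(normalize_cpm(counts), design)
            planted = set(truth.loc[truth.is_de, "mirna"])
            divergent = set(t.loc[t.divergent, "mirna"])
            sens.append(len(divergent & planted) / len(planted))
        assert np.mean(sens) >= 0.8


class TestSelectDysregulated:
    def frame(self, rows):
        return pd.DataFrame(
            [
                {"mirna": m, "sex": "M", "linear_fc": fc,
                 "pct_change": 100 * abs(fc - 1), "p_value": p, "divergent": div}
                for m, fc, p, div in rows
            ]
        )

    def test_thirty_percent_up_selected(self):
        t = self.frame([("m1", 1.30, 0.01, True)])
        assert select_dysregulated(t) == {"m1"}

    def test_twenty_percent_down_excluded(self):
        t = self.frame([("m1", 0.80, 0.01, True)])
        assert select_dysregulated(t) == set()

    def test_unit_fold_change_excluded(self):
        t = self.frame([("m1", 1.0, 0.001, True)])
        assert select_dysregulated(t) == set()

    def test_significant_gate_on_single_sex_table(self):
        t = self.frame([("m1", 1.5, 0.01, False), ("m2", 1.5, 0.5, False)])
        assert select_dysregulated(t, gate="auto") == {"m1"}

    def test_monotone_in_threshold(self):
        t = self.frame(
            [("m1", 1.3, 0.01, True), ("m2", 1.6, 0.01, True), ("m3", 2.4, 0.01, True)]
        )
        previous = None
        for thr in (10, 25, 40, 80, 200):
            sel = select_dysregulated(t, pct_threshold=thr)
            if previous is not None:
                assert sel <= previous
            previous = sel


class TestCoBinding:
    def test_empty_edges(self):
        assert cobinding_counts(EdgeTable(frozenset()), {"m1"}) == []

    def test_hand_counts(self):
        edges = EdgeTable(frozenset({("m1", "t1", ""), ("m2", "t1", ""), ("m1", "t2", "")}))
        res = {r.target_id: r.cobind_count for r in cobinding_counts(edges, {"m1", "m2"})}
        assert res == {"t1": 2, "t2": 1}

    def test_sources_collapse(self):
        edges = EdgeTable(frozenset({("m1", "t1", "targetscan"), ("m1", "t1", "cometa")}))
        (r,) = cobinding_counts(edges, {"m1"})
        assert r.cobind_count == 1

    def test_unselected_mirnas_ignored(self):
        edges = EdgeTable(frozenset({("m1", "t1", ""), ("mX", "t1", "")}))
        (r,) = cobinding_counts(edges, {"m1"})
        assert r.cobind_count == 1

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n_edges = int(rng.integers(1, 1000))
            mirnas = [f"m{i}" for i in range(20)]
            targets = [f"t{i}" for i in range(50)]
            edges = frozenset(
                (mirnas[rng.integers(20)], targets[rng.integers(50)], "")
                for _ in range(n_edges)
            )
            selected = set(rng.choice(mirnas, size=8, replace=False))
            got = {r.target_id: r.cobind_count
                   for r in cobinding_counts(EdgeTable(edges), selected)}
            brute = {}
            for t in targets:
                c = sum(
                    1 for m in selected
                    if any(e[0] == m and e[1] == t for e in edges)
                )
                if c:
                    brute[t] = c
            assert got == brute

    def test_prioritize_threshold(self):
        edges = EdgeTable(
            frozenset({(f"m{i}", "t1", "") for i in range(9)}
                      | {(f"m{i}", "t2", "") for i in range(7)})
        )
        res = cobinding_counts(edges, {f"m{i}" for i in range(9)})
        assert prioritize_targets(res, 8) == {"t1"}
        assert prioritize_targets(res, 1) == {"t1", "t2"}


class TestSexConcordance:
    def test_same_relation(self):
        flags, n = sex_concordance(
            {"t1": {"M": 1.0, "F": -1.0}}, {"M": 2.0, "F": -0.5}, relation="same"
        )
        assert flags["t1"] and n == 1

    def test_opposite_relation(self):
        flags, n = sex_concordance(
            {"t1": {"M": -1.0, "F": 1.0}}, {"M": 2.0, "F": -0.5}, relation="opposite"
        )
        assert flags["t1"] and n == 1

    def test_tally_and_unevaluable(self):
        targets = {
            "t1": {"M": 1.0, "F": -1.0},
            "t2": {"M": 1.0, "F": -2.0},
            "t3": {"M": -1.0, "F": -1.0},
            "t4": {"M": 1.0},  # missing F
        }
        flags, n = sex_concordance(targets, {"M": 1.0, "F": -1.0}, relation="same")
        assert n == 2
        assert flags["t3"] is False and flags["t4"] is None


class TestReadLengthFilter:
    def test_inclusive_boundaries(self):
        lengths = {"r17": 17, "r18": 18, "r26": 26, "r27": 27}
        assert filter_read_lengths(lengths) == {"r18", "r26"}

    def test_sequence_input(self):
        seqs = ["A" * 17, "A" * 18, "A" * 26, "A" * 27]
        kept = filter_read_lengths(seqs)
        assert kept == {"A" * 18, "A" * 26}
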