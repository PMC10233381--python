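import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from rbpcoreg.enrichment import (
    bin_edges,
    bin_profile,
    enrichment_score,
    permutation_significance,
    permutation_significance_batch,
    rank_targets,
    running_sum,
)
from rbpcoreg.io_formats import GeneSet, rank_pairs
from rbpcoreg.synthetic import SimConfig, simulate_ranked_overlap

from .conftest import brute_force_es


def random_instance(rng, n_max=50, k_max=10):
    n = int(rng.integers(3, n_max + 1))
    genes = [f"g{i}" for i in range(n)]
    scores = np.sort(rng.normal(scale=3.0, size=n))[::-1]
    k = int(rng.integers(1, min(k_max, n - 1) + 1))
    members = set(rng.choice(genes, size=k, replace=False))
    ranked = rank_pairs(
        [(g, float(s)) for g, s in zip(genes, scores)], name="rand"
    )
    return ranked, GeneSet(name="q", members=frozenset(members))


class TestEnrichmentScore:
    def test_top_singleton_unweighted(self, toy_ranked, geneset):
        r = enrichment_score(toy_ranked, geneset("g1"), p=0)
        assert r.es == pytest.approx(1.0)
        assert r.rank_at_max == 1 and r.rank_at_max_pct == 25.0
        assert r.leading_edge == frozenset({"g1"})

    def test_bottom_singleton_unweighted(self, toy_ranked, geneset):
        r = enrichment_score(toy_ranked, geneset("g4"), p=0)
        assert r.es == pytest.approx(-1.0)
        assert r.rank_at_max == 3
        assert r.leading_edge == frozenset({"g4"})

    def test_weighted_top_pair(self, toy_ranked, geneset):
        r = enrichment_score(toy_ranked, geneset("g1", "g2"), p=1)
        assert r.es == pytest.approx(1.0)
        assert r.rank_at_max == 2

    def test_running_sum_profile_matches_hand_values(self, toy_ranked, geneset):
        dev = running_sum(toy_ranked, geneset("g1"), p=0)
        assert np.allclose(dev, [1.0, 2 / 3, 1 / 3, 0.0])

    def test_no_overlap_is_error(self, toy_ranked, geneset):
        with pytest.raises(ValueError, match="no overlap"):
            enrichment_score(toy_ranked, geneset("absent"), p=0)

    def test_full_coverage_is_error(self, toy_ranked, geneset):
        with pytest.raises(ValueError, match="entire list"):
            enrichment_score(toy_ranked, geneset("g1", "g2", "g3", "g4"), p=0)

    def test_absent_members_dropped(self, toy_ranked, geneset):
        r = enrichment_score(toy_ranked, geneset("g1", "zzz"), p=0)
        assert r.n_hits == 1 and r.es == pytest.approx(1.0)

    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_matches_brute_force_oracle(self, p):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            ranked, s = random_instance(rng)
            r = enrichment_score(ranked, s, p=p)
            es, rank = brute_force_es(ranked.genes, list(ranked.scores), s.members, p)
            assert r.es == pytest.approx(es, abs=1e-12)
            assert r.rank_at_max == rank

    def test_antisymmetry_under_list_reversal(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            ranked, s = random_instance(rng, n_max=30, k_max=5)
            fwd = enrichment_score(ranked, s, p=0).es
            rev = rank_pairs(
                [(g, -sc) for g, sc, _ in ranked.entries], name="rev"
            )
            bwd = enrichment_score(rev, s, p=0).es
            if fwd > 0.5:  # top-concentrated sets flip to depletion
                assert bwd <= 0

    def test_es_bounded_and_saturates_at_rank_one(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            ranked, s = random_instance(rng)
            assert abs(enrichment_score(ranked, s, p=0).es) <= 1.0 + 1e-12
        ranked, _ = random_instance(rng, n_max=20, k_max=2)
        top = GeneSet(name="top", members=frozenset({ranked.genes[0]}))
        assert enrichment_score(ranked, top, p=0).es == pytest.approx(1.0)

    def test_monotone_in_member_rank_exhaustive(self):
        # moving one member strictly up never decreases ES (p=0), N <= 12
        n = 8
        genes = [f"g{i}" for i in range(n)]
        ranked = rank_pairs([(g, float(n - i)) for i, g in enumerate(genes)])
        for k in (1, 2, 3):
            for idx in combinations(range(n), k):
                es0 = enrichment_score(
                    ranked, GeneSet(name="s", members=frozenset(genes[i] for i in idx)), p=0
                ).es
                for pos, i in enumerate(idx):
                    for up in range(i):
                        if up in idx:
                            continue
                        moved = set(idx) - {i} | {up}
                        es1 = enrichment_score(
                            ranked,
                            GeneSet(name="s", members=frozenset(genes[j] for j in moved)),
                            p=0,
                        ).es
                        assert es1 >= es0 - 1e-12


class TestPermutationSignificance:
    def test_exhaustive_singleton_pooled_tail(self, toy_ranked, geneset):
        r = permutation_significance(toy_ranked, geneset("g1"), p=0, tail="pooled")
        assert r.p_nominal == pytest.approx(0.25)

    def test_exhaustive_singleton_same_sign_tail(self, toy_ranked, geneset):
        # null ES = {1, 2/3, -2/3, -1}: one of the two positive nulls reaches 1
        r = permutation_significance(toy_ranked, geneset("g1"), p=0, tail="same-sign")
        assert r.p_nominal == pytest.approx(0.5)

    def test_planted_overlap_clears_significance_gates(self):
        cfg = SimConfig(seed=8, n_genes=500, set_size=25,
                        concentration_percentile=5, concentration_fraction=1.0)
        ranked, query, _ = simulate_ranked_overlap(cfg)
        r = permutation_significance(ranked, query, p=1.0, n_permutations=1000, seed=8)
        assert r.p_nominal < 0.01 and r.fdr_q < 0.25
        assert r.es > 0 and r.nes > 1

    def test_null_pvalues_calibrated(self):
        from scipy import stats

        rng = np.random.default_rng(77)
        cfg = SimConfig(seed=77, n_genes=80, set_size=8, concentration_fraction=0.0)
        ranked, _, _ = simulate_ranked_overlap(cfg)
        ps = []
        for d in range(150):
            members = frozenset(rng.choice(ranked.genes, size=8, replace=False))
            r = permutation_significance(
                ranked, GeneSet(name="q", members=members),
                p=1.0, n_permutations=300, seed=5000 + d,
            )
            ps.append(r.p_nominal)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_batch_fdr_flags_only_planted_set(self):
        cfg = SimConfig(seed=13, n_genes=400, set_size=20,
                        concentration_percentile=5, concentration_fraction=1.0)
        ranked, planted, _ = simulate_ranked_overlap(cfg)
        rng = np.random.default_rng(13)
        randoms = [
            GeneSet(name=f"r{i}",
                    members=frozenset(rng.choice(ranked.genes, size=20, replace=False)))
            for i in range(4)
        ]
        results = permutation_significance_batch(
            ranked, [planted, *randoms], p=1.0, n_permutations=300, seed=13
        )
        by_name = {r.name: r for r in results}
        assert by_name["synthetic_query"].fdr_q < 0.25
        assert by_name["synthetic_query"].p_nominal < 0.01


class TestBinProfile:
    def test_bin_edges_sizes(self):
        edges = bin_edges(103, 10)
        sizes = [b - a + 1 for a, b in edges]
        assert sizes == [11, 11, 11, 10, 10, 10, 10, 10, 10, 10]
        assert edges[0][0] == 1 and edges[-1][1] == 103

    def test_forced_top_decile_placement(self):
        genes = [f"g{i}" for i in range(100)]
        ranked = rank_pairs([(g, float(100 - i)) for i, g in enumerate(genes)])
        s = GeneSet(name="top", members=frozenset(genes[:10]))
        prof = bin_profile(ranked, s, n_bins=10, p=0)
        assert [b.count for b in prof.bins] == [10] + [0] * 9
        assert prof.bins[0].fraction == 1.0
        assert prof.bins[0].flag == "all-members"  # 10-member bin of size 10
        assert prof.bins[1].flag == "no-members"

    def test_one_member_per_decile(self):
        genes = [f"g{i}" for i in range(100)]
        ranked = rank_pairs([(g, float(100 - i)) for i, g in enumerate(genes)])
        s = GeneSet(name="u", members=frozenset(genes[::10]))
        prof = bin_profile(ranked, s, n_bins=10, p=0)
        assert [b.count for b in prof.bins] == [1] * 10
        assert all(b.fraction == pytest.approx(0.1) for b in prof.bins)
        assert all(b.es is not None for b in prof.bins)

    def test_planted_54pct_recovered_in_bin1(self):
        fracs = []
        for seed in range(10):
            cfg = SimConfig(seed=seed, n_genes=1000, set_size=100,
                            concentration_percentile=10, concentration_fraction=0.54)
            ranked, query, _ = simulate_ranked_overlap(cfg)
            prof = bin_profile(ranked, query, n_bins=10, p=0)
            fracs.append(prof.bins[0].fraction)
        assert all(abs(f - 0.54) <= 0.1 for f in fracs)

    def test_subset_mode_scores_against_full_list(self):
        genes = [f"g{i}" for i in range(100)]
        ranked = rank_pairs([(g, float(100 - i)) for i, g in enumerate(genes)])
        s = GeneSet(name="m", members=frozenset(genes[:5] + genes[50:55]))
        prof = bin_profile(ranked, s, n_bins=10, p=0, mode="subset")
        assert prof.bins[0].es == pytest.approx(
            enrichment_score(ranked, GeneSet(name="x", members=frozenset(genes[:5])), p=0).es
        )


class TestRankTargets:
    def test_mapping_ranked_descending(self):
        r = rank_targets({"a": 1.0, "b": 2.0})
        assert r.genes == ["b", "a"]

    def test_equal_scores_lexicographic(self):
        r = rank_targets({"b": 2.0, "a": 2.0})
        assert r.genes == ["a", "b"]

    @given(st.permutations([("a", 1.0), ("b", 3.0), ("c", 2.0)]))
    def test_input_order_invariance(self, pairs):
        assert rank_targets(dict(pairs)).genes == ["b", "c", "a"]
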