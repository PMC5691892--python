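"""Weighted KS enrichment score, permutation null, and leading edge."""

import numpy as np
import pytest

from xsig.datamodel import GeneSet
from xsig.gsea import enrichment_score, gene_permutation_test, leading_edge

from conftest import (
    brute_force_es,
    exhaustive_null_es,
    exhaustive_sign_matched_p,
    gene_set_at,
    make_ranked,
)


class TestEnrichmentScore:
    def test_single_hit_at_top_unweighted(self):
        rl = make_ranked([4, 3, 2, 1])
        es, peak, _ = enrichment_score(rl, gene_set_at(rl, {0}), 0.0)
        assert es == pytest.approx(1.0)
        assert peak == 1

    def test_single_hit_at_bottom_unweighted(self):
        rl = make_ranked([4, 3, 2, 1])
        es, peak, _ = enrichment_score(rl, gene_set_at(rl, {3}), 0.0)
        assert es == pytest.approx(-1.0)

    def test_weighted_two_hit_example(self):
        rl = make_ranked([5, 4, 3, 2, 1])
        es, peak, run = enrichment_score(rl, gene_set_at(rl, {0, 2}), 1.0)
        assert es == pytest.approx(2 / 3)
        assert peak == 3
        assert run == pytest.approx(
            [0.625, 0.2916667, 0.6666667, 0.3333333, 0.0], abs=1e-6
        )

    def test_bounded_with_extremes_only_for_end_blocks(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(4, 30))
            m = np.sort(rng.normal(0, 1, n))[::-1]
            rl = make_ranked(list(m))
            k = int(rng.integers(1, n))
            pos = set(rng.choice(n, k, replace=False).tolist())
            es, _, _ = enrichment_score(rl, gene_set_at(rl, pos), 0.0)
            assert -1.0 - 1e-12 <= es <= 1.0 + 1e-12
            # |ES| = 1 only when the hits form a contiguous end block
            if abs(es) == pytest.approx(1.0):
                assert pos in (set(range(k)), set(range(n - k, n)))
        # the single-gene top/bottom cases attain them exactly
        rl = make_ranked([4, 3, 2, 1])
        assert enrichment_score(rl, gene_set_at(rl, {0}), 0.0)[0] == 1.0
        assert enrichment_score(rl, gene_set_at(rl, {3}), 0.0)[0] == -1.0

    def test_reversal_negates_unweighted_es(self):
        rng = np.random.default_rng(4)
        m = np.sort(rng.normal(0, 1, 20))[::-1]
        rl = make_ranked(list(m))
        pos = {2, 7, 11}
        es, _, _ = enrichment_score(rl, gene_set_at(rl, pos), 0.0)
        rl_rev = rl.reversed()
        pos_rev = {19 - p for p in pos}
        gs_rev = GeneSet("S", frozenset(rl_rev.genes[i] for i in pos_rev))
        es_rev, _, _ = enrichment_score(rl_rev, gs_rev, 0.0)
        assert es_rev == pytest.approx(-es)

    def test_errors_on_degenerate_sets(self):
        rl = make_ranked([3, 2, 1])
        with pytest.raises(ValueError, match="intersect"):
            enrichment_score(rl, GeneSet("S", frozenset({"absent"})), 1.0)
        with pytest.raises(ValueError, match="whole"):
            enrichment_score(rl, gene_set_at(rl, {0, 1, 2}), 1.0)
        rl0 = make_ranked([1.0, 0.0, -1.0])
        with pytest.raises(ValueError, match="N_R"):
            enrichment_score(rl0, gene_set_at(rl0, {1}), 1.0)

    def test_matches_gseapy_reference(self):
        """Cross-check the running-sum statistic against gseapy prerank."""
        gseapy = pytest.importorskip("gseapy")
        import pandas as pd

        rng = np.random.default_rng(5)
        m = np.sort(rng.normal(0, 2, 40))[::-1]
        rl = make_ranked(list(m))
        pos = set(rng.choice(40, 6, replace=False).tolist())
        gs = gene_set_at(rl, pos)
        es, _, _ = enrichment_score(rl, gs, 1.0)
        rnk = pd.Series(rl.metric, index=list(rl.genes))
        ref = gseapy.prerank(
            rnk=rnk, gene_sets={"S": sorted(gs.genes)}, permutation_num=4,
            min_size=1, max_size=40, weight=1.0, seed=0, outdir=None,
            no_plot=True,
        ).res2d
        assert es == pytest.approx(float(ref["ES"].iloc[0]), abs=1e-9)


class TestPermutationTest:
    def test_exhaustive_single_gene_example(self):
        # N=4, k=1, unweighted: null = {1, 2/3, -2/3, -1}; observed top
        # gene has sign-matched exhaustive p = 0.5 and NES = 1.2
        rl = make_ranked([4, 3, 2, 1])
        null = exhaustive_null_es(list(rl.metric), 1, 0.0)
        assert sorted(null) == pytest.approx([-1, -2 / 3, 2 / 3, 1])
        res = gene_permutation_test(
            rl, [gene_set_at(rl, {0})], n_perm=4000, weight_p=0.0, seed=0
        )[0]
        assert res.p == pytest.approx(0.5, abs=0.05)
        assert res.nes == pytest.approx(1.2, abs=0.05)

    def test_determinism(self):
        rng = np.random.default_rng(6)
        m = np.sort(rng.normal(0, 1, 30))[::-1]
        rl = make_ranked(list(m))
        sets = [gene_set_at(rl, {1, 5, 9}, "a"),
                gene_set_at(rl, {20, 25}, "b")]
        r1 = gene_permutation_test(rl, sets, n_perm=200, seed=123)
        r2 = gene_permutation_test(rl, sets, n_perm=200, seed=123)
        for a, b in zip(r1, r2):
            assert (a.es, a.nes, a.p, a.q) == (b.es, b.nes, b.p, b.q)
            assert a.leading_edge == b.leading_edge

    def test_nes_sign_matches_es_and_q_in_range(self):
        rng = np.random.default_rng(8)
        m = np.sort(rng.normal(0, 1, 50))[::-1]
        rl = make_ranked(list(m))
        sets = [gene_set_at(rl, {0, 1, 2}, "top"),
                gene_set_at(rl, {47, 48, 49}, "bottom"),
                gene_set_at(rl, {10, 25, 40}, "spread")]
        for r in gene_permutation_test(rl, sets, n_perm=300, seed=9):
            assert np.sign(r.nes) == np.sign(r.es)
            assert 0 <= r.p <= 1
            assert 0 <= r.q <= 1

    def test_single_set_q_equals_p(self):
        rl = make_ranked([5, 4, 3, 2, 1])
        res = gene_permutation_test(
            rl, [gene_set_at(rl, {0, 1})], n_perm=100, seed=2
        )[0]
        assert res.q == res.p


class TestLeadingEdge:
    def test_single_gene_top(self):
        rl = make_ranked([4, 3, 2, 1])
        gs = gene_set_at(rl, {0})
        es, peak, _ = enrichment_score(rl, gs, 0.0)
        assert leading_edge(rl, gs, es, peak) == (rl.genes[0],)

    def test_two_hit_example_includes_both(self):
        rl = make_ranked([5, 4, 3, 2, 1])
        gs = gene_set_at(rl, {0, 2})
        es, peak, _ = enrichment_score(rl, gs, 1.0)
        assert leading_edge(rl, gs, es, peak) == (rl.genes[0], rl.genes[2])

    def test_negative_es_collects_bottom_members_reversed(self):
        rl = make_ranked([6, 5, 4, 3, 2, 1])
        gs = gene_set_at(rl, {4, 5})
        es, peak, _ = enrichment_score(rl, gs, 0.0)
        assert es < 0
        assert leading_edge(rl, gs, es, peak) == (rl.genes[5], rl.genes[4])

    def test_zero_es_empty_with_warning(self, caplog):
        rl = make_ranked([4, 3, 2, 1])
        with caplog.at_level("WARNING"):
            le = leading_edge(rl, gene_set_at(rl, {1}), 0.0, 2)
        assert le == ()
        assert "ES == 0" in caplog.text

    def test_brute_force_agreement_on_random_instances(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            n = int(rng.integers(5, 25))
            m = np.sort(rng.normal(0, 1, n))[::-1]
            rl = make_ranked(list(m))
            k = int(rng.integers(1, min(5, n)))
            pos = set(rng.choice(n, k, replace=False).tolist())
            es, peak, _ = enrichment_score(rl, gene_set_at(rl, pos), 1.0)
            es_bf, peak_bf = brute_force_es(list(m), pos, 1.0)
            assert es == pytest.approx(es_bf, abs=1e-12)
            assert peak == peak_bf


def test_exhaustive_p_oracle_self_consistency():
    """The exhaustive sign-matched p equals 0.5 for the N=4 top gene."""
    null = exhaustive_null_es([4, 3, 2, 1], 1, 0.0)
    assert exhaustive_sign_matched_p(1.0, null) == pytest.approx(0.5)
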