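import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chipnet.enrichment import (
    GeneSet,
    RankedList,
    bh_adjust,
    enrichment_score,
    gsea_preranked,
    rank_metric,
    signature_from_contrast,
)
from chipnet.io import DERecord


def naive_bh(pvals):
    """Direct step-up reference: sort, p*m/i, cumulative min, unsort."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj


class TestBH:
    def test_worked_vector(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == [pytest.approx(0.2)]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_matches_naive_reference_on_random_vectors(self, rng):
        for _ in range(20):
            p = rng.uniform(size=int(rng.integers(1, 200))).tolist()
            assert bh_adjust(p) == pytest.approx(naive_bh(p))

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    def test_monotone_in_sorted_order(self, p):
        adj = bh_adjust(p)
        paired = sorted(zip(p, adj))
        for (_, a1), (_, a2) in zip(paired, paired[1:]):
            assert a1 <= a2 + 1e-12


def de(gene, lfc, p, fdr=0.5):
    return DERecord(gene, lfc, p, fdr, "C")


class TestSignature:
    def test_direction_filter_and_p_sort(self):
        table = [de("A", 1.0, 0.01), de("B", 2.0, 0.001), de("C", -1.0, 1e-5), de("D", 0.5, 0.5)]
        s = signature_from_contrast(table, "up", n=2)
        assert s.members == {"B", "A"}
        s = signature_from_contrast(table, "down", n=5)
        assert s.members == {"C"}

    def test_fewer_than_n_warns_and_returns_all(self, caplog):
        table = [de(f"G{i}", 1.0, 0.01) for i in range(3)]
        with caplog.at_level("WARNING"):
            s = signature_from_contrast(table, "up", n=100)
        assert len(s.members) == 3 and "only 3" in caplog.text

    def test_zero_qualifying_rejected(self):
        with pytest.raises(ValueError, match="down"):
            signature_from_contrast([de("A", 1.0, 0.01)], "down")

    def test_matches_full_sort_oracle_with_ties(self, rng):
        for _ in range(10):
            table = [
                de(f"G{i}", float(rng.choice([-2.0, -1.0, 1.0, 2.0])), float(rng.choice([0.01, 0.02, 0.03])))
                for i in range(50)
            ]
            got = signature_from_contrast(table, "up", n=10).members
            ups = [r for r in table if r.log2fc > 0]
            ups.sort(key=lambda r: (r.pvalue, -abs(r.log2fc), r.gene_id))
            assert got == {r.gene_id for r in ups[:10]}


class TestRankMetric:
    def test_analytic_examples(self):
        ranked = rank_metric([de("A", -2.0, 0.01), de("B", 1.0, 1.0), de("C", 3.0, 0.0)])
        scores = dict(ranked.entries)
        assert scores["A"] == pytest.approx(-2.0)
        assert scores["B"] == 0.0
        assert scores["C"] == 320.0  # p = 0 capped

    def test_descending_with_deterministic_ties(self):
        ranked = rank_metric([de("B", 1.0, 0.1), de("A", 1.0, 0.1), de("C", -1.0, 0.5)])
        assert ranked.genes == ("A", "B", "C")


def naive_unweighted_ks(genes, members):
    """Classic KS statistic: independent of scores, max signed deviation.

    When the largest positive and negative deviations tie in magnitude,
    the positive one is reported (the documented convention).
    """
    n, nh = len(genes), sum(1 for g in genes if g in members)
    running, curve = 0.0, []
    for g in genes:
        running += 1.0 / nh if g in members else -1.0 / (n - nh)
        curve.append(running)
    hi, lo = max(curve), min(curve)
    tol = 1e-12 * max(abs(hi), abs(lo), 1.0)  # ulp-level ties go positive
    return hi if abs(hi) >= abs(lo) - tol else lo


def equal_score_list(n):
    return RankedList(entries=tuple((f"G{i:02d}", float(n - i)) for i in range(n)))


class TestEnrichmentScore:
    def test_top_concentrated_set_reaches_one(self):
        ranked = RankedList(entries=tuple((f"G{i}", 5.0) for i in range(10)))
        es, running, leading = enrichment_score(ranked, GeneSet("s", frozenset(["G0", "G1"])))
        assert es == pytest.approx(1.0)
        assert set(leading) == {"G0", "G1"}

    def test_bottom_concentrated_set_reaches_minus_one(self):
        ranked = RankedList(entries=tuple((f"G{i}", 5.0) for i in range(10)))
        es, _, leading = enrichment_score(ranked, GeneSet("s", frozenset(["G8", "G9"])))
        assert es == pytest.approx(-1.0)
        assert set(leading) == {"G8", "G9"}

    def test_weight_zero_matches_unweighted_ks_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 40))
            scores = {f"G{i:02d}": float(rng.normal()) for i in range(n)}
            ranked = RankedList.from_scores(scores)
            m = int(rng.integers(1, n - 1))
            members = frozenset(rng.choice(ranked.genes, size=m, replace=False).tolist())
            es, _, _ = enrichment_score(ranked, GeneSet("s", members), weight=0.0)
            assert es == pytest.approx(naive_unweighted_ks(ranked.genes, members))

    def test_reversed_list_negates_es_at_weight_zero(self, rng):
        scores = {f"G{i:02d}": float(10 - i) for i in range(12)}
        ranked = RankedList.from_scores(scores)
        rev = RankedList(entries=tuple(reversed([(g, -s) for g, s in ranked.entries])))
        members = frozenset(["G01", "G03", "G07"])
        es_fwd, _, _ = enrichment_score(ranked, GeneSet("s", members), weight=0.0)
        es_rev, _, _ = enrichment_score(rev, GeneSet("s", members), weight=0.0)
        assert es_fwd == pytest.approx(-es_rev)

    def test_es_magnitude_bounded_by_one(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 60))
            ranked = RankedList.from_scores({f"G{i:02d}": float(rng.normal()) for i in range(n)})
            m = int(rng.integers(1, n - 1))
            members = frozenset(rng.choice(ranked.genes, size=m, replace=False).tolist())
            for w in (0.0, 1.0, 2.0):
                es, _, _ = enrichment_score(ranked, GeneSet("s", members), weight=w)
                assert abs(es) <= 1.0 + 1e-12

    def test_full_universe_set_rejected(self):
        ranked = equal_score_list(5)
        with pytest.raises(ValueError, match="degenerate|universe"):
            enrichment_score(ranked, GeneSet("s", frozenset(ranked.genes)))

    def test_zero_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            enrichment_score(equal_score_list(5), GeneSet("s", frozenset(["nope"])))


class TestGseaPreranked:
    def test_same_seed_identical_different_seed_close(self):
        rng = np.random.default_rng(8)
        ranked = RankedList.from_scores({f"G{i:03d}": float(rng.normal()) for i in range(100)})
        gs = GeneSet("s", frozenset(ranked.genes[:15]))
        r1 = gsea_preranked(ranked, [gs], nperm=500, seed=3)[0]
        r2 = gsea_preranked(ranked, [gs], nperm=500, seed=3)[0]
        assert (r1.es, r1.nes, r1.p_perm) == (r2.es, r2.nes, r2.p_perm)
        r3 = gsea_preranked(ranked, [gs], nperm=2000, seed=4)[0]
        assert abs(r1.p_perm - r3.p_perm) < 0.05

    def test_small_universe_matches_exhaustive_null(self):
        """Permutation p for N=8, |S|=3 agrees with the exact 56-subset null."""
        scores = {f"G{i}": s for i, s in enumerate([4.0, 3.0, 2.5, 1.0, -0.5, -1.0, -2.0, -3.0])}
        ranked = RankedList.from_scores(scores)
        members = frozenset(["G0", "G1", "G3"])
        gs = GeneSet("s", members)
        es_obs, _, _ = enrichment_score(ranked, gs)
        null_es = []
        for combo in itertools.combinations(ranked.genes, 3):
            es, _, _ = enrichment_score(ranked, GeneSet("x", frozenset(combo)))
            null_es.append(es)
        same = [e for e in null_es if (e >= 0) == (es_obs >= 0) and abs(e) >= abs(es_obs)]
        p_exact = len(same) / len(null_es)
        nperm = 4000
        res = gsea_preranked(ranked, [gs], nperm=nperm, seed=11)[0]
        # exact binomial 99% CI around the exhaustive proportion
        from scipy.stats import binom

        lo = binom.ppf(0.005, nperm, p_exact) / nperm
        hi = binom.ppf(0.995, nperm, p_exact) / nperm
        assert lo <= res.p_perm <= hi + 1.0 / nperm

    def test_p_floor_with_plus_one_correction(self):
        ranked = equal_score_list(60)
        gs = GeneSet("top", frozenset(ranked.genes[:5]))
        res = gsea_preranked(ranked, [gs], nperm=200, seed=1)[0]
        assert res.p_perm >= 1.0 / 201

    def test_null_fast_path_matches_full_running_sum(self, rng):
        """The candidate-extremum shortcut used for permutation nulls
        agrees with the full running-sum computation."""
        from chipnet.enrichment import _es_from_positions

        for _ in range(50):
            n = int(rng.integers(6, 50))
            ranked = RankedList.from_scores({f"G{i:02d}": float(rng.normal()) for i in range(n)})
            m = int(rng.integers(1, n - 1))
            members = frozenset(rng.choice(ranked.genes, size=m, replace=False).tolist())
            for w in (0.0, 1.0):
                es_full, _, _ = enrichment_score(ranked, GeneSet("s", members), weight=w)
                positions = np.array(
                    sorted(i for i, g in enumerate(ranked.genes) if g in members)
                )
                es_fast = _es_from_positions(positions, np.abs(ranked.scores) ** w, n)
                assert es_fast == pytest.approx(es_full)

    def test_oversized_set_rejected(self):
        ranked = equal_score_list(5)
        with pytest.raises(ValueError):
            gsea_preranked(ranked, [GeneSet("s", frozenset(ranked.genes))], nperm=10, seed=0)
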