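"""Rank metrics, preranked GSEA (with brute-force and external oracles), ssGSEA."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_normalized
from dilutionlab.enrichment import (
    GeneSetCollection,
    RankedList,
    enrichment_score,
    gsea_preranked,
    rank_metric,
    ssgsea_score,
)


def brute_force_es(genes, metrics, gene_set, weight):
    """Enumerate the running sum prefix by prefix (independent oracle)."""
    order = sorted(range(len(genes)), key=lambda i: (-metrics[i], genes[i]))
    hits = [genes[i] in gene_set for i in order]
    n, n_hit = len(genes), sum(hits)
    w_hit = sum(abs(metrics[i]) ** weight for i in order if genes[i] in gene_set)
    running, best = 0.0, 0.0
    for i, is_hit in zip(order, hits):
        if is_hit:
            if w_hit > 0:
                running += abs(metrics[i]) ** weight / w_hit
            else:
                running += 1.0 / n_hit
        else:
            running -= 1.0 / (n - n_hit)
        if abs(running) > abs(best):
            best = running
    return best


class TestRankMetric:
    def _nm(self):
        return make_normalized(
            {
                "up": [8.0, 8.0, 2.0, 2.0],
                "flat": [5.0, 5.0, 5.0, 5.0],
                "down": [1.0, 1.0, 9.0, 9.0],
            },
            samples=["a1", "a2", "b1", "b2"],
        )

    def test_log2_ratio_values_and_order(self):
        ranked = rank_metric(
            self._nm(), ["a1", "a2"], ["b1", "b2"], "log2_ratio", pseudocount=0.0
        )
        assert list(ranked.genes) == ["up", "flat", "down"]
        assert ranked.metrics[0] == pytest.approx(2.0)  # log2(8/2)
        assert ranked.metrics[1] == pytest.approx(0.0)

    def test_signal_to_noise_arithmetic(self):
        nm = make_normalized(
            {"g": [2.5, 1.5, 1.5, 0.5]}, samples=["a1", "a2", "b1", "b2"]
        )
        # muA=2, muB=1, sdA=sdB~0.707 > floor -> s2n = 1/1.414
        ranked = rank_metric(nm, ["a1", "a2"], ["b1", "b2"], "signal_to_noise")
        expected = (2.0 - 1.0) / (np.sqrt(0.5) + np.sqrt(0.5))
        assert ranked.metrics[0] == pytest.approx(expected)

    def test_signal_to_noise_floors_small_sd(self):
        nm = make_normalized(
            {"g": [2.0, 2.0, 1.0, 1.0]}, samples=["a1", "a2", "b1", "b2"]
        )
        ranked = rank_metric(nm, ["a1", "a2"], ["b1", "b2"], "signal_to_noise")
        # zero within-pool sd floored at 0.2*|mean|
        assert ranked.metrics[0] == pytest.approx(1.0 / (0.4 + 0.2))

    def test_overlapping_pools_rejected(self):
        with pytest.raises(ValueError):
            rank_metric(self._nm(), ["a1"], ["a1", "b1"])


class TestEnrichmentScore:
    def test_top_gene_singleton_set(self):
        ranked = RankedList(
            genes=np.array(["a", "b", "c", "d"], object),
            metrics=np.array([4.0, 3.0, 2.0, 1.0]),
        )
        # hit +1 at rank 1, then three misses of 1/3 back to zero;
        # the maximum deviation of the running sum is 1.0
        assert enrichment_score(ranked, {"a"}, weight=1.0) == pytest.approx(1.0)

    def test_matches_brute_force_on_random_draws(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 21))
            genes = np.array([f"g{i}" for i in range(n)], dtype=object)
            metrics = np.round(rng.normal(size=n), 3)
            ranked = RankedList(genes=genes, metrics=metrics)
            size = int(rng.integers(1, n))
            gene_set = set(rng.choice(genes, size=size, replace=False))
            weight = float(rng.choice([0.0, 0.5, 1.0, 1.5]))
            assert enrichment_score(ranked, gene_set, weight) == pytest.approx(
                brute_force_es(list(genes), list(metrics), gene_set, weight),
                abs=1e-12,
            )

    def test_weight_zero_is_unweighted_ks_statistic(self, rng):
        n = 15
        genes = np.array([f"g{i}" for i in range(n)], dtype=object)
        metrics = rng.normal(size=n)
        ranked = RankedList(genes=genes, metrics=metrics)
        gene_set = set(genes[:5])
        hit = np.isin(ranked.genes, list(gene_set))
        ks_run = np.cumsum(np.where(hit, 1 / 5, -1 / (n - 5)))
        expected = ks_run[np.argmax(np.abs(ks_run))]
        assert enrichment_score(ranked, gene_set, weight=0.0) == pytest.approx(
            expected
        )

    def test_sign_flips_when_ranking_reversed(self, rng):
        n = 12
        genes = np.array([f"g{i}" for i in range(n)], dtype=object)
        metrics = np.sort(rng.normal(size=n))[::-1]
        gene_set = set(genes[:4])
        fwd = enrichment_score(
            RankedList(genes=genes, metrics=metrics), gene_set, weight=0.0
        )
        rev = enrichment_score(
            RankedList(genes=genes, metrics=-metrics), gene_set, weight=0.0
        )
        assert rev == pytest.approx(-fwd)

    def test_es_bounded_by_one(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 40))
            genes = np.array([f"g{i}" for i in range(n)], dtype=object)
            ranked = RankedList(genes=genes, metrics=rng.normal(size=n))
            size = int(rng.integers(1, n))
            es = enrichment_score(
                ranked, set(rng.choice(genes, size, replace=False)), 1.0
            )
            assert abs(es) <= 1.0 + 1e-12

    def test_set_equal_to_universe_rejected(self):
        ranked = RankedList(
            genes=np.array(["a", "b"], object), metrics=np.array([2.0, 1.0])
        )
        with pytest.raises(ValueError):
            enrichment_score(ranked, {"a", "b"})


class TestGseaPreranked:
    def _planted(self, rng, n=400, set_size=25):
        genes = np.array([f"g{i:03d}" for i in range(n)], dtype=object)
        metrics = rng.normal(size=n)
        # plant every member of the "hot" set in the top decile
        top = np.argsort(-metrics)[: n // 10]
        hot = set(genes[rng.choice(top, size=set_size, replace=False)])
        cold = set(rng.choice(genes, size=set_size, replace=False))
        return RankedList(genes=genes, metrics=metrics), hot, cold

    def test_planted_set_gets_low_fdr(self, rng):
        ranked, hot, cold = self._planted(rng)
        res = gsea_preranked(
            ranked,
            GeneSetCollection.from_dict({"hot": hot, "cold": cold}),
            n_perm=1000,
            seed=1,
        )
        assert res.table.loc["hot", "ES"] > 0.5
        assert res.table.loc["hot", "FDR"] < 0.05
        assert ((res.table.FDR >= 0) & (res.table.FDR <= 1)).all()

    def test_nes_scales_es_against_null_mean(self, rng):
        ranked, hot, _ = self._planted(rng)
        res = gsea_preranked(
            ranked, GeneSetCollection.from_dict({"hot": hot}), n_perm=200, seed=2
        )
        row = res.table.loc["hot"]
        assert row.NES > 1.0  # stronger than typical random set
        assert np.sign(row.NES) == np.sign(row.ES)

    def test_seeded_determinism(self, rng):
        ranked, hot, cold = self._planted(rng)
        sets = GeneSetCollection.from_dict({"hot": hot, "cold": cold})
        a = gsea_preranked(ranked, sets, n_perm=100, seed=3).table
        b = gsea_preranked(ranked, sets, n_perm=100, seed=3).table
        pd.testing.assert_frame_equal(a, b)

    def test_matches_gseapy_es(self, rng):
        gseapy = pytest.importorskip("gseapy")
        n = 200
        genes = [f"g{i:03d}" for i in range(n)]
        metrics = np.round(np.sort(rng.normal(size=n))[::-1], 4)
        gene_set = list(rng.choice(genes, size=20, replace=False))
        rnk = pd.DataFrame({"gene": genes, "metric": metrics})
        ext = gseapy.prerank(
            rnk=rnk,
            gene_sets={"s": gene_set},
            permutation_num=4,
            outdir=None,
            seed=7,
            min_size=2,
            max_size=500,
            weight=1.0,
            no_plot=True,
        )
        ours = enrichment_score(
            RankedList(genes=np.array(genes, object), metrics=metrics),
            set(gene_set),
            weight=1.0,
        )
        assert float(ext.res2d.ES.iloc[0]) == pytest.approx(ours, abs=1e-6)


class TestSsgseaScore:
    def test_identical_samples_center_to_zero(self):
        nm = make_normalized(
            {"a": [5.0, 5.0], "b": [3.0, 3.0], "c": [1.0, 1.0], "d": [0.5, 0.5]}
        )
        scores = ssgsea_score(nm, {"a", "b"}, row_center=True)
        np.testing.assert_allclose(scores, 0.0, atol=1e-12)

    def test_top_ranked_set_scores_positive(self):
        nm = make_normalized(
            {"a": [9.0, 8.0], "b": [8.0, 9.0], "c": [1.0, 2.0], "d": [0.5, 0.1]}
        )
        scores = ssgsea_score(nm, {"a", "b"}, row_center=False)
        assert (scores > 0).all()
        assert scores.iloc[0] == pytest.approx(scores.iloc[1])

    def test_three_gene_toy_hand_computed(self):
        # sample s0: order a(6) > b(4) > c(2); set {a, c}
        # rank-norm r = (1, 2/3, 1/3); w = r**0.5
        nm = make_normalized({"a": [6.0], "b": [4.0], "c": [2.0]})
        w1, w3 = 1.0, (1 / 3) ** 0.5
        denom = w1 + w3
        ecdf_hit = np.array([w1 / denom, w1 / denom, 1.0])
        ecdf_miss = np.array([0.0, 1.0, 1.0])
        expected = float(np.sum(ecdf_hit - ecdf_miss))
        got = ssgsea_score(nm, {"a", "c"}, weight=0.5, row_center=False)
        assert got.iloc[0] == pytest.approx(expected)

    def test_row_center_requires_two_samples(self):
        nm = make_normalized({"a": [6.0], "b": [4.0], "c": [2.0]})
        with pytest.raises(ValueError):
            ssgsea_score(nm, {"a", "b"}, row_center=True)

    def test_small_intersection_rejected(self):
        nm = make_normalized({"a": [6.0, 1.0], "b": [4.0, 2.0], "c": [2.0, 3.0]})
        with pytest.raises(ValueError):
            ssgsea_score(nm, {"a"}, row_center=False)
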