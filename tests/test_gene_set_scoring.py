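"""ORA, GSEA and GSVA scorers against independent brute-force oracles."""

import math
from math import comb

import numpy as np
import pandas as pd
import pytest

from annobench.gene_set_scoring import (
    GseaParams,
    GsvaParams,
    OraParams,
    gsea_enrichment_score,
    gsea_scores,
    gsva_scores,
    neglog10_transform,
    ora_scores,
)
from annobench.io import GeneSetDB


def hypergeom_tail_oracle(N, K, n, k):
    """P(X >= k) by exhaustive enumeration of the hypergeometric pmf."""
    return sum(
        comb(K, j) * comb(N - K, n - j) / comb(N, n)
        for j in range(k, min(K, n) + 1)
        if n - j <= N - K
    )


def walk_es_oracle(genes, weights, members, p_exp=1.0):
    """Literal running-sum loop; returns (signed extreme, max positive deviation)."""
    hits = [g in members for g in genes]
    nh = sum(hits)
    denom = sum(abs(w) ** p_exp for g, w, h in zip(genes, weights, hits) if h)
    miss = 0.0 if nh == len(genes) else 1.0 / (len(genes) - nh)
    run, best, best_pos = 0.0, 0.0, 0.0
    for g, w, h in zip(genes, weights, hits):
        run += (abs(w) ** p_exp) / denom if h else -miss
        if abs(run) > abs(best):
            best = run
        best_pos = max(best_pos, run)
    return best, best_pos


class TestNegLog10:
    def test_endpoints_and_closed_form(self):
        assert neglog10_transform(1.0, 1e-6) == 0.0
        assert neglog10_transform(0.001, 1e-6) == pytest.approx(3.0)
        assert neglog10_transform(0.0, 1 / 1001) == pytest.approx(math.log10(1001))

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            neglog10_transform(1.5, 0.01)
        with pytest.raises(ValueError):
            neglog10_transform(0.5, 0.0)


class TestOra:
    def test_zero_overlap_scores_zero(self):
        db = GeneSetDB(sets={"t": ["g1", "g2"]})
        scores = ora_scores({"c": ["g3", "g4"]}, db, matrix_genes=["g1", "g2", "g3", "g4"])
        assert scores.loc["t", "c"] == 0.0

    def test_list_equal_to_universe_scores_zero(self):
        db = GeneSetDB(sets={"t": ["g1", "g2"]})
        scores = ora_scores({"c": ["g1", "g2"]}, db, matrix_genes=["g1", "g2"])
        assert scores.loc["t", "c"] == 0.0  # containment forced, p = 1

    def test_full_overlap_closed_form(self):
        genes = [f"g{i:02d}" for i in range(20)]
        db = GeneSetDB(sets={"t": genes[:5], "pad": genes})
        scores = ora_scores({"c": genes[:5]}, db, matrix_genes=genes)
        assert scores.loc["t", "c"] == pytest.approx(-math.log10(1 / comb(20, 5)))

    def test_missing_set_flagged_nan(self):
        db = GeneSetDB(sets={"t": ["g1"], "absent": ["zz"]})
        scores = ora_scores({"c": ["g1"]}, db, matrix_genes=["g1", "g2"])
        assert np.isnan(scores.loc["absent", "c"])

    def test_empty_universe_errors(self):
        db = GeneSetDB(sets={"t": ["g1"]})
        with pytest.raises(ValueError, match="universe"):
            ora_scores({"c": ["g9"]}, db, matrix_genes=["g9"])

    def test_matches_exhaustive_hypergeometric_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            N = int(rng.integers(5, 31))
            genes = [f"g{i:02d}" for i in range(N)]
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            gene_set = list(rng.choice(genes, size=K, replace=False))
            drawn = list(rng.choice(genes, size=n, replace=False))
            db = GeneSetDB(sets={"t": gene_set, "pad": genes})
            score = ora_scores({"c": drawn}, db, matrix_genes=genes).loc["t", "c"]
            k = len(set(gene_set) & set(drawn))
            expected = hypergeom_tail_oracle(N, K, n, k)
            assert score == pytest.approx(-math.log10(max(expected, 1e-300)), rel=1e-9)


class TestGseaEnrichmentScore:
    def test_set_is_top_gene_gives_one(self):
        assert gsea_enrichment_score(["a", "b", "c"], [5, 3, 1], ["a"]) == pytest.approx(1.0)

    def test_four_gene_worked_example(self):
        es = gsea_enrichment_score(["g1", "g2", "g3", "g4"], [3, 2, 1, 1], ["g1", "g3"])
        assert es == pytest.approx(0.75)

    def test_bottom_set_flips_sign(self):
        up = gsea_enrichment_score(["a", "b", "c", "d"], [4, 3, 2, 1], ["a", "b"])
        down = gsea_enrichment_score(["d", "c", "b", "a"], [4, 3, 2, 1], ["a", "b"])
        assert up > 0 > down

    def test_empty_intersection_errors(self):
        with pytest.raises(ValueError, match="no genes"):
            gsea_enrichment_score(["a"], [1.0], ["zz"])

    def test_matches_brute_force_walk_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            N = int(rng.integers(2, 13))
            genes = [f"g{i}" for i in range(N)]
            weights = rng.normal(size=N)
            k = int(rng.integers(1, N + 1))
            members = set(rng.choice(genes, size=k, replace=False))
            p_exp = float(rng.choice([0.0, 1.0, 2.0]))
            es = gsea_enrichment_score(genes, weights, members, p_exp)
            oracle, _ = walk_es_oracle(genes, weights, members, p_exp)
            assert es == pytest.approx(oracle, abs=1e-12)


class TestGseaScores:
    def _planted(self):
        genes = [f"g{i:03d}" for i in range(100)]
        values = np.linspace(10.0, 0.1, 100)
        exy = pd.DataFrame({"c1": values, "c2": values[::-1]}, index=genes)
        db = GeneSetDB(sets={"t": genes[:5]})
        return exy, db

    def test_planted_markers_hit_the_p_floor(self):
        exy, db = self._planted()
        scores = gsea_scores(exy, db, GseaParams(nperm=1000, seed=1))
        assert scores.loc["t", "c1"] == pytest.approx(math.log10(1001))

    def test_same_seed_same_scores(self):
        exy, db = self._planted()
        a = gsea_scores(exy, db, GseaParams(nperm=100, seed=9))
        b = gsea_scores(exy, db, GseaParams(nperm=100, seed=9))
        pd.testing.assert_frame_equal(a, b)

    def test_permutation_p_agrees_with_independent_loop(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i:02d}" for i in range(40)]
        values = rng.gamma(2.0, 2.0, size=40)
        exy = pd.DataFrame({"c1": values, "c2": rng.gamma(2.0, 2.0, size=40)}, index=genes)
        members = set(rng.choice(genes, size=6, replace=False))
        db = GeneSetDB(sets={"t": sorted(members)})
        nperm = 1000
        scores = gsea_scores(exy, db, GseaParams(nperm=nperm, seed=12))
        p_impl = 10 ** (-scores.loc["t", "c1"])
        # independent oracle: python-loop permutations of the hit labels
        order = sorted(genes, key=lambda g: (-exy.loc[g, "c1"], g))
        weights = [exy.loc[g, "c1"] for g in order]
        _, obs = walk_es_oracle(order, weights, members)
        py_rng = np.random.default_rng(999)
        hits_ge = 0
        for _ in range(nperm):
            perm = set(py_rng.choice(genes, size=len(members), replace=False))
            _, es = walk_es_oracle(order, weights, perm)
            hits_ge += es >= obs - 1e-12
        p_oracle = (1 + hits_ge) / (nperm + 1)
        # binomial agreement: both are MC estimates of the same tail probability
        p_hat = (p_impl + p_oracle) / 2
        half_width = 2.58 * math.sqrt(2 * p_hat * (1 - p_hat) / nperm) + 2 / nperm
        assert abs(p_impl - p_oracle) <= half_width


def gsva_literal_oracle(exy, sets, tau=1.0):
    """Stage-by-stage reimplementation of the enrichment statistic with loops."""
    from scipy.stats import norm

    genes = list(exy.index)
    G = len(genes)
    z = {}
    for g in genes:
        row = exy.loc[g].to_numpy()
        sd = row.std(ddof=1)
        if sd == 0:
            for c in exy.columns:
                z[g, c] = 0.5
            continue
        h = sd / 4
        for c in exy.columns:
            z[g, c] = np.mean([norm.cdf((exy.loc[g, c] - v) / h) for v in row])
    out = {}
    for c in exy.columns:
        order = sorted(genes, key=lambda g: (-z[g, c], g))
        for name, members in sets.items():
            k = len([g for g in order if g in members])
            denom = sum(
                abs(G / 2 - (i + 1)) ** tau for i, g in enumerate(order) if g in members
            )
            miss = 0.0 if G == k else 1.0 / (G - k)
            run, best_pos, best_neg = 0.0, 0.0, 0.0
            for i, g in enumerate(order):
                if g in members:
                    run += (abs(G / 2 - (i + 1)) ** tau) / denom if denom else 1.0 / k
                else:
                    run -= miss
                best_pos = max(best_pos, run)
                best_neg = min(best_neg, run)
            out[name, c] = best_pos + best_neg
    return out


class TestGsva:
    def test_matches_literal_stage_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            exy = pd.DataFrame(
                rng.gamma(2.0, 2.0, size=(6, 3)),
                index=[f"g{i}" for i in range(6)], columns=["c1", "c2", "c3"],
            )
            sets = {"s1": {"g0", "g3"}, "s2": {"g1", "g2", "g5"}}
            db = GeneSetDB(sets={k: sorted(v) for k, v in sets.items()})
            scores = gsva_scores(exy, db, GsvaParams())
            oracle = gsva_literal_oracle(exy, sets)
            for (name, c), es in oracle.items():
                assert scores.loc[name, c] == pytest.approx(es, abs=1e-10)

    def test_planted_top_set_orders_clusters(self):
        genes = [f"g{i}" for i in range(20)]
        rng = np.random.default_rng(4)
        exy = pd.DataFrame(rng.gamma(2.0, 1.0, size=(20, 3)) + 0.1,
                           index=genes, columns=["A", "B", "C"])
        exy.loc[genes[:4], "A"] += 50.0  # set genes strictly top-ranked in A only
        db = GeneSetDB(sets={"s": genes[:4]})
        scores = gsva_scores(exy, db)
        assert scores.loc["s", "A"] > 0 > scores.loc["s", "B"]
        assert scores.loc["s", "A"] > 0 > scores.loc["s", "C"]

    def test_cluster_column_equivariance(self):
        rng = np.random.default_rng(8)
        exy = pd.DataFrame(rng.gamma(2.0, 2.0, size=(10, 4)),
                           index=[f"g{i}" for i in range(10)], columns=list("abcd"))
        db = GeneSetDB(sets={"s": ["g1", "g4", "g7"]})
        perm = ["c", "a", "d", "b"]
        direct = gsva_scores(exy[perm], db)
        permuted = gsva_scores(exy, db)[perm]
        pd.testing.assert_frame_equal(direct, permuted)

    def test_es_bounded_and_missing_flagged(self):
        rng = np.random.default_rng(13)
        exy = pd.DataFrame(rng.gamma(2.0, 2.0, size=(12, 5)),
                           index=[f"g{i}" for i in range(12)], columns=list("abcde"))
        db = GeneSetDB(sets={"s": ["g0", "g5"], "absent": ["zz"]})
        scores = gsva_scores(exy, db)
        assert ((scores.loc["s"] >= -1) & (scores.loc["s"] <= 1)).all()
        assert scores.loc["absent"].isna().all()

    def test_fewer_than_three_clusters_errors(self, toy_expression):
        with pytest.raises(ValueError, match="3 clusters"):
            gsva_scores(toy_expression, GeneSetDB(sets={"s": ["gA"]}))


def test_scorers_invariant_to_gene_row_order(small_fixture):
    exy, db = small_fixture["exy"], small_fixture["db"]
    rng = np.random.default_rng(0)
    shuffled = exy.loc[rng.permutation(exy.index)]
    lists_a = {"c": list(exy.index[:20])}
    pd.testing.assert_frame_equal(
        ora_scores(lists_a, db, matrix_genes=exy.index),
        ora_scores(lists_a, db, matrix_genes=shuffled.index),
    )
    pd.testing.assert_frame_equal(
        gsva_scores(exy, db), gsva_scores(shuffled, db)
    )
    pd.testing.assert_frame_equal(
        gsea_scores(exy, db, GseaParams(nperm=50, seed=2)),
        gsea_scores(shuffled, db, GseaParams(nperm=50, seed=2)),
    )
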