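"""Preranked GSEA, hypergeometric overlap, BH, decile trajectories."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from grccax import bh_adjust, decile_trajectories, gsea_preranked, hypergeom_overlap
from grccax.enrichment import enrichment_score


def brute_force_es(ranked: pd.Series, gene_set) -> float:
    """Full running-sum enumeration (weight exponent 1)."""
    hits = set(gene_set)
    total = sum(abs(v) for g, v in ranked.items() if g in hits)
    n = len(ranked)
    nh = len([g for g in ranked.index if g in hits])
    running, best = 0.0, 0.0
    for g, v in ranked.items():
        if g in hits:
            running += abs(v) / total
        else:
            running -= 1.0 / (n - nh)
        if abs(running) > abs(best) or (abs(running) == abs(best) and running > best):
            best = running
    return best


def ranked_fixture(n=10, seed=0):
    rng = np.random.default_rng(seed)
    s = pd.Series(np.sort(rng.normal(size=n))[::-1], index=[f"g{i:02d}" for i in range(n)])
    return s


class TestEnrichmentScore:
    def test_top_heavy_set_matches_brute_force(self):
        ranked = ranked_fixture(10)
        es, _ = enrichment_score(ranked, ["g00", "g01", "g02"])
        assert es == pytest.approx(brute_force_es(ranked, ["g00", "g01", "g02"]), abs=1e-12)
        assert es > 0

    @pytest.mark.parametrize("seed", range(5))
    def test_random_sets_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        ranked = pd.Series(rng.normal(size=20), index=[f"f{i:02d}" for i in range(20)])
        gene_set = list(rng.choice(ranked.index, size=6, replace=False))
        es, _ = enrichment_score(ranked.sort_values(ascending=False), gene_set)
        order = sorted(ranked.index, key=lambda i: (-ranked[i], i))
        assert es == pytest.approx(brute_force_es(ranked.loc[order], gene_set), abs=1e-12)

    def test_sign_antisymmetry(self):
        ranked = ranked_fixture(12, seed=3)
        gene_set = ["g00", "g01", "g05"]
        es_pos, _ = enrichment_score(ranked, gene_set)
        flipped = (-ranked).sort_values(ascending=False)
        es_neg, _ = enrichment_score(flipped, gene_set)
        assert es_neg == pytest.approx(-es_pos, abs=1e-12)

    def test_all_features_set_rejected(self):
        ranked = ranked_fixture(5)
        with pytest.raises(ValueError):
            enrichment_score(ranked, list(ranked.index))

    def test_es_bounded_by_one(self):
        ranked = ranked_fixture(15, seed=1)
        es, _ = enrichment_score(ranked, ["g00", "g01"])
        assert -1 <= es <= 1


class TestGseaPreranked:
    def test_planted_top_set_significant_positive(self):
        rng = np.random.default_rng(0)
        scores = pd.Series(rng.normal(size=200), index=[f"g{i}" for i in range(200)])
        top = list(scores.sort_values(ascending=False).index[:20])
        scores.loc[top] += 2.0
        res = gsea_preranked(scores, {"planted": top, "random": [f"g{i}" for i in range(50, 70)]},
                             n_perm=200, seed=1)
        assert res.loc["planted", "nes"] > 0
        assert res.loc["planted", "fdr"] < 0.05
        assert res.loc["random", "p"] > 0.05

    def test_sign_flip_negates_es_and_nes(self):
        rng = np.random.default_rng(2)
        scores = pd.Series(rng.normal(size=100), index=[f"g{i}" for i in range(100)])
        sets = {"s": [f"g{i}" for i in range(10)]}
        a = gsea_preranked(scores, sets, n_perm=100, seed=5)
        b = gsea_preranked(-scores, sets, n_perm=100, seed=5)
        assert b.loc["s", "es"] == pytest.approx(-a.loc["s", "es"], abs=1e-12)
        assert np.sign(b.loc["s", "nes"]) == -np.sign(a.loc["s", "nes"])

    def test_small_sets_skipped(self):
        scores = pd.Series(np.arange(20.0), index=[f"g{i}" for i in range(20)])
        res = gsea_preranked(scores, {"tiny": ["g0", "g1"]}, n_perm=10, seed=0, min_size=5)
        assert res.empty

    def test_null_p_uniform(self):
        """Random scores, random sets: p-values pass a KS uniformity check."""
        rng = np.random.default_rng(7)
        scores = pd.Series(rng.normal(size=150), index=[f"g{i}" for i in range(150)])
        sets = {f"s{j}": list(rng.choice(scores.index, size=15, replace=False)) for j in range(200)}
        res = gsea_preranked(scores, sets, n_perm=200, seed=8)
        ks = stats.kstest(res["p"], "uniform")
        assert ks.pvalue > 0.01


class TestHypergeomOverlap:
    def test_complete_overlap_exact_combinatorial_p(self):
        """N=20, m=K=k=5: p = 1/C(20,5) = 1/15504."""
        universe = [f"u{i}" for i in range(20)]
        res = hypergeom_overlap(universe[:5], {"s": universe[:5]}, universe)
        assert res.loc["s", "p"] == pytest.approx(1 / math.comb(20, 5), rel=1e-10)

    def test_exact_tail_sum_oracle(self):
        """Upper-tail p equals the sum of point probabilities for N <= 30."""
        universe = [f"u{i}" for i in range(30)]
        query = universe[:8]
        s = universe[4:14]  # K = 10, overlap k = 4
        res = hypergeom_overlap(query, {"s": s}, universe)
        N, K, m, k = 30, 10, 8, 4
        exact = sum(
            math.comb(K, i) * math.comb(N - K, m - i) / math.comb(N, m)
            for i in range(k, min(K, m) + 1)
        )
        assert res.loc["s", "p"] == pytest.approx(exact, rel=1e-10)

    def test_independence_expectation_large_p(self):
        universe = [f"u{i}" for i in range(100)]
        query = universe[:20]
        s = universe[15:40]  # K = 25; overlap with query = 5 = 20 * 25 / 100
        res = hypergeom_overlap(query, {"s": s}, universe)
        assert res.loc["s", "p"] > 0.3

    def test_zero_overlap_p_one(self):
        universe = [f"u{i}" for i in range(10)]
        res = hypergeom_overlap(universe[:3], {"s": universe[5:]}, universe)
        assert res.loc["s", "p"] == pytest.approx(1.0)
        assert np.isfinite(res.loc["s", "odds_ratio"])  # Haldane correction applied

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_overlap(["x"], {"s": ["a"]}, ["a", "b"])


class TestBhAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.37]), [0.37])

    def test_hand_step_up_fixture(self):
        """p = (.01,.02,.03,.04): all adjusted to 0.04."""
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_nan_propagates_without_affecting_ranking(self):
        out = bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], bh_adjust([0.01, 0.02]))

    def test_order_preserved(self):
        p = [0.5, 0.001, 0.9, 0.02]
        out = bh_adjust(p)
        assert out[1] < out[3] < out[0] <= out[2]


class TestDecileTrajectories:
    def stage_matrix(self, features, n_stages=4, fill=1.0):
        return pd.DataFrame(fill, index=features, columns=[f"w{j}" for j in range(n_stages)])

    def test_constant_matrix_flat_curves(self):
        features = [f"g{i:02d}" for i in range(40)]
        scores = pd.Series(np.linspace(1, -1, 40), index=features)
        out = decile_trajectories(scores, self.stage_matrix(features))
        assert (out["median"] == 1.0).all() and (out["mean"] == 1.0).all()

    def test_monotone_outer_product_orders_deciles(self):
        features = [f"g{i:02d}" for i in range(50)]
        scores = pd.Series(np.linspace(2, -2, 50), index=features)
        stages = pd.DataFrame(np.outer(scores, np.arange(1, 5)), index=features,
                              columns=list("abcd"))
        out = decile_trajectories(scores, stages)
        for stage in "abcd":
            med = out[out["stage"] == stage].set_index("decile")["median"]
            assert (np.diff(med.to_numpy()) <= 0).all()  # decile 1 most positive

    def test_twenty_features_make_deciles_of_two(self):
        features = [f"g{i:02d}" for i in range(20)]
        scores = pd.Series(np.arange(20.0)[::-1], index=features)
        out = decile_trajectories(scores, self.stage_matrix(features, 1))
        assert (out["n_features"] == 2).all()
        assert sorted(out["decile"].unique()) == list(range(1, 11))

    def test_unshared_features_dropped(self):
        features = [f"g{i:02d}" for i in range(30)]
        scores = pd.Series(np.arange(30.0), index=features)
        out = decile_trajectories(scores, self.stage_matrix(features[:20], 2))
        assert out[out["stage"] == "w0"]["n_features"].sum() == 20

    def test_too_few_shared_rejected(self):
        scores = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            decile_trajectories(scores, self.stage_matrix(["a", "b"], 2))
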