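"""Rank- and overlap-based gene set enrichment.

``gsea_preranked`` implements the classic weighted Kolmogorov-Smirnov
running-sum statistic on a preranked score vector, with a gene-sampling null
(random same-size sets), sign-matched one-sided p-values, and NES
normalization by the mean |null ES| of matching sign. ``hypergeom_overlap``
is the one-sided hypergeometric overlap test. BH correction is applied across
sets in both.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_adjust",
    "read_gmt",
    "write_gmt",
    "enrichment_score",
    "gsea_preranked",
    "hypergeom_overlap",
    "decile_trajectories",
]

logger = logging.getLogger(__name__)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving with the input.

    NaN inputs propagate as NaN and are excluded from the ranking.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> ids..."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: GMT lines need >= 3 tab-separated fields")
            name, _desc, *ids = parts
            ids = [i for i in ids if i]
            if not ids:
                raise ValueError(f"{path}: line {lineno}: gene set {name!r} is empty")
            sets[name] = list(dict.fromkeys(ids))
    return sets


def write_gmt(sets: dict[str, list[str]], path, descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, ids in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *ids]) + "\n")


def _rank_scores(scores: pd.Series) -> pd.Series:
    """Sort descending by score; ties broken deterministically by feature id."""
    s = scores.astype(float)
    if not np.all(np.isfinite(s.to_numpy())):
        raise ValueError("scores must be finite")
    order = sorted(s.index, key=lambda i: (-s[i], str(i)))
    return s.loc[order]


def enrichment_score(ranked: pd.Series, gene_set, weight: float = 1.0) -> tuple[float, list[str]]:
    """Weighted-KS enrichment score of ``gene_set`` in a descending-ranked vector.

    Hits increment the running sum by |score|^weight / sum over hits; misses
    decrement by 1/(N - n_set). ES is the extremum of largest magnitude
    (positive extremum wins ties); leading edge is the hits up to (ES > 0) or
    from (ES < 0) the extremum.
    """
    hit = ranked.index.isin(set(gene_set))
    n, nh = len(ranked), int(hit.sum())
    if nh == 0 or nh == n:
        raise ValueError("gene set intersection is empty or spans all features")
    w = np.abs(ranked.to_numpy()) ** weight
    hit_w = np.where(hit, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all hit scores exactly zero: fall back to unweighted hits
        hit_w = hit.astype(float)
        denom = hit_w.sum()
    running = np.cumsum(hit_w / denom - (~hit) / (n - nh))
    i_max, i_min = int(np.argmax(running)), int(np.argmin(running))
    if running[i_max] >= -running[i_min]:
        es = float(running[i_max])
        leading = list(ranked.index[: i_max + 1][hit[: i_max + 1]])
    else:
        es = float(running[i_min])
        leading = list(ranked.index[i_min:][hit[i_min:]])
    return es, leading


def gsea_preranked(
    scores: pd.Series,
    sets: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int | None = None,
    min_size: int = 5,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Preranked GSEA over a feature -> score map.

    Null distribution per set size: ``n_perm`` random same-size sets drawn from
    the ranked features. p is one-sided among null ES of the matching sign,
    ``(1 + #{|null| >= |ES|, same sign}) / (1 + #{same sign})``; NES is
    ES / mean(|null ES| of the same sign). BH across scored sets.
    """
    ranked = _rank_scores(scores)
    rng = np.random.default_rng(seed)
    n = len(ranked)
    features = np.array(ranked.index)

    null_cache: dict[int, np.ndarray] = {}

    def null_es(size: int) -> np.ndarray:
        if size not in null_cache:
            es = np.empty(n_perm)
            for b in range(n_perm):
                idx = rng.choice(n, size=size, replace=False)
                es[b], _ = enrichment_score(ranked, features[idx], weight=weight)
            null_cache[size] = es
        return null_cache[size]

    rows = []
    for name, ids in sets.items():
        size = int(ranked.index.isin(set(ids)).sum())
        if size < min_size or size >= n:
            logger.info("gsea_preranked: set %r skipped (effective size %d)", name, size)
            continue
        es, leading = enrichment_score(ranked, ids, weight=weight)
        null = null_es(size)
        same = null >= 0 if es >= 0 else null < 0
        k = int(np.sum(np.abs(null[same]) >= abs(es)))
        p = (1 + k) / (1 + int(same.sum()))
        scale = np.abs(null[same]).mean() if same.any() else np.nan
        nes = es / scale if scale and np.isfinite(scale) and scale > 0 else np.nan
        rows.append(
            {"set": name, "size": size, "es": es, "nes": nes, "p": p,
             "leading_edge": ",".join(map(str, leading))}
        )
    result = pd.DataFrame(rows, columns=["set", "size", "es", "nes", "p", "leading_edge"])
    result["fdr"] = bh_adjust(result["p"].to_numpy()) if len(result) else pd.Series(dtype=float)
    return result.set_index("set")


def hypergeom_overlap(query, sets: dict[str, list[str]], universe) -> pd.DataFrame:
    """One-sided upper-tail hypergeometric overlap of ``query`` against each set.

    Odds ratio from the 2x2 table with Haldane's 0.5 correction when a zero
    cell occurs. Sets with empty intersection with the universe are skipped.
    """
    universe = set(universe)
    query = set(query)
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    N, m = len(universe), len(query)
    rows = []
    for name, ids in sets.items():
        s = set(ids) & universe
        if not s:
            logger.info("hypergeom_overlap: set %r has no overlap with universe; skipped", name)
            continue
        K = len(s)
        k = len(query & s)
        p = float(stats.hypergeom.sf(k - 1, N, K, m))
        a, b = k, m - k
        c, d = K - k, N - m - (K - k)
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        rows.append({"set": name, "overlap": k, "set_size": K, "query_size": m,
                     "universe_size": N, "odds_ratio": (a * d) / (b * c), "p": p})
    result = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "query_size",
                                         "universe_size", "odds_ratio", "p"])
    result["fdr"] = bh_adjust(result["p"].to_numpy()) if len(result) else pd.Series(dtype=float)
    return result.set_index("set")


def decile_trajectories(scores: pd.Series, stage_matrix: pd.DataFrame) -> pd.DataFrame:
    """Median and mean stage profiles of score deciles.

    Decile 1 holds the most positive scores, decile 10 the most negative
    (rank order, ties broken by feature id). Features missing from either
    input are dropped with a logged count. Returns a tidy frame with columns
    ``decile, stage, median, mean, n_features``.
    """
    shared = scores.index.intersection(stage_matrix.index)
    dropped = len(scores) - len(shared)
    if dropped:
        logger.info("decile_trajectories: dropped %d features absent from the stage matrix", dropped)
    if len(shared) < 10:
        raise ValueError("need at least 10 shared features to form deciles")
    ranked = _rank_scores(scores.loc[shared])
    n = len(ranked)
    decile = np.minimum(np.arange(n) * 10 // n, 9) + 1
    mat = stage_matrix.loc[ranked.index]
    rows = []
    for d in range(1, 11):
        sub = mat.iloc[decile == d]
        for stage in mat.columns:
            rows.append({"decile": d, "stage": stage, "median": float(sub[stage].median()),
                         "mean": float(sub[stage].mean()), "n_features": len(sub)})
    return pd.DataFrame(rows)
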