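"""Count filtering, normalization, residualization, and PC-covariate screening.

All functions operate on features x samples DataFrames (the file convention of
bulk RNA-seq count tables) and record the transforms applied in
``df.attrs["provenance"]``.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .enrichment import bh_adjust

__all__ = [
    "filter_min_counts",
    "feature_stats",
    "filter_by_cv",
    "size_factors",
    "normalize_transform",
    "residualize",
    "pc_covariate_screen",
]

logger = logging.getLogger(__name__)


def _provenance(df: pd.DataFrame) -> list[str]:
    return list(df.attrs.get("provenance", []))


def _with_provenance(df: pd.DataFrame, parent: pd.DataFrame, step: str) -> pd.DataFrame:
    df.attrs["provenance"] = _provenance(parent) + [step]
    return df


def filter_min_counts(
    counts: pd.DataFrame, min_count: int = 10, min_fraction: float = 0.8
) -> pd.DataFrame:
    """Keep features with >= ``min_count`` counts in >= ``min_fraction`` of samples.

    The sample threshold is ``ceil(min_fraction * n_samples)``, so a feature
    passing in exactly 80% of samples is retained. Feature order is preserved.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must lie in (0, 1]")
    n_needed = math.ceil(min_fraction * counts.shape[1])
    keep = (counts >= min_count).sum(axis=1) >= n_needed
    if not keep.any():
        warnings.warn("filter_min_counts removed every feature", stacklevel=2)
    out = counts.loc[keep].copy()
    return _with_provenance(out, counts, f"filter_min_counts(min_count={min_count}, min_fraction={min_fraction})")


def feature_stats(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-feature mean, variance, sd and coefficient of variation (sd/mean).

    CV is NaN-flagged (``zero_mean=True``) where the mean is zero.
    """
    mean = matrix.mean(axis=1)
    var = matrix.var(axis=1, ddof=1)
    sd = np.sqrt(var)
    zero_mean = mean == 0
    cv = sd / mean.where(~zero_mean)
    return pd.DataFrame({"mean": mean, "variance": var, "sd": sd, "cv": cv, "zero_mean": zero_mean})


def filter_by_cv(matrix: pd.DataFrame, cv_cutoff: float) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop low-variation features: those with CV = sd/mean below ``cv_cutoff``.

    Zero-mean features have undefined CV and are removed with a logged reason.
    Returns the filtered matrix and the stats table for *all* input features.
    """
    if cv_cutoff < 0:
        raise ValueError("cv_cutoff must be >= 0")
    st = feature_stats(matrix)
    if st["zero_mean"].any():
        logger.warning(
            "filter_by_cv: removing %d zero-mean features (CV undefined)",
            int(st["zero_mean"].sum()),
        )
    keep = (st["cv"] >= cv_cutoff) & ~st["zero_mean"]
    out = matrix.loc[keep].copy()
    out = _with_provenance(out, matrix, f"filter_by_cv(cv_cutoff={cv_cutoff})")
    return out, st


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference).

    The reference is the per-feature geometric mean over features with strictly
    positive counts in every sample; each sample's factor is the median ratio
    of its counts to the reference. Falls back to library-size ratios
    (normalized to geometric mean 1) when no feature is all-positive.
    """
    values = counts.to_numpy(dtype=float)
    all_pos = (values > 0).all(axis=1)
    if all_pos.any():
        logref = np.log(values[all_pos]).mean(axis=1)
        sf = np.exp(np.median(np.log(values[all_pos]) - logref[:, None], axis=0))
    else:
        logger.warning("size_factors: no all-positive feature; using library-size ratios")
        lib = values.sum(axis=0)
        sf = lib / np.exp(np.mean(np.log(lib)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize_transform(counts: pd.DataFrame) -> pd.DataFrame:
    """Size-factor normalization followed by log2(x + 1).

    A variance-stabilizing stand-in: median-of-ratios factors absorb depth
    differences; the shifted log tames the count-variance/mean relationship.
    """
    if counts.shape[1] < 2:
        raise ValueError("normalize_transform needs at least 2 samples")
    sf = size_factors(counts)
    out = np.log2(counts / sf + 1.0)
    return _with_provenance(out, counts, "normalize_transform(log2 median-of-ratios)")


def _design_with_intercept(covariates: pd.DataFrame) -> np.ndarray:
    C = np.asarray(covariates, dtype=float)
    return np.column_stack([np.ones(C.shape[0]), C])


def _check_full_rank(D: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        # name the collinear columns via pivoted QR
        _, _, piv = linalg.qr(D, pivoting=True, mode="economic")
        dropped = sorted(piv[rank:])
        cols = ["intercept"] + names
        bad = [cols[j] for j in dropped]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def residualize(expr: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """OLS residuals of each feature on [intercept, covariates].

    ``covariates`` rows must align with the samples (columns of ``expr``).
    Residual means are zero; regressing the same design twice is a no-op.
    """
    if list(covariates.index) != list(expr.columns):
        covariates = covariates.loc[expr.columns]
    D = _design_with_intercept(covariates)
    _check_full_rank(D, list(covariates.columns))
    E = expr.to_numpy(dtype=float).T  # samples x features
    beta, *_ = np.linalg.lstsq(D, E, rcond=None)
    resid = E - D @ beta
    out = pd.DataFrame(resid.T, index=expr.index, columns=expr.columns)
    return _with_provenance(out, expr, f"residualize({list(covariates.columns)})")


def pc_covariate_screen(
    expr: pd.DataFrame,
    covariates: pd.DataFrame,
    var_threshold: float = 0.02,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Screen covariates against major expression principal components.

    Feature-standardized expression is decomposed into sample-space PCs;
    covariates whose Pearson correlation with any PC explaining more than
    ``var_threshold`` of total variance survives BH at ``fdr`` are flagged.
    Returns the per-(PC, covariate) report with columns
    ``pc, variance_explained, covariate, r, p, fdr, flagged``.
    """
    if expr.shape[1] < 3:
        raise ValueError("pc_covariate_screen needs at least 3 samples")
    if list(covariates.index) != list(expr.columns):
        covariates = covariates.loc[expr.columns]
    X = expr.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=1)
    ok = sd > 0
    Xs = (X[ok] - X[ok].mean(axis=1, keepdims=True)) / sd[ok][:, None]
    # sample-space PCs of the feature-standardized matrix (rows already centered)
    _, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    share = s**2 / np.sum(s**2)
    big = np.nonzero(share > var_threshold)[0]

    rows = []
    n = expr.shape[1]
    for name in covariates.columns:
        c = covariates[name].to_numpy(dtype=float)
        if np.std(c) == 0:
            warnings.warn(f"pc_covariate_screen: covariate {name!r} is constant; skipped", stacklevel=2)
            continue
        for j in big:
            r, p = stats.pearsonr(Vt[j], c)
            rows.append({"pc": j + 1, "variance_explained": share[j], "covariate": name, "r": r, "p": p})
    report = pd.DataFrame(rows, columns=["pc", "variance_explained", "covariate", "r", "p"])
    if len(report):
        report["fdr"] = bh_adjust(report["p"].to_numpy())
        report["flagged"] = report["fdr"] < fdr
    else:
        report["fdr"] = pd.Series(dtype=float)
        report["flagged"] = pd.Series(dtype=bool)
    return report
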