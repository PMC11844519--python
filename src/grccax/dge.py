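"""Per-feature differential-expression arm (linear model on processed expression).

Each feature is regressed on an intercept, three diagnosis indicators
(SCZ/BD/MDD versus the control baseline) and the numeric MCA covariates; the
SCZ coefficient, its t statistic, two-sided p and BH FDR are the primary
output, with the BD and MDD contrasts carried along. Fits are vectorized
across features (one least-squares solve for the whole matrix).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_adjust
from .preprocess import _check_full_rank

__all__ = ["fit_dge", "compare_to_grcca", "diagnosis_indicators"]


def diagnosis_indicators(
    diagnosis: pd.Series, baseline: str = "Control", levels=("SCZ", "BD", "MDD")
) -> pd.DataFrame:
    """0/1 indicator columns for each non-baseline diagnosis level."""
    if not set(diagnosis) <= {baseline, *levels}:
        raise ValueError(f"unexpected diagnosis labels: {sorted(set(diagnosis) - {baseline, *levels})}")
    return pd.DataFrame(
        {lvl: (diagnosis == lvl).astype(float) for lvl in levels}, index=diagnosis.index
    )


def fit_dge(
    expr: pd.DataFrame,
    sample_table: pd.DataFrame,
    mca_dims: pd.DataFrame | None = None,
    contrast: str = "SCZ",
) -> pd.DataFrame:
    """OLS differential expression per feature.

    ``expr`` is features x samples; ``sample_table`` must carry a
    ``diagnosis`` column aligned to the samples; ``mca_dims`` (samples x dims)
    enters as numeric covariates. Returns a per-feature frame with ``effect``
    (the ``contrast`` coefficient on the expression scale), ``t``, ``p``,
    ``fdr`` plus ``effect_<g>``/``t_<g>`` for the other contrasts.
    """
    if "diagnosis" not in sample_table.columns:
        raise ValueError("sample_table must contain a 'diagnosis' column")
    samples = list(expr.columns)
    diag = sample_table.loc[samples, "diagnosis"]
    ind = diagnosis_indicators(diag)
    parts = [ind]
    if mca_dims is not None and mca_dims.shape[1] > 0:
        parts.append(mca_dims.loc[samples].astype(float))
    C = pd.concat(parts, axis=1)
    D = np.column_stack([np.ones(len(samples)), C.to_numpy(dtype=float)])
    _check_full_rank(D, list(C.columns))
    names = ["intercept", *C.columns]

    E = expr.to_numpy(dtype=float).T  # samples x features
    n, q = D.shape
    beta, *_ = np.linalg.lstsq(D, E, rcond=None)
    resid = E - D @ beta
    df_resid = n - q
    sigma2 = (resid**2).sum(axis=0) / df_resid
    XtX_inv = np.linalg.inv(D.T @ D)

    def contrast_stats(name: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        j = names.index(name)
        b = beta[j]
        se = np.sqrt(sigma2 * XtX_inv[j, j])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = b / se
        p = 2.0 * stats.t.sf(np.abs(t), df=df_resid)
        return b, t, p

    b, t, p = contrast_stats(contrast)
    out = pd.DataFrame({"effect": b, "t": t, "p": p, "fdr": bh_adjust(p)}, index=expr.index)
    for other in ("SCZ", "BD", "MDD"):
        if other == contrast:
            continue
        ob, ot, op = contrast_stats(other)
        out[f"effect_{other}"] = ob
        out[f"t_{other}"] = ot
        out[f"p_{other}"] = op
    out.index.name = "feature_id"
    return out


def compare_to_grcca(dge: pd.DataFrame, x_structure: pd.DataFrame) -> tuple[float, float, pd.DataFrame]:
    """Pearson correlation of DGE t statistics with GRCCA structure correlations.

    Returns ``(r, p, joined)`` over the shared features.
    """
    shared = dge.index.intersection(x_structure.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared features")
    joined = pd.DataFrame({"t": dge.loc[shared, "t"], "r_x": x_structure.loc[shared, "r"]})
    r, p = stats.pearsonr(joined["t"], joined["r_x"])
    return float(r), float(p), joined
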