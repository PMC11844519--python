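"""Weighted co-expression module detection.

A simplified WGCNA-style pipeline: soft-thresholded correlation adjacency,
topological overlap matrix (TOM), average-linkage hierarchical clustering of
1 - TOM, a static tree cut, and a minimum module size below which clusters
fall into module 0 (the "gray" module of unassigned features). The resulting
feature -> module map is the grouping vector consumed by the GRCCA stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import linregress
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = [
    "NetworkParams",
    "ModuleAssignment",
    "adjacency",
    "topological_overlap",
    "cluster_modules",
    "pick_soft_threshold",
    "module_eigengene",
    "ModuleDetector",
]


@dataclass
class NetworkParams:
    """Network construction parameters.

    Defaults are the gene-level choices used throughout this package (for
    transcript-resolution data the conventional values are beta=2,
    cut_height=0.988, min_module_size=35).
    """

    beta: float = 3.0
    signed: bool = False
    cut_height: float = 0.980
    min_module_size: int = 40

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if not 0 < self.cut_height <= 1:
            raise ValueError("cut_height must lie in (0, 1]")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")


@dataclass
class ModuleAssignment:
    """Feature -> module map; module 0 collects unassigned features."""

    labels: pd.Series  # feature_id -> module id

    @property
    def feature_ids(self) -> list:
        return list(self.labels.index)

    @property
    def module_sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    def groups(self) -> np.ndarray:
        return self.labels.to_numpy()


def _corr(expr: pd.DataFrame) -> np.ndarray:
    values = expr.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    dead = [str(f) for f, s in zip(expr.index, sd) if s == 0]
    if dead:
        raise ValueError(f"zero-variance features: {dead[:10]}{'...' if len(dead) > 10 else ''}")
    return np.corrcoef(values)


def adjacency(expr: pd.DataFrame, params: NetworkParams) -> np.ndarray:
    """Soft-thresholded adjacency over features (rows of ``expr``).

    Unsigned: ``|cor|^beta``; signed: ``((1 + cor)/2)^beta``. Diagonal 1.
    """
    C = _corr(expr)
    A = ((1.0 + C) / 2.0) ** params.beta if params.signed else np.abs(C) ** params.beta
    np.fill_diagonal(A, 1.0)
    return (A + A.T) / 2.0


def topological_overlap(A: np.ndarray) -> np.ndarray:
    """Topological overlap matrix.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_{u != i,j} a_iu a_uj and k_i = sum_{u != i} a_iu; diagonal 1.
    """
    A = np.asarray(A, dtype=float)
    if not np.allclose(A, A.T) or A.min() < 0 or A.max() > 1 + 1e-12:
        raise ValueError("adjacency must be symmetric with entries in [0, 1]")
    k = A.sum(axis=1) - np.diag(A)
    L = A @ A - A * np.diag(A)[None, :] - np.diag(A)[:, None] * A  # remove u = i and u = j
    denom = np.minimum.outer(k, k) + 1.0 - A
    np.fill_diagonal(denom, 1.0)  # diagonal overwritten below; avoid 0/0
    tom = (L + A) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip((tom + tom.T) / 2.0, 0.0, 1.0)


def cluster_modules(tom: np.ndarray, params: NetworkParams, feature_ids=None) -> ModuleAssignment:
    """Cut the average-linkage dendrogram of 1 - TOM at ``cut_height``.

    Clusters smaller than ``min_module_size`` merge into module 0; the rest
    are renumbered 1..K by decreasing size (ties broken by first occurrence).
    """
    n = tom.shape[0]
    if feature_ids is None:
        feature_ids = [f"F{i}" for i in range(n)]
    dissim = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(dissim, 0.0)
    Z = linkage(squareform(dissim, checks=False), method="average")
    flat = fcluster(Z, t=params.cut_height, criterion="distance")

    labels = np.zeros(n, dtype=int)
    sizes = pd.Series(flat).value_counts()
    kept = sizes[sizes >= params.min_module_size]
    order = sorted(kept.index, key=lambda c: (-kept[c], int(np.argmax(flat == c))))
    for new_id, old in enumerate(order, start=1):
        labels[flat == old] = new_id
    return ModuleAssignment(labels=pd.Series(labels, index=feature_ids, name="module_id"))


def pick_soft_threshold(
    expr: pd.DataFrame,
    candidate_powers=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10),
    signed: bool = False,
    r2_target: float = 0.8,
    n_bins: int = 10,
) -> tuple[float, pd.DataFrame]:
    """Scale-free-topology criterion for the soft-threshold power.

    For each candidate power, connectivity k_i is binned and the R^2 of the
    log10(freq) ~ log10(k) fit computed; the smallest power reaching
    ``r2_target`` is chosen, else the power with maximal R^2.
    """
    if expr.shape[0] < 3:
        raise ValueError("need at least 3 features")
    sd = expr.to_numpy(dtype=float).std(axis=1, ddof=1)
    if (sd == 0).any():
        warnings.warn(
            f"pick_soft_threshold: excluding {int((sd == 0).sum())} constant features", stacklevel=2
        )
        expr = expr.loc[sd > 0]
    C = _corr(expr)
    rows = []
    for beta in candidate_powers:
        A = ((1.0 + C) / 2.0) ** beta if signed else np.abs(C) ** beta
        np.fill_diagonal(A, 1.0)
        k = A.sum(axis=1) - 1.0
        k = k[k > 0]
        freq, edges = np.histogram(k, bins=max(n_bins, 10))
        centers = (edges[:-1] + edges[1:]) / 2.0
        ok = (freq > 0) & (centers > 0)
        if ok.sum() >= 3 and np.unique(np.log10(centers[ok])).size >= 2:
            fit = linregress(np.log10(centers[ok]), np.log10(freq[ok]))
            r2 = float(fit.rvalue**2)
            slope = float(fit.slope)
        else:  # degenerate connectivity distribution
            r2, slope = 0.0, np.nan
        rows.append({"power": beta, "r2": r2, "slope": slope,
                     "mean_k": float(k.mean()), "max_k": float(k.max())})
    table = pd.DataFrame(rows)
    passing = table[table["r2"] >= r2_target]
    power = float(passing["power"].iloc[0]) if len(passing) else float(
        table.loc[table["r2"].idxmax(), "power"]
    )
    return power, table


def module_eigengene(expr: pd.DataFrame, assignment: ModuleAssignment) -> pd.DataFrame:
    """First principal component of each module's standardized expression.

    Returns a modules x samples frame. The eigengene sign is fixed so it
    correlates non-negatively with the module's mean expression profile; a
    singleton module's eigengene is the standardized feature itself.
    """
    out = {}
    for module in sorted(set(assignment.labels) - {0}):
        ids = assignment.labels.index[assignment.labels == module]
        sub = expr.loc[ids].to_numpy(dtype=float)
        mean_profile = sub.mean(axis=0)
        sd = sub.std(axis=1, ddof=1)
        if (sd == 0).any():
            raise ValueError(f"module {module} contains constant features")
        stdized = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
        if stdized.shape[0] == 1:
            eig = stdized[0]
        else:
            _, _, Vt = np.linalg.svd(stdized, full_matrices=False)
            eig = Vt[0]
        c = np.corrcoef(eig, mean_profile)[0, 1]
        if np.isfinite(c) and c < 0:
            eig = -eig
        out[module] = eig
    return pd.DataFrame(out, index=expr.columns).T.rename_axis("module_id")


class ModuleDetector(BaseEstimator, ClusterMixin):
    """End-to-end module detection estimator.

    ``fit`` expects a features x samples DataFrame (or array) and exposes
    ``labels_`` (module id per feature, 0 = unassigned), ``tom_``, and
    ``assignment_``.
    """

    def __init__(self, beta: float = 3.0, signed: bool = False,
                 cut_height: float = 0.980, min_module_size: int = 40):
        self.beta = beta
        self.signed = signed
        self.cut_height = cut_height
        self.min_module_size = min_module_size

    def _params(self) -> NetworkParams:
        return NetworkParams(beta=self.beta, signed=self.signed,
                             cut_height=self.cut_height, min_module_size=self.min_module_size)

    def fit(self, X, y=None):
        expr = pd.DataFrame(X)
        params = self._params()
        A = adjacency(expr, params)
        self.tom_ = topological_overlap(A)
        self.assignment_ = cluster_modules(self.tom_, params, feature_ids=list(expr.index))
        self.labels_ = self.assignment_.labels.to_numpy()
        return self
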