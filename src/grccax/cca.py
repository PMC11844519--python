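"""Group-regularized canonical correlation analysis (GRCCA).

The model links a wide expression matrix X (samples x features) to a narrow
covariate matrix Y (samples x covariates; diagnosis indicators plus numeric
covariates such as MCA dimensions) through a single canonical pair
(LV_x = X w_x, LV_y = Y w_y) maximizing cov(LV_x, LV_y) subject to

    w_x' R w_x = 1,   w_y' C_yy w_y = 1,

where R = lambda (I - B) + mu B and B is the block-averaging projector over
feature groups (co-expression modules; module 0 is a group of its own). With
lambda = 1 - 1/p close to 1 and mu small, within-group deviations of w_x are
shrunk hard while group mean weights move cheaply: coordinated, distributed
group effects are rewarded. Because I - B and B are orthogonal projections,
R^{-1/2} = lambda^{-1/2}(I - B) + mu^{-1/2} B in closed form, and the problem
reduces to an SVD in the transformed space X R^{-1/2}.

Model capacity is controlled by the fraction f of X-variance retained (PCA of
the transformed X); f is selected by permutation testing over a grid.
Inference: permutation p for the model, bootstrap Z-scores for weight
stability, and structure correlations r = cor(column, LV) with t-based p and
BH FDR for feature interpretation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.base import BaseEstimator

from .enrichment import bh_adjust

__all__ = [
    "GroupMetric",
    "build_group_metric",
    "GRCCA",
    "PermutationResult",
    "fit_grcca",
    "permutation_test",
    "optimize_variance_fraction",
    "bootstrap_z",
    "structure_correlations",
    "significant_features",
]

Z_CAP = 1e6  # sentinel for zero bootstrap sd


# ---------------------------------------------------------------------------
# group metric


class GroupMetric:
    """The quadratic penalty metric R = lambda (I - B) + mu B.

    ``B`` is the block-averaging operator of the grouping vector:
    (B w)_i = mean of w over the group containing feature i. Both B and I - B
    are orthogonal projections, so any analytic function of R acts as
    g(lambda) on deviations from group means and g(mu) on the means.
    """

    def __init__(self, groups, lam: float, mu: float):
        groups = np.asarray(groups)
        if groups.ndim != 1 or len(groups) == 0:
            raise ValueError("groups must be a non-empty 1-d array")
        if lam <= 0 or mu <= 0:
            raise ValueError("lambda and mu must be positive")
        self.lam = float(lam)
        self.mu = float(mu)
        uniq, self.index = np.unique(groups, return_inverse=True)
        self.n_groups = len(uniq)
        self.group_sizes = np.bincount(self.index).astype(float)
        self.p = len(groups)

    def block_average(self, W: np.ndarray) -> np.ndarray:
        """Apply B along the last axis of a (... , p) array."""
        W = np.asarray(W, dtype=float)
        sums = np.zeros(W.shape[:-1] + (self.n_groups,))
        np.add.at(sums.reshape(-1, self.n_groups).T, self.index, W.reshape(-1, self.p).T)
        means = sums / self.group_sizes
        return means[..., self.index]

    def _combine(self, a: float, b: float, W: np.ndarray) -> np.ndarray:
        BW = self.block_average(W)
        return a * (W - BW) + b * BW

    def apply(self, W: np.ndarray) -> np.ndarray:
        """R acting on the last axis."""
        return self._combine(self.lam, self.mu, W)

    def apply_inv_sqrt(self, W: np.ndarray) -> np.ndarray:
        """R^{-1/2} acting on the last axis (closed form via projections)."""
        return self._combine(self.lam ** -0.5, self.mu ** -0.5, W)

    def apply_sqrt(self, W: np.ndarray) -> np.ndarray:
        return self._combine(self.lam ** 0.5, self.mu ** 0.5, W)

    def quadratic_form(self, w: np.ndarray) -> float:
        return float(w @ self.apply(w))

    def dense(self) -> np.ndarray:
        """Materialize R as a p x p matrix (tests / small problems only)."""
        return self.apply(np.eye(self.p))


def build_group_metric(groups, lam: float, mu: float) -> GroupMetric:
    """Construct the group penalty metric; see :class:`GroupMetric`."""
    return GroupMetric(groups, lam, mu)


# ---------------------------------------------------------------------------
# helpers


def _standardize(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    return mean, sd


def _corr_with_vector(M: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Pearson correlation of each column of M with v (NaN for constant columns)."""
    Mc = M - M.mean(axis=0)
    vc = v - v.mean()
    denom = np.sqrt((Mc**2).sum(axis=0) * (vc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return (Mc.T @ vc) / denom


def _corr_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p of a Pearson correlation from the t distribution, n-2 df."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def _inv_sqrt_psd(M: np.ndarray, rcond: float = 1e-10) -> np.ndarray:
    vals, vecs = linalg.eigh(M)
    if vals[-1] <= 0:
        raise ValueError("matrix is not positive definite")
    if vals[0] < rcond * vals[-1]:
        raise ValueError("Y covariance is rank deficient; drop collinear covariates")
    return (vecs / np.sqrt(vals)) @ vecs.T


@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    p: float


# ---------------------------------------------------------------------------
# estimator


class GRCCA(BaseEstimator):
    """Group-regularized CCA estimator (first canonical pair).

    Parameters
    ----------
    groups : array-like of shape (p,) or None
        Feature grouping vector (module ids; 0 is a valid group). ``None``
        means every feature is its own group (plain ridge-metric CCA).
    mu : float
        Group-level penalty (shrinkage of group mean weights).
    lam : float or None
        Feature-level penalty; ``None`` uses the 1 - 1/p rule.
    variance_fraction : float
        Fraction f of transformed-X variance retained: the smallest leading
        set of principal components with cumulative variance share >= f.
    standardize : bool
        Column-standardize X and Y before fitting (recommended).

    Attributes (after ``fit``)
    --------------------------
    x_weights_, y_weights_ : canonical weight vectors (original feature space)
    x_scores_, y_scores_ : LV_x = X w_x and LV_y = Y w_y
    latent_correlation_ : Pearson correlation of the two latent variables
    x_structure_, y_structure_ : DataFrames with r, p, fdr per column
    n_components_ : number of PCs retained at ``variance_fraction``
    """

    def __init__(self, groups=None, mu: float = 0.1, lam: float | None = None,
                 variance_fraction: float = 1.0, standardize: bool = True):
        self.groups = groups
        self.mu = mu
        self.lam = lam
        self.variance_fraction = variance_fraction
        self.standardize = standardize

    # -- internals ---------------------------------------------------------

    def _validate(self, X, Y) -> tuple[np.ndarray, np.ndarray, list, list]:
        x_names = list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{j}" for j in range(np.shape(X)[1])]
        y_names = list(Y.columns) if isinstance(Y, pd.DataFrame) else [f"y{j}" for j in range(np.shape(Y)[1])]
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must be 2-d with aligned rows")
        if not (0 < self.variance_fraction <= 1):
            raise ValueError("variance_fraction must lie in (0, 1]")
        return X, Y, x_names, y_names

    def _prepare(self, X: np.ndarray, Y: np.ndarray):
        """Standardize, transform by R^{-1/2}, PCA X-side, whiten Y-side."""
        p = X.shape[1]
        lam = (1.0 - 1.0 / p) if self.lam is None else float(self.lam)
        groups = np.arange(p) if self.groups is None else np.asarray(self.groups)
        if len(groups) != p:
            raise ValueError("groups length must equal the number of X columns")
        metric = GroupMetric(groups, lam, self.mu)

        if self.standardize:
            xm, xs = _standardize(X)
            ym, ys = _standardize(Y)
            if (xs == 0).any():
                raise ValueError("X has constant columns; remove them before fitting")
            if (ys == 0).any():
                raise ValueError("Y has constant columns; remove them before fitting")
            X = (X - xm) / xs
            Y = (Y - ym) / ys
        else:
            X = X - X.mean(axis=0)
            Y = Y - Y.mean(axis=0)

        Xt = metric.apply_inv_sqrt(X)
        U, s, Vt = np.linalg.svd(Xt, full_matrices=False)
        keep = s > 1e-12 * s[0] if s.size and s[0] > 0 else np.zeros(0, dtype=bool)
        U, s, Vt = U[:, keep], s[keep], Vt[keep]
        shares = s**2 / np.sum(s**2)
        n = X.shape[0]
        Cyy = (Y.T @ Y) / (n - 1)
        Wy = _inv_sqrt_psd(Cyy)
        return dict(X=X, Y=Y, metric=metric, U=U, s=s, Vt=Vt, shares=shares, Wy=Wy, n=n)

    @staticmethod
    def _n_components(shares: np.ndarray, f: float) -> int:
        cum = np.cumsum(shares)
        k = int(np.searchsorted(cum, f - 1e-12) + 1)
        k = min(k, len(shares))
        if k == 0:
            raise ValueError("variance_fraction retains zero components")
        return k

    @staticmethod
    def _solve(cache: dict, Y: np.ndarray, k: int):
        """First canonical pair between the k leading scores and Y.

        Returns (a, w_y, latent_correlation) with a in score space. The X-side
        constraint is the identity in the R^{-1/2}-transformed coordinates
        (i.e. w_x' R w_x = 1) and the Y side is whitened by C_yy.
        """
        T = cache["U"][:, :k] * cache["s"][:k]
        n = cache["n"]
        M = (T.T @ Y) / (n - 1) @ cache["Wy"]
        u, sv, vt = np.linalg.svd(M, full_matrices=False)
        a = u[:, 0]
        wy = cache["Wy"] @ vt[0]
        lvx = T @ a
        lvy = Y @ wy
        denom = lvx.std() * lvy.std()
        r = float(np.corrcoef(lvx, lvy)[0, 1]) if denom > 0 else 0.0
        return a, wy, r

    # -- API ---------------------------------------------------------------

    def fit(self, X, Y):
        X, Y, x_names, y_names = self._validate(X, Y)
        cache = self._prepare(X, Y)
        self._cache = cache
        k = self._n_components(cache["shares"], self.variance_fraction)
        a, wy, r = self._solve(cache, cache["Y"], k)

        wx = cache["metric"].apply_inv_sqrt(cache["Vt"][:k].T @ a)
        lvx = cache["X"] @ wx
        lvy = cache["Y"] @ wy

        ry = _corr_with_vector(cache["Y"], lvy)
        if ry[np.nanargmax(np.abs(ry))] < 0:  # sign convention
            wx, wy, lvx, lvy, ry = -wx, -wy, -lvx, -lvy, -ry
        rx = _corr_with_vector(cache["X"], lvx)

        n = cache["n"]
        self.n_components_ = k
        self.x_weights_ = pd.Series(wx, index=x_names, name="w_x")
        self.y_weights_ = pd.Series(wy, index=y_names, name="w_y")
        self.x_scores_ = lvx
        self.y_scores_ = lvy
        self.latent_correlation_ = float(np.corrcoef(lvx, lvy)[0, 1])
        self.x_structure_ = _structure_frame(rx, n, x_names)
        self.y_structure_ = _structure_frame(ry, n, y_names)
        self.x_names_, self.y_names_ = x_names, y_names
        return self

    def permutation_test(self, n_perm: int = 1000, seed: int | None = None) -> PermutationResult:
        """Permute Y rows and refit at the fitted variance fraction.

        p = (1 + #{null latent correlation >= observed}) / (1 + n_perm); with
        1000 permutations the smallest attainable p is therefore 1/1001,
        which prints as 0.001 at three decimals.
        """
        if not hasattr(self, "_cache"):
            raise ValueError("fit before permutation_test")
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        cache = self._cache
        k = self.n_components_
        null = np.empty(n_perm)
        n = cache["n"]
        for b in range(n_perm):
            perm = rng.permutation(n)
            _, _, null[b] = self._solve(cache, cache["Y"][perm], k)
        observed = self.latent_correlation_
        p = (1 + int(np.sum(null >= observed))) / (1 + n_perm)
        self.perm_null_ = null
        self.perm_p_ = p
        return PermutationResult(observed=observed, null=null, p=p)

    def bootstrap_z(self, X, Y, n_boot: int = 1000, seed: int | None = None,
                    max_degenerate: float = 0.10):
        """Bootstrap Z-scores of the canonical weights.

        Samples are resampled with replacement; each replicate is refit with
        the fitted hyperparameters and sign-aligned to the point estimate by
        the correlation of its LV_y with the point-estimate LV_y on the
        resampled rows. Z = weight / sd(bootstrap weights). Zero-sd weights
        get a capped sentinel (+-1e6) and a flag; degenerate replicates are
        dropped, erroring above ``max_degenerate``.
        """
        if not hasattr(self, "x_weights_"):
            raise ValueError("fit before bootstrap_z")
        X, Y, _, _ = self._validate(X, Y)
        rng = np.random.default_rng(seed)
        n = X.shape[0]
        wx_boot = np.empty((n_boot, X.shape[1]))
        wy_boot = np.empty((n_boot, Y.shape[1]))
        lvy_point = self.y_scores_
        bad = 0
        kept = 0
        for _ in range(n_boot):
            idx = rng.integers(n, size=n)
            try:
                rep = GRCCA(groups=self.groups, mu=self.mu, lam=self.lam,
                            variance_fraction=self.variance_fraction,
                            standardize=self.standardize)
                rep.fit(X[idx], Y[idx])
            except ValueError:
                bad += 1
                continue
            c = np.corrcoef(rep.y_scores_, lvy_point[idx])[0, 1]
            if not np.isfinite(c) or rep.y_scores_.std() == 0:
                bad += 1
                continue
            sgn = 1.0 if c >= 0 else -1.0
            wx_boot[kept] = sgn * rep.x_weights_.to_numpy()
            wy_boot[kept] = sgn * rep.y_weights_.to_numpy()
            kept += 1
        if bad > max_degenerate * n_boot:
            raise RuntimeError(f"{bad}/{n_boot} degenerate bootstrap replicates")

        def z_of(point: np.ndarray, boots: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            sd = boots[:kept].std(axis=0, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                z = point / sd
            # numerically-zero sd (weight constant across bootstraps): cap with flag
            flag = ~(np.abs(z) < Z_CAP)
            z[flag] = np.sign(point[flag]) * Z_CAP
            return z, flag

        zx, fx = z_of(self.x_weights_.to_numpy(), wx_boot)
        zy, fy = z_of(self.y_weights_.to_numpy(), wy_boot)
        self.z_x_ = pd.Series(zx, index=self.x_names_, name="Z")
        self.z_y_ = pd.Series(zy, index=self.y_names_, name="Z")
        self.z_x_capped_ = pd.Series(fx, index=self.x_names_)
        self.z_y_capped_ = pd.Series(fy, index=self.y_names_)
        self.n_degenerate_boot_ = bad
        return self.z_x_, self.z_y_


def _structure_frame(r: np.ndarray, n: int, names) -> pd.DataFrame:
    p = _corr_p(r, n)
    return pd.DataFrame({"r": r, "p": p, "fdr": bh_adjust(p)}, index=names)


# ---------------------------------------------------------------------------
# functional wrappers


def fit_grcca(X, Y, groups=None, mu: float = 0.1, lam: float | None = None,
              variance_fraction: float = 1.0) -> GRCCA:
    """Fit a :class:`GRCCA` model (first canonical pair) and return it."""
    return GRCCA(groups=groups, mu=mu, lam=lam,
                 variance_fraction=variance_fraction).fit(X, Y)


def permutation_test(model: GRCCA, n_perm: int = 1000, seed: int | None = None) -> PermutationResult:
    return model.permutation_test(n_perm=n_perm, seed=seed)


def optimize_variance_fraction(
    X, Y, groups=None, mu: float = 0.1, lam: float | None = None,
    grid=tuple(np.round(np.arange(0.1, 1.01, 0.1), 1)),
    n_perm: int = 1000, seed: int | None = None,
) -> tuple[GRCCA, pd.DataFrame]:
    """Grid-search the retained variance fraction by permutation p.

    The chosen f minimizes the permutation p; ties break by larger observed
    latent correlation, then by smaller f. Returns the refit model at the
    chosen f (with ``perm_p_`` and ``chosen_f_`` set) and the per-f table.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("grid must be non-empty")
    rng = np.random.default_rng(seed)
    rows = []
    fits: dict[float, GRCCA] = {}
    for f in grid:
        model = GRCCA(groups=groups, mu=mu, lam=lam, variance_fraction=f)
        model.fit(X, Y)
        res = model.permutation_test(n_perm=n_perm, seed=int(rng.integers(2**31 - 1)))
        fits[f] = model
        rows.append({"f": f, "n_components": model.n_components_,
                     "latent_correlation": model.latent_correlation_, "perm_p": res.p})
    table = pd.DataFrame(rows)
    best = table.sort_values(
        by=["perm_p", "latent_correlation", "f"], ascending=[True, False, True]
    ).iloc[0]
    chosen = fits[best["f"]]
    chosen.chosen_f_ = float(best["f"])
    return chosen, table


def bootstrap_z(model: GRCCA, X, Y, n_boot: int = 1000, seed: int | None = None):
    return model.bootstrap_z(X, Y, n_boot=n_boot, seed=seed)


def structure_correlations(M, lv: np.ndarray, names=None) -> pd.DataFrame:
    """Correlation of each column of M with a latent variable, with p and FDR."""
    if names is None:
        names = list(M.columns) if isinstance(M, pd.DataFrame) else None
    M = np.asarray(M, dtype=float)
    r = _corr_with_vector(M, np.asarray(lv, dtype=float))
    if np.isnan(r).any():
        warnings.warn("structure_correlations: constant columns give undefined r", stacklevel=2)
    return _structure_frame(r, M.shape[0], names if names is not None else range(M.shape[1]))


def significant_features(model: GRCCA, z_thresh: float = 2.0, fdr: float = 0.05) -> pd.DataFrame:
    """Features passing BOTH |Z| >= z_thresh (inclusive) and r_x FDR < fdr (strict).

    Sorted by |r_x| descending.
    """
    if not hasattr(model, "z_x_"):
        raise ValueError("bootstrap_z before significant_features")
    out = model.x_structure_.copy()
    out["Z"] = model.z_x_
    out["significant"] = (out["Z"].abs() >= z_thresh) & (out["fdr"] < fdr)
    out = out[out["significant"]]
    return out.reindex(out["r"].abs().sort_values(ascending=False).index)
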