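"""Multiple correspondence analysis of categorical exposure tables.

Indicator-matrix correspondence analysis: the samples x variables table is
expanded into a 0/1 indicator matrix over category levels, and the SVD of the
standardized residual matrix yields sample coordinates and category loadings.
Used to compress the ternary toxicology table (present/absent/unknown, with
unknown folded into absent) into a few numeric covariates.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["MCA", "impute_unknown", "mca", "select_dimensions"]


def impute_unknown(table: pd.DataFrame, unknown: str = "unknown", absent: str = "absent") -> pd.DataFrame:
    """Replace every ``unknown`` entry with ``absent``; everything else unchanged."""
    return table.replace(unknown, absent) if (table == unknown).any().any() else table.copy()


class MCA(BaseEstimator, TransformerMixin):
    """Multiple correspondence analysis via indicator-matrix CA.

    Parameters
    ----------
    n_components : int or None
        Number of dimensions to retain; ``None`` keeps all non-trivial ones.

    Attributes (after ``fit``)
    --------------------------
    sample_coordinates_ : DataFrame, samples x dims (principal coordinates)
    loadings_ : DataFrame, category levels x dims
    eigenvalues_ : ndarray, squared singular values per dim
    explained_inertia_ : ndarray, eigenvalue / total inertia
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X: pd.DataFrame, y=None):
        self.fit_transform(X)
        return self

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        table = pd.DataFrame(X)
        if table.isna().any().any():
            raise ValueError("categorical table contains missing values")
        constant = [c for c in table.columns if table[c].nunique() < 2]
        if constant:
            warnings.warn(f"MCA: dropping constant variables {constant}", stacklevel=2)
            table = table.drop(columns=constant)
        if table.shape[1] == 0:
            raise ValueError("no non-constant variables left for MCA")

        Z = pd.get_dummies(table.astype(str), prefix_sep="=").astype(float)
        total = Z.to_numpy().sum()
        P = Z.to_numpy() / total
        r = P.sum(axis=1)
        c = P.sum(axis=0)
        S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        U, s, Vt = np.linalg.svd(S, full_matrices=False)

        keep = s > 1e-12
        U, s, Vt = U[:, keep], s[keep], Vt[keep]
        if self.n_components is not None:
            U, s, Vt = U[:, : self.n_components], s[: self.n_components], Vt[: self.n_components]

        rows = (U * s) / np.sqrt(r)[:, None]
        cols = (Vt.T * s) / np.sqrt(c)[:, None]
        # fix SVD sign indeterminacy: largest-|loading| category positive per dim
        for j in range(cols.shape[1]):
            if cols[np.argmax(np.abs(cols[:, j])), j] < 0:
                cols[:, j] *= -1
                rows[:, j] *= -1

        dims = [f"dim{j + 1}" for j in range(rows.shape[1])]
        self.row_masses_ = pd.Series(r, index=table.index)
        self.sample_coordinates_ = pd.DataFrame(rows, index=table.index, columns=dims)
        self.loadings_ = pd.DataFrame(cols, index=Z.columns, columns=dims)
        self.singular_values_ = s
        self.eigenvalues_ = s**2
        self.total_inertia_ = float(np.sum(S**2))
        self.explained_inertia_ = self.eigenvalues_ / self.total_inertia_
        return self.sample_coordinates_

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        # fixed-dataset method: transform is only defined for the fitted table
        if not hasattr(self, "sample_coordinates_"):
            raise ValueError("MCA instance is not fitted")
        return self.sample_coordinates_


def select_dimensions(
    explained_inertia, min_var: float = 0.05, cum_var: float = 0.75
) -> list[int]:
    """Smallest leading set of dims each explaining > ``min_var`` of inertia
    and jointly more than ``cum_var``.

    The individual rule wins on conflict: the selection never includes a
    dimension at or below ``min_var``, and a warning reports any cumulative
    shortfall. Returns 1-based dimension numbers.
    """
    shares = np.asarray(explained_inertia, dtype=float)
    selected: list[int] = []
    cum = 0.0
    for j, share in enumerate(shares):
        if share <= min_var:
            break
        selected.append(j + 1)
        cum += share
        if cum > cum_var:
            return selected
    if not selected:
        warnings.warn(f"select_dimensions: no dimension exceeds min_var={min_var}", stacklevel=2)
    elif cum <= cum_var:
        warnings.warn(
            f"select_dimensions: individual rule exhausted at cumulative {cum:.3f} <= {cum_var}",
            stacklevel=2,
        )
    return selected


def mca(table: pd.DataFrame, n_dims: int | None = None) -> MCA:
    """Fit an :class:`MCA` on an (already imputed) categorical table."""
    model = MCA(n_components=n_dims)
    model.fit(table)
    return model
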