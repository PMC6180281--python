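"""Canonical correlation analysis with pseudo-inverse whitening.

Solved via singular-value decomposition of the whitened cross-covariance;
rank-deficient (p > n) designs are handled by truncating to numerical rank,
in which case the leading canonical correlation of a generic wide feature
matrix is exactly 1.  Structure coefficients are correlations of the
original variables with the canonical variates of their own set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CanonicalModel",
    "fit_cca",
    "structure_coefficients",
    "rank_canonical_pairs",
]


@dataclass
class CanonicalModel:
    u_weights: np.ndarray      # p x k
    v_weights: np.ndarray      # q x k
    correlations: np.ndarray   # k, descending, in [0, 1]
    x_mean: np.ndarray
    y_mean: np.ndarray
    x_structure: np.ndarray | None = None  # p x k
    y_structure: np.ndarray | None = None  # q x k

    @property
    def k(self) -> int:
        return self.correlations.size

    def x_variates(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.x_mean) @ self.u_weights

    def y_variates(self, Y: np.ndarray) -> np.ndarray:
        return (np.asarray(Y, dtype=float) - self.y_mean) @ self.v_weights


def _whiten(M: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Economy SVD basis of a centered matrix truncated at numerical rank.

    Returns (orthonormal column basis Q, weight map W with M @ W = Q, rank).
    """
    u, s, vt = np.linalg.svd(M, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        return u[:, :0], vt.T[:, :0], 0
    tol = max(M.shape) * np.finfo(float).eps * s[0]
    r = int(np.sum(s > tol))
    return u[:, :r], vt.T[:, :r] / s[:r], r


def fit_cca(X: np.ndarray, Y: np.ndarray) -> CanonicalModel:
    """Fit CCA between column-centered X (n x p) and Y (n x q)."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    n = X.shape[0]
    if n < 3:
        raise ValueError("CCA needs at least 3 samples")
    if np.all(Y.std(axis=0) == 0):
        raise ValueError("all Y columns are constant")
    const_y = np.flatnonzero(Y.std(axis=0) == 0)
    if const_y.size:
        logger.warning("dropping %d zero-variance Y columns: %s", const_y.size, const_y)

    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean

    qx, wx, rx = _whiten(Xc)
    qy, wy, ry = _whiten(Yc)
    k = min(rx, ry)
    if k == 0:
        raise ValueError("degenerate input: zero-rank matrix after centering")
    u, rho, vt = np.linalg.svd(qx.T @ qy)
    rho = np.clip(rho[:k], 0.0, 1.0)
    u_weights = wx @ u[:, :k]
    v_weights = wy @ vt.T[:, :k]
    model = CanonicalModel(
        u_weights=u_weights,
        v_weights=v_weights,
        correlations=rho,
        x_mean=x_mean,
        y_mean=y_mean,
    )
    model.x_structure, model.y_structure = structure_coefficients(model, X, Y)
    return model


def _column_corr(M: np.ndarray, variates: np.ndarray) -> np.ndarray:
    """Correlation of each column of M with each variate; NaN for constants."""
    Mc = M - M.mean(axis=0)
    Vc = variates - variates.mean(axis=0)
    m_sd = Mc.std(axis=0)
    v_sd = Vc.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Mc.T @ Vc) / M.shape[0] / np.outer(m_sd, v_sd)
    corr[m_sd == 0, :] = np.nan
    return np.clip(corr, -1.0, 1.0, out=corr, where=np.isfinite(corr))


def structure_coefficients(
    model: CanonicalModel, X: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Loadings: Pearson correlation of original columns with the canonical
    variates of their own set."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[1] != model.u_weights.shape[0] or Y.shape[1] != model.v_weights.shape[0]:
        raise ValueError("X/Y column counts do not match the fitted model")
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    return (
        _column_corr(X, model.x_variates(X)),
        _column_corr(Y, model.y_variates(Y)),
    )


def rank_canonical_pairs(
    model: CanonicalModel,
    x_names: list[str] | None = None,
    y_names: list[str] | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Rank canonical pairs by their maximum absolute X-side structure
    coefficient and emit a long-format report (pair, variable, side,
    coefficient, rank)."""
    if model.x_structure is None or model.y_structure is None:
        raise ValueError("model has no structure coefficients")
    p, k = model.x_structure.shape
    q = model.y_structure.shape[0]
    x_names = x_names if x_names is not None else [f"x{j + 1}" for j in range(p)]
    y_names = y_names if y_names is not None else [f"y{j + 1}" for j in range(q)]
    strength = np.nanmax(np.abs(model.x_structure), axis=0)
    order = np.argsort(-strength, kind="stable")
    ranks = np.empty(k, dtype=int)
    ranks[order] = np.arange(1, k + 1)
    rows = []
    for c in range(k):
        for j in range(p):
            rows.append(
                {
                    "pair": c + 1,
                    "rank": int(ranks[c]),
                    "variable": x_names[j],
                    "side": "x",
                    "coefficient": model.x_structure[j, c],
                }
            )
        for j in range(q):
            rows.append(
                {
                    "pair": c + 1,
                    "rank": int(ranks[c]),
                    "variable": y_names[j],
                    "side": "y",
                    "coefficient": model.y_structure[j, c],
                }
            )
    return ranks, pd.DataFrame(rows)
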