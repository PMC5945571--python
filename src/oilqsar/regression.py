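"""Ordinary least squares with leave-one-out cross-validation.

Q2 is computed through the hat-matrix identity e_i / (1 - h_ii), which is
algebraically exact for OLS; tests verify it against an explicit refit-n-times
oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MlrModel", "fit_ols", "loo_q2", "press_statistic"]

_COND_LIMIT = 1e10


@dataclass(frozen=True)
class MlrModel:
    """A fitted descriptor-subset linear model with validation statistics."""

    descriptors: tuple[str, ...]
    coefficients: np.ndarray = field(repr=False)
    intercept: float
    n: int
    r2: float
    q2: float
    s: float
    f: float
    contributions: dict[str, float]  # standardized weights
    raw_coefficients: dict[str, float]

    @property
    def k(self) -> int:
        return len(self.descriptors)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        arr = X[list(self.descriptors)].to_numpy(dtype=float)
        return self.intercept + arr @ self.coefficients


def _design(X: pd.DataFrame) -> np.ndarray:
    arr = X.to_numpy(dtype=float)
    return np.column_stack([np.ones(len(arr)), arr])


def fit_ols(X: pd.DataFrame, y: pd.Series) -> MlrModel:
    """Least-squares fit of y on the columns of X (plus intercept)."""
    if len(X) != len(y):
        raise ValueError("X and y disagree on sample count")
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 (n={n}, k={k})")
    if (k and X.isna().any().any()) or y.isna().any():
        raise ValueError("missing values in design or response")
    D = _design(X)
    cond = np.linalg.cond(D)
    if k and (cond > _COND_LIMIT or np.linalg.matrix_rank(D) < k + 1):
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax()
        raise ValueError(
            f"design is (near-)rank-deficient; most collinear columns: {worst}")

    yv = y.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(D, yv, rcond=None)
    resid = yv - D @ beta
    tss = float(((yv - yv.mean()) ** 2).sum())
    rss = float((resid ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    dof = n - k - 1
    s = float(np.sqrt(rss / dof))
    if k and rss > 0:
        f = float(((tss - rss) / k) / (rss / dof))
    else:
        f = 0.0 if k == 0 else float("inf")
    q2 = loo_q2(X, y)

    sd_y = float(np.std(yv, ddof=1))
    contributions = {}
    raw = {}
    for j, name in enumerate(X.columns):
        raw[name] = float(beta[j + 1])
        sd_x = float(np.std(X[name].to_numpy(dtype=float), ddof=1))
        contributions[name] = float(beta[j + 1] * sd_x / sd_y) if sd_y > 0 else 0.0

    return MlrModel(
        descriptors=tuple(X.columns),
        coefficients=beta[1:],
        intercept=float(beta[0]),
        n=n, r2=r2, q2=q2, s=s, f=f,
        contributions=contributions,
        raw_coefficients=raw,
    )


def press_statistic(X: pd.DataFrame, y: pd.Series) -> float:
    """Leave-one-out PRESS via the hat-matrix shortcut."""
    D = _design(X)
    yv = y.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(D, yv, rcond=None)
    h = np.einsum("ij,jk,ik->i", D, np.linalg.pinv(D.T @ D), D)
    if np.any(h >= 1.0 - 1e-12):
        raise ValueError("leverage of 1: an observation determines itself")
    resid = yv - D @ beta
    return float(((resid / (1.0 - h)) ** 2).sum())


def loo_q2(X: pd.DataFrame, y: pd.Series) -> float:
    """Leave-one-out cross-validated explained variance 1 - PRESS/TSS."""
    yv = y.to_numpy(dtype=float)
    tss = float(((yv - yv.mean()) ** 2).sum())
    if tss == 0:
        warnings.warn("constant response: Q2 undefined, returning 0")
        return 0.0
    return 1.0 - press_statistic(X, y) / tss
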