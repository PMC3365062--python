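"""Ordinary least squares with Gaussian AIC: the engine behind every stage.

Models are compared with AIC = n*ln(RSS/n) + 2K, where K counts the fitted
coefficients (including the intercept) plus one for the residual variance.
The additive constant n*(ln(2*pi) + 1) of the full Gaussian log-likelihood is
omitted; only AIC *differences* are used downstream, and those are invariant
to it.  The small-sample correction 2K(K+1)/(n-K-1) is available behind the
``corrected`` flag.

Exhaustive all-subsets enumeration needs ~1.3e5 fits per run, so subset fits
are solved from a single precomputed Gram system (X'X, X'y, y'y) in batches
grouped by subset size; ``fit_ols`` is the reference single-fit path with
standard errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateFitError,
    InsufficientDataError,
    SingularDesignError,
)
from .io import DesignMatrix

#: minimum Cholesky pivot of the unit-diagonal Gram block below which a
#: subset is treated as collinear (pivot^2 ~ fraction of a column's variance
#: not explained by the columns before it)
_PIVOT_TOL = 3e-7


@dataclass
class FittedModel:
    """One least-squares fit and its information-theoretic bookkeeping.

    ``delta`` (AIC above the best model of a set) and ``weight`` (Akaike
    weight) are relative to a model set and filled in by the multimodel stage.
    """

    variable_names: list[str]          # excludes the intercept
    coefficients: np.ndarray           # intercept first
    coef_se: np.ndarray
    rss: float
    n: int
    k_params: int                      # coefficients incl. intercept, +1 for sigma^2
    aic: float
    r2: float
    delta: float = math.nan
    weight: float = math.nan
    cov: np.ndarray | None = field(default=None, repr=False)


def aic_value(n: int, rss: float, n_coef: int, corrected: bool = False) -> float:
    """Gaussian AIC from the residual sum of squares.

    ``n_coef`` is the number of regression coefficients including the
    intercept; K = n_coef + 1 counts the residual variance as a parameter.
    """
    if rss <= 0.0:
        raise DegenerateFitError("RSS is zero; Gaussian AIC undefined")
    k = n_coef + 1
    out = n * math.log(rss / n) + 2.0 * k
    if corrected:
        if n <= k + 1:
            raise InsufficientDataError(
                f"AICc undefined for n={n} <= K+1={k + 1}")
        out += 2.0 * k * (k + 1) / (n - k - 1)
    return out


def aic(fit: FittedModel, corrected: bool = False) -> float:
    """AIC of a fitted model (recomputed from its stored RSS)."""
    return aic_value(fit.n, fit.rss, len(fit.coefficients), corrected)


def _collinear_columns(X: np.ndarray, columns: list[str]) -> list[str]:
    """Name columns involved in a rank deficiency via QR pivot diagnostics."""
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = X.shape[1] * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    return [columns[i] for i in np.where(diag <= tol)[0]]


def fit_ols(design: DesignMatrix, corrected: bool = False) -> FittedModel:
    """Least-squares fit with classical (unbiased residual variance) SEs."""
    X, y = design.X, design.y
    if y is None:
        raise ValueError("design carries no response")
    n, p = X.shape
    if n <= p:
        raise InsufficientDataError(f"n={n} <= p={p}: cannot fit")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        bad = _collinear_columns(X, design.columns)
        raise SingularDesignError(
            f"design is rank deficient (rank {rank} < {p}); "
            f"collinear columns: {bad or design.columns}", columns=bad)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if tss == 0.0 else min(max(1.0 - rss / tss, 0.0), 1.0)
    sigma2 = rss / (n - p)
    xtx_inv = np.linalg.inv(X.T @ X)
    cov = sigma2 * xtx_inv
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return FittedModel(
        variable_names=list(design.columns[1:]),
        coefficients=coef, coef_se=se, rss=rss, n=n, k_params=p + 1,
        aic=aic_value(n, rss, p, corrected) if rss > 0 else -math.inf,
        r2=r2, cov=cov)


# ---------------------------------------------------------------------------
# Gram-system machinery for mass subset fitting

@dataclass
class GramSystem:
    """Precomputed normal-equation blocks for a fixed full design.

    Column 0 of the underlying design is the intercept; subsets index the
    remaining term columns (0-based term indices).
    """

    columns: list[str]     # term names, excluding intercept
    G: np.ndarray          # (1+t) x (1+t) = X'X of [intercept | terms]
    b: np.ndarray          # X'y
    yty: float
    n: int
    tss: float

    @classmethod
    def from_design(cls, design: DesignMatrix) -> "GramSystem":
        X, y = design.X, design.y
        if y is None:
            raise ValueError("design carries no response")
        ybar = y.mean()
        return cls(columns=list(design.columns[1:]),
                   G=X.T @ X, b=X.T @ y, yty=float(y @ y),
                   n=X.shape[0], tss=float(np.sum((y - ybar) ** 2)))

    def rss_batch(self, subsets: np.ndarray) -> np.ndarray:
        """Residual sums of squares for many same-size subsets.

        ``subsets`` is an (m, s) integer array of 0-based term indices; the
        intercept is always included.  The normal equations are solved on a
        column-normalized (unit-diagonal) Gram block, with a batched Cholesky
        factorization guarding conditioning: subsets that are singular or
        numerically collinear yield NaN.
        """
        m = subsets.shape[0]
        idx = np.concatenate(
            [np.zeros((m, 1), dtype=np.int64), subsets.astype(np.int64) + 1],
            axis=1)
        d = np.sqrt(np.diag(self.G))
        zero_col = d <= 0.0
        d = np.where(zero_col, 1.0, d)
        ds = d[idx]
        Gs = self.G[idx[:, :, None], idx[:, None, :]] / (ds[:, :, None] * ds[:, None, :])
        bs = self.b[idx] / ds
        bad = np.any(zero_col[idx], axis=1)
        q = idx.shape[1]
        if np.any(bad):   # keep the batched factorization well defined
            Gs[bad] = np.eye(q)
        try:
            L = np.linalg.cholesky(Gs)
        except np.linalg.LinAlgError:
            L = np.empty_like(Gs)
            for i in range(m):
                try:
                    L[i] = np.linalg.cholesky(Gs[i])
                except np.linalg.LinAlgError:
                    L[i] = np.eye(q)
                    bad[i] = True
        bad |= L.diagonal(axis1=1, axis2=2).min(axis=1) < _PIVOT_TOL
        # rss = y'y - b' G^{-1} b = y'y - ||L^{-1} b||^2 via forward substitution
        y = np.empty_like(bs)
        with np.errstate(divide="ignore", invalid="ignore"):
            for i in range(q):
                acc = np.einsum("mj,mj->m", L[:, i, :i], y[:, :i]) if i else 0.0
                y[:, i] = (bs[:, i] - acc) / L[:, i, i]
        rss = self.yty - np.einsum("mj,mj->m", y, y)
        rss = np.maximum(rss, 0.0)
        rss[bad] = np.nan
        return rss

    def rss_single(self, subset: tuple[int, ...]) -> float:
        arr = np.asarray(subset, dtype=np.int64).reshape(1, -1)
        return float(self.rss_batch(arr)[0])


def aic_array(n: int, rss: np.ndarray, n_coef: np.ndarray,
              corrected: bool = False) -> np.ndarray:
    """Vectorized AIC over many fits (NaN-safe for singular subsets)."""
    rss = np.asarray(rss, float)
    k = np.asarray(n_coef, float) + 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = n * np.log(rss / n) + 2.0 * k
        if corrected:
            out = out + 2.0 * k * (k + 1.0) / (n - k - 1.0)
    out[~np.isfinite(out)] = np.nan
    return out
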