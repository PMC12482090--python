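"""Test statistics and similarity measures consumed by the experiments.

Scalar reference implementations of the two-sample Welch t-test, the overall
regression F-test, the two-matrix GFI and SRMR fit indices, and Monte Carlo
proportion summaries.  The simulation drivers use vectorized kernels for
speed; those kernels are tested against these functions, which in turn are
tested against scipy / statsmodels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .latent import DegenerateInputError

__all__ = [
    "TestResult",
    "CorrelationPair",
    "PowerEstimate",
    "welch_t_test",
    "ols_overall_f_test",
    "gfi",
    "srmr",
    "proportion_estimate",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value outside [0,1]: {self.p_value}")
        if not self.df > 0:
            raise ValueError(f"df must be positive: {self.df}")


@dataclass(frozen=True)
class CorrelationPair:
    """Reference correlation matrix A (RTN data) and comparison B (Likert data)."""

    A: np.ndarray
    B: np.ndarray

    def __post_init__(self) -> None:
        A, B = np.asarray(self.A, float), np.asarray(self.B, float)
        for name, M in (("A", A), ("B", B)):
            if M.ndim != 2 or M.shape[0] != M.shape[1]:
                raise ValueError(f"{name} must be square")
            if not np.allclose(M, M.T, atol=1e-10):
                raise ValueError(f"{name} must be symmetric")
            if not np.allclose(np.diag(M), 1.0, atol=1e-10):
                raise ValueError(f"{name} must have unit diagonal")
        if A.shape != B.shape:
            raise ValueError("A and B must be conformable")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", B)

    def gfi(self) -> float:
        return gfi(self.A, self.B)

    def srmr(self) -> float:
        return srmr(self.A, self.B)


@dataclass(frozen=True)
class PowerEstimate:
    """Monte Carlo rejection proportion with its binomial SE and 95% CI."""

    p_hat: float
    n_reps: int
    se: float
    ci_low: float
    ci_high: float


def welch_t_test(x: np.ndarray, y: np.ndarray, pooled: bool = False) -> TestResult:
    """Two-sided two-sample t-test, unequal variances by default.

    ``pooled=True`` switches to Student's equal-variance test for
    sensitivity runs.  Raises :class:`DegenerateInputError` when both groups
    have zero variance (the experiments count that as a non-rejection).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if v1 == 0.0 and v2 == 0.0:
        raise DegenerateInputError("zero variance in both groups")
    if pooled:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = float(n1 + n2 - 2)
    else:
        a, b = v1 / n1, v2 / n2
        se = math.sqrt(a + b)
        df = (a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))
    t = (x.mean() - y.mean()) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(min(p, 1.0)))


def _collapse_duplicate_columns(X: np.ndarray) -> np.ndarray:
    """Drop exactly duplicated columns (arising from rho=1 constructions)."""
    _, idx = np.unique(X.T, axis=0, return_index=True)
    return X[:, np.sort(idx)]


def ols_overall_f_test(y: np.ndarray, X: np.ndarray) -> TestResult:
    """Overall F-test of all slopes in an intercept-included linear regression.

    Exactly duplicated predictor columns are collapsed first; a design still
    rank-deficient after collapsing raises :class:`DegenerateInputError`.
    """
    y = np.asarray(y, float).ravel()
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    X = _collapse_duplicate_columns(X)
    n, q = X.shape
    if y.size != n:
        raise ValueError("y and X have incompatible shapes")
    if n <= q + 1:
        raise ValueError(f"need n > q+1 observations, got n={n}, q={q}")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    beta, _, rank, _ = np.linalg.lstsq(Xc, yc, rcond=None)
    if rank < q:
        raise DegenerateInputError("design matrix rank-deficient after collapsing")
    sst = float(yc @ yc)
    if sst == 0.0:
        raise DegenerateInputError("response has zero variance")
    ssr = float((Xc @ beta) @ yc)
    r2 = ssr / sst
    df2 = n - q - 1
    f = (r2 / q) / ((1.0 - r2) / df2)
    p = float(sps.f.sf(f, q, df2))
    return TestResult(float(f), float(q), p)


def gfi(A: np.ndarray, B: np.ndarray) -> float:
    """Goodness-of-fit index 1 − F(A,B)/F(A,I).

    F is the squared Frobenius distance over all p² entries, so gfi equals 1
    iff A = B, equals 0 at B = I, and is unbounded below.  Undefined (raises
    :class:`DegenerateInputError`) when the reference matrix is the identity.
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    denom = float(((A - np.eye(A.shape[0])) ** 2).sum())
    if denom == 0.0:
        raise DegenerateInputError("reference matrix equals the identity")
    return 1.0 - float(((A - B) ** 2).sum()) / denom


def srmr(A: np.ndarray, B: np.ndarray) -> float:
    """Standardized root mean squared residual between two correlation matrices.

    sqrt(2 * sum_{i=1..p} sum_{j<=i} (a_ij − b_ij)² / (p(p+1))), the lower
    triangle including the (vanishing, for correlation matrices) diagonal.
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    p = A.shape[0]
    il = np.tril_indices(p)
    d2 = ((A - B)[il] ** 2).sum()
    return float(math.sqrt(2.0 * d2 / (p * (p + 1))))


def proportion_estimate(rejections: int, n_reps: int) -> PowerEstimate:
    """Rejection proportion with binomial SE and normal-approximation 95% CI."""
    if not 0 <= rejections <= n_reps:
        raise ValueError("rejections must lie in [0, n_reps]")
    p = rejections / n_reps
    se = math.sqrt(p * (1.0 - p) / n_reps)
    return PowerEstimate(
        p_hat=p,
        n_reps=n_reps,
        se=se,
        ci_low=max(0.0, p - 1.96 * se),
        ci_high=min(1.0, p + 1.96 * se),
    )
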