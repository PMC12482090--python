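"""Rectified-normal latent model and equal-interval Likert discretization.

The latent response intensity is modelled as a normal draw *clipped* to a
finite range ``[lower, upper]`` — a rectified normal (RTN).  Unlike the
truncated normal, clipping leaves point masses at both limits; those masses
are how floor and ceiling effects enter the model.  A k-point Likert (LKS)
variable is obtained by cutting the RTN range into k equal-width intervals
and mapping interval j to the integer level j (1..k).

With the default latent scale ``sigma = 1`` and limits ``±2``, the open
interval carries 95.4% of the mass when the latent mean is 0; shifting the
mean moves mass onto one of the limits.

All moments here are exact (standard-normal CDF/PDF terms for the interior
plus the two boundary point masses), so effect-size attenuation under
discretization can be computed without simulation noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = [
    "RTNSpec",
    "LikertScheme",
    "MomentPair",
    "TwoGroupDesign",
    "DomainError",
    "DegenerateInputError",
    "NumericalFailureError",
    "UndefinedRatioError",
    "rtn_sample",
    "rtn_moments",
    "discretize",
    "likert_probabilities",
    "lks_moments",
    "standardized_mean_difference",
    "calibrate_shift",
    "effect_size_ratio",
]


class DomainError(ValueError):
    """A value lies outside the supported domain (e.g. outside the RTN range)."""


class DegenerateInputError(ValueError):
    """An input makes the requested statistic undefined (e.g. zero variance)."""


class NumericalFailureError(RuntimeError):
    """A numerical routine failed to converge."""


class UndefinedRatioError(ZeroDivisionError):
    """An attenuation ratio was requested for a zero effect size."""


@dataclass(frozen=True)
class RTNSpec:
    """Parameters of one rectified-normal variable.

    Parameters
    ----------
    mu : float
        Latent normal mean, in latent-scale units.
    sigma : float
        Latent normal standard deviation (default 1, the model's unit scale).
    lower, upper : float
        Clipping limits (defaults ±2, i.e. ±2σ on the unit latent scale).
    """

    mu: float = 0.0
    sigma: float = 1.0
    lower: float = -2.0
    upper: float = 2.0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if not self.lower < self.upper:
            raise ValueError(f"require lower < upper, got [{self.lower}, {self.upper}]")

    def shifted(self, delta: float) -> "RTNSpec":
        """The same variable with the latent mean shifted by ``delta``."""
        return RTNSpec(self.mu + delta, self.sigma, self.lower, self.upper)

    def interior_probability(self) -> float:
        """Probability strictly inside (lower, upper)."""
        a = (self.lower - self.mu) / self.sigma
        b = (self.upper - self.mu) / self.sigma
        return float(norm.cdf(b) - norm.cdf(a))


@dataclass(frozen=True)
class LikertScheme:
    """Equal-interval k-point discretization of an RTN range.

    ``edges`` are the k+1 cut points e_0 < ... < e_k with e_0 = lower and
    e_k = upper, equally spaced; interval j (half-open on the left, with the
    lower limit absorbed into level 1) maps to integer level j in 1..k.
    """

    k: int
    lower: float = -2.0
    upper: float = 2.0
    edges: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError(f"need at least 2 points, got k={self.k}")
        if not self.lower < self.upper:
            raise ValueError(f"require lower < upper, got [{self.lower}, {self.upper}]")
        edges = np.linspace(self.lower, self.upper, self.k + 1)
        object.__setattr__(self, "edges", edges)

    @property
    def levels(self) -> np.ndarray:
        """Integer levels 1..k."""
        return np.arange(1, self.k + 1)


@dataclass(frozen=True)
class MomentPair:
    """Mean and variance of a (possibly discretized) RTN variable."""

    mean: float
    variance: float

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError(f"variance must be nonnegative, got {self.variance}")


@dataclass(frozen=True)
class TwoGroupDesign:
    """A calibrated two-group comparison.

    ``delta`` is the latent mean shift of group 2 relative to the group-1
    baseline; ``target_es`` is the standardized mean difference it realizes
    on the RTN scale (not the latent scale — clipping attenuates the shift).
    """

    n1: int
    n2: int
    delta: float
    target_es: float

    def __post_init__(self) -> None:
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("group sizes must be positive")


def rtn_sample(
    spec: RTNSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` rectified-normal values: normal draws clipped to the limits.

    Clipping (not truncation) is used, so values exactly equal to the limits
    occur with positive probability.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    z = rng.normal(spec.mu, spec.sigma, size=n)
    return np.clip(z, spec.lower, spec.upper)


def _clip_moments(mu, sigma: float, lower: float, upper: float):
    """Exact mean and variance of clip(Z, lower, upper), Z ~ N(mu, sigma^2).

    Vectorized over ``mu``.  Interior contribution from standard-normal
    CDF/PDF terms; boundary point masses P(Z<=lower), P(Z>=upper) sit at the
    limits themselves.
    """
    mu = np.asarray(mu, dtype=float)
    a = (lower - mu) / sigma
    b = (upper - mu) / sigma
    ca, cb = norm.cdf(a), norm.cdf(b)
    pa, pb = norm.pdf(a), norm.pdf(b)
    inside = cb - ca
    # E[Z·1{a<z<b}] and E[Z²·1{a<z<b}] for Z = mu + sigma·z
    ez1 = pa - pb
    ez2 = inside + a * pa - b * pb
    m1 = lower * ca + upper * (1.0 - cb) + mu * inside + sigma * ez1
    m2 = (
        lower**2 * ca
        + upper**2 * (1.0 - cb)
        + mu**2 * inside
        + 2.0 * mu * sigma * ez1
        + sigma**2 * ez2
    )
    var = np.maximum(m2 - m1**2, 0.0)
    return m1, var


def rtn_moments(spec: RTNSpec) -> MomentPair:
    """Exact mean and variance of the rectified-normal variable."""
    m, v = _clip_moments(spec.mu, spec.sigma, spec.lower, spec.upper)
    return MomentPair(float(m), float(v))


def discretize(x: np.ndarray, scheme: LikertScheme) -> np.ndarray:
    """Map RTN values onto integer Likert levels 1..k.

    Bins are half-open on the left, (e_{j-1}, e_j] -> j, with the lower limit
    absorbed into level 1.  Interior edges carry zero probability under any
    continuous latent law, so the convention is statistically immaterial but
    makes the map deterministic.
    """
    x = np.asarray(x)
    if np.any(x < scheme.lower) or np.any(x > scheme.upper):
        raise DomainError(
            f"values outside [{scheme.lower}, {scheme.upper}] cannot be discretized"
        )
    inner = scheme.edges[1:-1]
    return np.searchsorted(inner, x, side="left") + 1


def likert_probabilities(spec: RTNSpec, scheme: LikertScheme) -> np.ndarray:
    """Exact level probabilities P(level=1..k) of the discretized variable.

    The boundary point masses fold into the extreme levels, so the vector
    sums to 1: P(1) = Φ((e_1−μ)/σ), interior differences of Φ, and
    P(k) = 1 − Φ((e_{k−1}−μ)/σ).
    """
    if not (
        math.isclose(scheme.lower, spec.lower) and math.isclose(scheme.upper, spec.upper)
    ):
        raise ValueError("scheme limits must equal spec limits")
    z = (scheme.edges - spec.mu) / spec.sigma
    cdf = norm.cdf(z)
    cdf[0] = 0.0
    cdf[-1] = 1.0
    return np.diff(cdf)


def lks_moments(spec: RTNSpec, scheme: LikertScheme) -> MomentPair:
    """Exact mean and variance of the k-point Likert variable on levels 1..k."""
    p = likert_probabilities(spec, scheme)
    levels = scheme.levels
    mean = float(np.dot(levels, p))
    var = float(np.dot(levels.astype(float) ** 2, p) - mean**2)
    return MomentPair(mean, max(var, 0.0))


def standardized_mean_difference(
    m1: MomentPair, m2: MomentPair, n1: int, n2: int
) -> float:
    """Heteroscedasticity-aware standardized mean difference.

    (μ1−μ2) / sqrt((n2·σ1² + n1·σ2²)/(n1+n2)) — each group's variance is
    weighted by the *other* group's sample size; with n1 = n2 this reduces
    to the usual pooled-unit form (μ1−μ2)/sqrt((σ1²+σ2²)/2).
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("sample sizes must be positive")
    denom_sq = (n2 * m1.variance + n1 * m2.variance) / (n1 + n2)
    if denom_sq <= 0:
        raise DegenerateInputError("both variances are zero")
    return (m1.mean - m2.mean) / math.sqrt(denom_sq)


def calibrate_shift(
    target_es: float,
    spec_base: RTNSpec | None = None,
    n1: int = 100,
    n2: int = 100,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> TwoGroupDesign:
    """Find the latent shift delta whose RTN-scale effect size is ``target_es``.

    Group 1 keeps the baseline latent mean; group 2 is shifted by delta.  The
    map delta -> RTN effect size is continuous and strictly increasing, so a
    bracketing bisection (auto-expanding upper bracket) is used.  Raises
    :class:`NumericalFailureError` if the target exceeds the attainable range
    (the RTN mean saturates at the upper limit).
    """
    if spec_base is None:
        spec_base = RTNSpec()
    if target_es == 0.0:
        return TwoGroupDesign(n1, n2, 0.0, 0.0)

    sign = 1.0 if target_es > 0 else -1.0
    target = abs(target_es)
    m_base = rtn_moments(spec_base)

    def es_of(delta: float) -> float:
        m2 = rtn_moments(spec_base.shifted(sign * delta))
        return abs(standardized_mean_difference(m_base, m2, n1, n2))

    lo, hi = 0.0, 1.0
    expansions = 0
    while es_of(hi) < target:
        lo, hi = hi, hi * 2.0
        expansions += 1
        if expansions > 60:
            raise NumericalFailureError(
                f"effect size {target} not attainable on the RTN scale"
            )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f = es_of(mid) - target
        if abs(f) <= tol:
            break
        if f < 0:
            lo = mid
        else:
            hi = mid
    else:
        raise NumericalFailureError("bisection did not converge")
    return TwoGroupDesign(n1, n2, sign * mid, target_es)


def effect_size_ratio(
    scheme: LikertScheme,
    design: TwoGroupDesign,
    spec_base: RTNSpec | None = None,
) -> float:
    """Attenuation ratio: Likert-scale effect size over RTN-scale effect size.

    Both standardized mean differences are computed from exact moments, so
    the ratio is noise-free.  For the model's grid it lies in (0, 1] and
    increases toward 1 as k grows.
    """
    if design.target_es == 0.0:
        raise UndefinedRatioError("attenuation ratio undefined at zero effect size")
    if spec_base is None:
        spec_base = RTNSpec(lower=scheme.lower, upper=scheme.upper)
    spec2 = spec_base.shifted(design.delta)
    smd_lks = standardized_mean_difference(
        lks_moments(spec_base, scheme), lks_moments(spec2, scheme), design.n1, design.n2
    )
    smd_rtn = standardized_mean_difference(
        rtn_moments(spec_base), rtn_moments(spec2), design.n1, design.n2
    )
    return smd_lks / smd_rtn
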