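"""Synthetic-data engine: correlated latent normals, clipping, coupled Likert views.

Surveys rarely ask one question; related items share a common construct.  The
generator emulates that with an exchangeable latent correlation structure: p
standard-scale normal variables sharing a single pairwise correlation rho,
built from one common factor and p unique factors,

    X_j = sqrt(rho) * C + sqrt(1 - rho) * U_j + mu_j,

which is exact at both endpoints (rho = 0 gives independence, rho = 1
duplicates one variable).  Each latent draw is then clipped to the RTN range
and discretized under every requested Likert scheme, so all variable types
within a replicate are deterministic views of the SAME latent matrix — the
coupling the experiments rely on for variance reduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .latent import LikertScheme, RTNSpec, TwoGroupDesign, discretize

__all__ = [
    "MultivariateSpec",
    "CoupledDataset",
    "exchangeable_latent_sample",
    "make_coupled_dataset",
    "two_group_dataset",
    "write_dataset",
]


@dataclass(frozen=True)
class MultivariateSpec:
    """p latent-normal variables with exchangeable pairwise correlation rho."""

    p: int
    rho: float = 0.0
    mu_vector: np.ndarray = None  # type: ignore[assignment]
    lower: float = -2.0
    upper: float = 2.0

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError(f"need p >= 1 variables, got {self.p}")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(
                f"exchangeable rho must lie in [0, 1], got {self.rho}"
            )
        mu = self.mu_vector
        mu = np.zeros(self.p) if mu is None else np.broadcast_to(
            np.asarray(mu, dtype=float), (self.p,)
        ).copy()
        object.__setattr__(self, "mu_vector", mu)

    def rtn_spec(self, j: int = 0) -> RTNSpec:
        """Marginal RTN spec of variable j."""
        return RTNSpec(float(self.mu_vector[j]), 1.0, self.lower, self.upper)


@dataclass(frozen=True)
class CoupledDataset:
    """One latent draw with its clipped (RTN) and discretized (Likert) views.

    ``rtn`` is elementwise clip of ``latent``; each entry of ``lks_by_scheme``
    is the discretization of ``rtn`` under a k-point scheme.  Everything is a
    deterministic function of the same latent matrix.
    """

    latent: np.ndarray
    rtn: np.ndarray
    lks_by_scheme: dict[int, np.ndarray] = field(default_factory=dict)


def exchangeable_latent_sample(
    spec: MultivariateSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n x p matrix of unit-variance normals with exchangeable correlation rho."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    common = rng.standard_normal((n, 1))
    unique = rng.standard_normal((n, spec.p))
    x = np.sqrt(spec.rho) * common + np.sqrt(1.0 - spec.rho) * unique
    return x + spec.mu_vector


def make_coupled_dataset(
    spec: MultivariateSpec,
    schemes: list[LikertScheme],
    n: int,
    rng: np.random.Generator,
) -> CoupledDataset:
    """Draw once, derive every variable type from that single latent matrix."""
    latent = exchangeable_latent_sample(spec, n, rng)
    rtn = np.clip(latent, spec.lower, spec.upper)
    lks = {s.k: discretize(rtn, s) for s in schemes}
    return CoupledDataset(latent=latent, rtn=rtn, lks_by_scheme=lks)


def two_group_dataset(
    design: TwoGroupDesign,
    spec0: MultivariateSpec,
    schemes: list[LikertScheme],
    rng: np.random.Generator,
) -> tuple[CoupledDataset, CoupledDataset]:
    """Two-group data: group 1 at the baseline means, group 2 shifted by delta.

    The calibrated latent shift is applied to every coordinate of group 2, so
    each marginal attains the design's target RTN-scale effect size.
    """
    spec1 = spec0
    spec2 = MultivariateSpec(
        spec0.p,
        spec0.rho,
        spec0.mu_vector + design.delta,
        spec0.lower,
        spec0.upper,
    )
    g1 = make_coupled_dataset(spec1, schemes, design.n1, rng)
    g2 = make_coupled_dataset(spec2, schemes, design.n2, rng)
    return g1, g2


def write_dataset(ds: CoupledDataset, path_prefix: str, delimiter: str = "\t") -> list[str]:
    """Export a coupled dataset as delimited text, one file per variable type."""
    paths = []
    p = ds.rtn.shape[1]
    for name, mat, fmt in [("latent", ds.latent, "%.6g"), ("rtn", ds.rtn, "%.6g")] + [
        (f"lks{k}", m, "%d") for k, m in sorted(ds.lks_by_scheme.items())
    ]:
        path = f"{path_prefix}_{name}.tsv"
        header = delimiter.join(f"{name}_v{j + 1}" for j in range(p))
        np.savetxt(path, mat, fmt=fmt, delimiter=delimiter, header=header, comments="")
        paths.append(path)
    return paths
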