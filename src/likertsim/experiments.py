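"""Simulation drivers: the four Monte Carlo experiments and sample-size search.

Four questions are answered, each as a factor grid of Monte Carlo cells:

1. ``run_single_response_power`` — type-1 error / power of the two-sample
   t-test on one variable, across effect size, per-group n, and variable type
   (the clipped-normal RTN benchmark vs its 2..7-point Likert transforms).
2. ``run_merged_power`` — power of the t-test on a *total score* summing p
   exchangeably correlated items, across p, latent correlation rho, and type,
   with the sample size each Likert type would need to match the RTN power.
3. ``run_correlation_similarity`` — how well the Likert transforms preserve
   the correlation matrix of the underlying clipped variables, measured by
   GFI and SRMR between the two sample correlation matrices.
4. ``run_regression_power`` — power of the overall regression F-test when
   response and explanatory variables are independently assigned types.

Within a cell all variable types are *coupled*: they are deterministic views
of the same latent draws, which removes between-type Monte Carlo noise from
the comparisons.  The merged and regression grids go further and share
common random numbers across their factor levels (rho, p, q), so the
monotone patterns across those factors are also compared on common draws.
Random streams are derived from the master seed via ``SeedSequence`` spawn
keys and are invariant to cell evaluation order.

Replicates are processed in chunks with fully vectorized Welch / OLS /
correlation kernels; the kernels are tested against the scalar routines in
:mod:`likertsim.stats`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .latent import (
    LikertScheme,
    RTNSpec,
    TwoGroupDesign,
    UndefinedRatioError,
    calibrate_shift,
    discretize,
    effect_size_ratio,
)
from .stats import PowerEstimate, proportion_estimate

__all__ = [
    "SimulationConfig",
    "CellResult",
    "RTN_LABEL",
    "run_single_response_power",
    "run_merged_power",
    "run_correlation_similarity",
    "run_regression_power",
    "run_effect_size_curve",
    "required_n_for_power",
]

RTN_LABEL = "RTN"

# stable experiment ids entering the per-cell seed derivation
_EXP_SINGLE, _EXP_MERGED, _EXP_CORR, _EXP_REGRESSION, _EXP_CURVE = 1, 2, 3, 4, 5


@dataclass(frozen=True)
class SimulationConfig:
    """Experiment grids and Monte Carlo settings.

    Defaults reproduce the study conditions: effect sizes {0, 0.2, 0.5} on
    the RTN scale, per-group sample sizes {30..500}, 2–7-point Likert types,
    exchangeable correlations {0..1}, merge counts {2,3,5,10}, explanatory
    counts {1,2,3,5,10}, 10,000 replicates at alpha = 0.05.  The merged
    experiment fixes effect size 0.2 and n=100/group; the correlation and
    regression experiments fix n=200 per dataset, the latter with latent
    rho = 0.2 and types capped at 5 points.
    """

    effect_sizes: tuple[float, ...] = (0.0, 0.2, 0.5)
    sample_sizes: tuple[int, ...] = (30, 50, 100, 300, 500)
    likert_points: tuple[int, ...] = (2, 3, 4, 5, 6, 7)
    rhos: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    merge_counts: tuple[int, ...] = (2, 3, 5, 10)
    n_explanatory: tuple[int, ...] = (1, 2, 3, 5, 10)
    n_reps: int = 10_000
    alpha: float = 0.05
    seed: int = 20_250_929
    chunk_size: int = 2_000
    merged_es: float = 0.2
    merged_n: int = 100
    corr_n: int = 200
    regression_n: int = 200
    regression_rho: float = 0.2
    regression_points: tuple[int, ...] = (2, 3, 4, 5)
    es_grid: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5)
    lower: float = -2.0
    upper: float = 2.0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        clean = {
            k: tuple(v) if isinstance(v, (list, tuple)) else v for k, v in d.items()
        }
        return cls(**clean)

    def scheme(self, k: int) -> LikertScheme:
        return LikertScheme(k, self.lower, self.upper)

    def base_spec(self, mu: float = 0.0) -> RTNSpec:
        return RTNSpec(mu, 1.0, self.lower, self.upper)


@dataclass(frozen=True)
class CellResult:
    """One grid cell: factor levels, its power estimate, and any extras."""

    cell: dict
    power: PowerEstimate | None = None
    required_n: int | None = None
    extras: dict = field(default_factory=dict)
    n_degenerate: int = 0

    def to_row(self) -> dict:
        row = dict(self.cell)
        if self.power is not None:
            row.update(
                power_pct=100.0 * self.power.p_hat,
                se_pct=100.0 * self.power.se,
                ci_low_pct=100.0 * self.power.ci_low,
                ci_high_pct=100.0 * self.power.ci_high,
                n_reps=self.power.n_reps,
            )
        row["required_n"] = self.required_n
        row.update(self.extras)
        row["n_degenerate"] = self.n_degenerate
        return row


def _frame(results: Iterable[CellResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])


def _cell_rng(seed: int, exp_id: int, cell_index: int) -> np.random.Generator:
    """Independent stream per grid cell, invariant to cell evaluation order."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(exp_id, cell_index))
    )


def _chunks(n_reps: int, chunk_size: int):
    done = 0
    while done < n_reps:
        take = min(chunk_size, n_reps - done)
        done += take
        yield take


def _type_labels(points: Sequence[int]) -> list[str]:
    return [RTN_LABEL] + [f"{k}pt" for k in points]


# ---------------------------------------------------------------------------
# vectorized kernels (replicates along axis 0)
# ---------------------------------------------------------------------------

def welch_p_values(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Welch t-test p-values for stacked replicates x: (R, n1), y: (R, n2).

    Returns (p_values, degenerate_mask); degenerate replicates (zero variance
    in both groups) get p = 1, i.e. they count as non-rejections.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = x.shape[1], y.shape[1]
    m1, m2 = x.mean(axis=1), y.mean(axis=1)
    v1, v2 = x.var(axis=1, ddof=1), y.var(axis=1, ddof=1)
    a, b = v1 / n1, v2 / n2
    denom = a + b
    degenerate = denom == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(denom)
        df = denom**2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))
    p = np.ones_like(t)
    ok = ~degenerate
    p[ok] = 2.0 * sps.t.sf(np.abs(t[ok]), df[ok])
    return np.minimum(p, 1.0), degenerate


def batched_correlation(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sample correlation matrices for stacked datasets data: (R, n, p).

    Returns (corr (R, p, p), degenerate_mask) where a replicate is degenerate
    if any column is constant.
    """
    data = np.asarray(data, float)
    xc = data - data.mean(axis=1, keepdims=True)
    cov = np.einsum("rni,rnj->rij", xc, xc)
    sd = np.sqrt(np.diagonal(cov, axis1=1, axis2=2))
    degenerate = (sd == 0.0).any(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / (sd[:, :, None] * sd[:, None, :])
    return corr, degenerate


def batched_gfi_srmr(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """GFI and SRMR for stacked correlation-matrix pairs (R, p, p).

    Returns (gfi, srmr, gfi_undefined_mask); GFI is undefined where the
    reference matrix equals the identity.
    """
    p = A.shape[1]
    eye = np.eye(p)
    num = ((A - B) ** 2).sum(axis=(1, 2))
    den = ((A - eye) ** 2).sum(axis=(1, 2))
    undefined = den == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        g = 1.0 - num / den
    il = np.tril_indices(p)
    d2 = ((A - B)[:, il[0], il[1]] ** 2).sum(axis=1)
    s = np.sqrt(2.0 * d2 / (p * (p + 1)))
    return g, s, undefined


def batched_overall_f(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Overall-F p-values and R² for stacked regressions y: (R, n), X: (R, n, q)."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    R, n, q = X.shape
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sxx = np.einsum("rni,rnj->rij", Xc, Xc)
    sxy = np.einsum("rni,rn->ri", Xc, yc)
    try:
        beta = np.linalg.solve(sxx, sxy[..., None])[..., 0]
    except np.linalg.LinAlgError:
        beta = np.stack(
            [np.linalg.lstsq(sxx[r], sxy[r], rcond=None)[0] for r in range(R)]
        )
    ssr = np.einsum("ri,ri->r", beta, sxy)
    sst = np.einsum("rn,rn->r", yc, yc)
    r2 = np.clip(ssr / sst, 0.0, 1.0)
    df2 = n - q - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (r2 / q) / ((1.0 - r2) / df2)
    pvals = sps.f.sf(f, q, df2)
    return np.asarray(pvals), r2


def _exchangeable_chunk(
    rng: np.random.Generator, reps: int, n: int, p: int, rho: float, mu: float
) -> np.ndarray:
    """(reps, n, p) latent normals, exchangeable correlation rho, common mean mu."""
    common = rng.standard_normal((reps, n, 1))
    unique = rng.standard_normal((reps, n, p))
    return math.sqrt(rho) * common + math.sqrt(1.0 - rho) * unique + mu


# ---------------------------------------------------------------------------
# experiment 1: single-response t-test power
# ---------------------------------------------------------------------------

def run_single_response_power(cfg: SimulationConfig) -> pd.DataFrame:
    """Type-1 error / power of the t-test per (effect size, n, variable type).

    Per replicate both groups are drawn on the latent scale (group 2 shifted
    by the calibrated delta), clipped, and discretized under every Likert
    scheme; the same draws feed every variable type.
    """
    schemes = [cfg.scheme(k) for k in cfg.likert_points]
    labels = _type_labels(cfg.likert_points)
    results: list[CellResult] = []
    cell_index = 0
    for es in cfg.effect_sizes:
        for n in cfg.sample_sizes:
            design = calibrate_shift(es, cfg.base_spec(), n, n)
            rng = _cell_rng(cfg.seed, _EXP_SINGLE, cell_index)
            cell_index += 1
            rejections = {lab: 0 for lab in labels}
            degenerate = {lab: 0 for lab in labels}
            for take in _chunks(cfg.n_reps, cfg.chunk_size):
                g1 = rng.standard_normal((take, n))
                g2 = rng.standard_normal((take, n)) + design.delta
                r1 = np.clip(g1, cfg.lower, cfg.upper)
                r2 = np.clip(g2, cfg.lower, cfg.upper)
                views = {RTN_LABEL: (r1, r2)}
                for s in schemes:
                    views[f"{s.k}pt"] = (discretize(r1, s), discretize(r2, s))
                for lab, (x, y) in views.items():
                    p, degen = welch_p_values(x, y)
                    rejections[lab] += int((p < cfg.alpha).sum())
                    degenerate[lab] += int(degen.sum())
            for lab in labels:
                results.append(
                    CellResult(
                        cell={"effect_size": es, "n_per_group": n, "type": lab},
                        power=proportion_estimate(rejections[lab], cfg.n_reps),
                        n_degenerate=degenerate[lab],
                    )
                )
    return _frame(results)


# ---------------------------------------------------------------------------
# experiment 2: merged (total-score) t-test power
# ---------------------------------------------------------------------------

def run_merged_power(cfg: SimulationConfig) -> pd.DataFrame:
    """Power of the t-test on the sum of p correlated items, per (p, rho, type).

    Effect size is fixed on the RTN scale per item (default 0.2) and applied
    to every coordinate of group 2; sample size defaults to 100/group.  Each
    Likert cell also reports the per-group n needed to match the same-cell
    RTN power, from a normal-approximation inversion on the pooled
    merged-score standardized mean differences.

    The whole (p, rho) grid shares common random numbers — one common and
    p_max unique factors per replicate, remixed per cell — so comparisons
    across correlations and merge counts are variance-reduced.
    """
    schemes = [cfg.scheme(k) for k in cfg.likert_points]
    labels = _type_labels(cfg.likert_points)
    n = cfg.merged_n
    design = calibrate_shift(cfg.merged_es, cfg.base_spec(), n, n)
    p_max = max(cfg.merge_counts)
    cells = [(p, r) for p in cfg.merge_counts for r in cfg.rhos]
    rng = _cell_rng(cfg.seed, _EXP_MERGED, 0)
    rejections = {c: {lab: 0 for lab in labels} for c in cells}
    degenerate = {c: {lab: 0 for lab in labels} for c in cells}
    # pooled score sums for moment-based effect-size recovery
    sums = {c: {lab: np.zeros(2) for lab in labels} for c in cells}
    sumsqs = {c: {lab: np.zeros(2) for lab in labels} for c in cells}
    total_obs = 0
    for take in _chunks(cfg.n_reps, cfg.chunk_size):
        # common random numbers across the whole (p, rho) grid: one common
        # factor and p_max unique factors per group, remixed per cell
        c1 = rng.standard_normal((take, n, 1))
        u1 = rng.standard_normal((take, n, p_max))
        c2 = rng.standard_normal((take, n, 1))
        u2 = rng.standard_normal((take, n, p_max))
        total_obs += take * n
        for p_vars, rho in cells:
            sq_r, sq_u = math.sqrt(rho), math.sqrt(1.0 - rho)
            l1 = sq_r * c1 + sq_u * u1[:, :, :p_vars]
            l2 = sq_r * c2 + sq_u * u2[:, :, :p_vars] + design.delta
            r1 = np.clip(l1, cfg.lower, cfg.upper)
            r2 = np.clip(l2, cfg.lower, cfg.upper)
            views = {RTN_LABEL: (r1, r2)}
            for s in schemes:
                views[f"{s.k}pt"] = (discretize(r1, s), discretize(r2, s))
            for lab, (x3, y3) in views.items():
                x = x3.sum(axis=2, dtype=float)
                y = y3.sum(axis=2, dtype=float)
                pv, degen = welch_p_values(x, y)
                cell = (p_vars, rho)
                rejections[cell][lab] += int((pv < cfg.alpha).sum())
                degenerate[cell][lab] += int(degen.sum())
                sums[cell][lab] += (x.sum(), y.sum())
                sumsqs[cell][lab] += ((x**2).sum(), (y**2).sum())
    results: list[CellResult] = []
    for cell in cells:
        p_vars, rho = cell
        # pooled merged-score SMD per type (equal group sizes)
        d_hat = {}
        for lab in labels:
            m = sums[cell][lab] / total_obs
            v = sumsqs[cell][lab] / total_obs - m**2
            d_hat[lab] = (m[1] - m[0]) / math.sqrt((v[0] + v[1]) / 2.0)
        for lab in labels:
            req = None
            if lab != RTN_LABEL and d_hat[lab] > 0:
                req = math.ceil(n * (d_hat[RTN_LABEL] / d_hat[lab]) ** 2)
            results.append(
                CellResult(
                    cell={"merge_count": p_vars, "rho": rho, "type": lab},
                    power=proportion_estimate(rejections[cell][lab], cfg.n_reps),
                    required_n=req,
                    extras={"merged_smd": d_hat[lab]},
                    n_degenerate=degenerate[cell][lab],
                )
            )
    return _frame(results)


# ---------------------------------------------------------------------------
# experiment 3: correlation-structure preservation (GFI / SRMR)
# ---------------------------------------------------------------------------

def run_correlation_similarity(cfg: SimulationConfig) -> pd.DataFrame:
    """Mean GFI / SRMR between RTN and Likert sample correlation matrices.

    Per replicate one coupled dataset of p items (n defaults to 200) yields
    the reference correlation matrix A (clipped data) and, per k, the
    comparison matrix B (discretized data).  Replicates where either matrix
    is undefined, or where A equals the identity (GFI undefined), are dropped
    from the affected summary and counted.
    """
    schemes = [cfg.scheme(k) for k in cfg.likert_points]
    rhos = tuple(r for r in cfg.rhos if r < 1.0)
    n = cfg.corr_n
    results: list[CellResult] = []
    cell_index = 0
    for p_vars in cfg.merge_counts:
        for rho in rhos:
            rng = _cell_rng(cfg.seed, _EXP_CORR, cell_index)
            cell_index += 1
            acc = {
                s.k: {"g": 0.0, "g2": 0.0, "gn": 0, "s": 0.0, "s2": 0.0, "sn": 0, "drop": 0}
                for s in schemes
            }
            for take in _chunks(cfg.n_reps, cfg.chunk_size):
                latent = _exchangeable_chunk(rng, take, n, p_vars, rho, 0.0)
                rtn = np.clip(latent, cfg.lower, cfg.upper)
                A, degA = batched_correlation(rtn)
                for s in schemes:
                    B, degB = batched_correlation(discretize(rtn, s))
                    g, sr, undef = batched_gfi_srmr(A, B)
                    ok = ~(degA | degB)
                    a = acc[s.k]
                    gok = ok & ~undef
                    a["g"] += float(g[gok].sum())
                    a["g2"] += float((g[gok] ** 2).sum())
                    a["gn"] += int(gok.sum())
                    a["s"] += float(sr[ok].sum())
                    a["s2"] += float((sr[ok] ** 2).sum())
                    a["sn"] += int(ok.sum())
                    a["drop"] += int((~ok).sum() + (ok & undef).sum())
            for s in schemes:
                a = acc[s.k]
                gm = a["g"] / a["gn"] if a["gn"] else math.nan
                gse = (
                    math.sqrt(max(a["g2"] / a["gn"] - gm**2, 0.0) / a["gn"])
                    if a["gn"]
                    else math.nan
                )
                sm = a["s"] / a["sn"] if a["sn"] else math.nan
                sse = (
                    math.sqrt(max(a["s2"] / a["sn"] - sm**2, 0.0) / a["sn"])
                    if a["sn"]
                    else math.nan
                )
                results.append(
                    CellResult(
                        cell={"merge_count": p_vars, "rho": rho, "type": f"{s.k}pt"},
                        extras={
                            "gfi_mean": gm,
                            "gfi_se": gse,
                            "srmr_mean": sm,
                            "srmr_se": sse,
                            "n_used": a["sn"],
                        },
                        n_degenerate=a["drop"],
                    )
                )
    return _frame(results)


# ---------------------------------------------------------------------------
# experiment 4: regression overall-F power
# ---------------------------------------------------------------------------

def _ncf_power(q: int, n: int, rho2: float, alpha: float) -> float:
    """Power of the overall F(q, n−q−1) test at population R² = rho2."""
    df2 = n - q - 1
    if df2 < 1:
        return 0.0
    lam = n * rho2 / (1.0 - rho2)
    crit = sps.f.isf(alpha, q, df2)
    return float(sps.ncf.sf(crit, q, df2, lam))


def _required_n_regression(
    q: int, rho2: float, target_power: float, alpha: float
) -> int | None:
    """Smallest total n whose overall-F power reaches ``target_power``."""
    if rho2 <= 0:
        return None
    lo, hi = q + 2, q + 3
    while _ncf_power(q, hi, rho2, alpha) < target_power:
        lo, hi = hi, hi * 2
        if hi > 10_000_000:
            return None
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _ncf_power(q, mid, rho2, alpha) >= target_power:
            hi = mid
        else:
            lo = mid
    return hi


def run_regression_power(cfg: SimulationConfig) -> pd.DataFrame:
    """Overall-F power per (response type, explanatory type, q).

    One coupled dataset of q+1 exchangeably correlated items (latent rho
    defaults to 0.2, n to 200) supplies every type combination: column 1 in
    the response type is regressed on columns 2..q+1 in the explanatory type.
    Likert-explanatory cells also report the total n needed to match the
    RTN-explanatory power for the same response type, via a noncentral-F
    inversion on the mean adjusted R².
    """
    schemes = [cfg.scheme(k) for k in cfg.regression_points]
    labels = _type_labels(cfg.regression_points)
    n = cfg.regression_n
    rho = cfg.regression_rho
    q_max = max(cfg.n_explanatory)
    rng = _cell_rng(cfg.seed, _EXP_REGRESSION, 0)
    rejections = {
        (q, r, e): 0 for q in cfg.n_explanatory for r in labels for e in labels
    }
    r2_sums = {key: 0.0 for key in rejections}
    for take in _chunks(cfg.n_reps, cfg.chunk_size):
        # common random numbers across q: draw q_max+1 coupled columns once,
        # smaller designs use the leading columns of the same draw
        latent = _exchangeable_chunk(rng, take, n, q_max + 1, rho, 0.0)
        rtn = np.clip(latent, cfg.lower, cfg.upper)
        mats = {RTN_LABEL: rtn}
        for s in schemes:
            mats[f"{s.k}pt"] = discretize(rtn, s).astype(float)
        for q in cfg.n_explanatory:
            for r_lab in labels:
                y = mats[r_lab][:, :, 0]
                for e_lab in labels:
                    X = mats[e_lab][:, :, 1 : q + 1]
                    pv, r2 = batched_overall_f(y, X)
                    rejections[(q, r_lab, e_lab)] += int((pv < cfg.alpha).sum())
                    r2_sums[(q, r_lab, e_lab)] += float(r2.sum())
    results: list[CellResult] = []
    for q in cfg.n_explanatory:
        # matched required n: Likert explanatory vs RTN explanatory, same response
        df2 = n - q - 1
        rho2_adj = {
            (r, e): max(
                0.0,
                1.0 - (1.0 - r2_sums[(q, r, e)] / cfg.n_reps) * (n - 1) / df2,
            )
            for r in labels
            for e in labels
        }
        for r_lab in labels:
            target = rejections[(q, r_lab, RTN_LABEL)] / cfg.n_reps
            for e_lab in labels:
                req = None
                if e_lab != RTN_LABEL:
                    req = _required_n_regression(
                        q, rho2_adj[(r_lab, e_lab)], target, cfg.alpha
                    )
                results.append(
                    CellResult(
                        cell={
                            "response_type": r_lab,
                            "explanatory_type": e_lab,
                            "n_explanatory": q,
                        },
                        power=proportion_estimate(
                            rejections[(q, r_lab, e_lab)], cfg.n_reps
                        ),
                        required_n=req,
                        extras={"mean_r2_adj": rho2_adj[(r_lab, e_lab)]},
                    )
                )
    return _frame(results)


# ---------------------------------------------------------------------------
# effect-size curve and required-sample-size search
# ---------------------------------------------------------------------------

def run_effect_size_curve(cfg: SimulationConfig) -> pd.DataFrame:
    """Analytic attenuation ratios per (type, RTN effect size), noise-free."""
    rows = []
    for es in cfg.es_grid:
        design = calibrate_shift(es, cfg.base_spec(), cfg.merged_n, cfg.merged_n)
        rows.append(
            {"type": RTN_LABEL, "effect_size": es, "ratio": 1.0, "lks_es": es}
        )
        for k in cfg.likert_points:
            ratio = effect_size_ratio(cfg.scheme(k), design, cfg.base_spec())
            rows.append(
                {
                    "type": f"{k}pt",
                    "effect_size": es,
                    "ratio": ratio,
                    "lks_es": es * ratio,
                }
            )
    return pd.DataFrame(rows)


def required_n_for_power(
    type_: str | int,
    es_rtn: float,
    power_target: float = 0.8,
    cfg: SimulationConfig | None = None,
    refine: bool = False,
) -> int:
    """Smallest per-group n giving ``power_target`` for the two-sample t-test.

    ``type_`` is ``"RTN"`` (or 0) for the clipped benchmark, otherwise the
    Likert point count.  The effect size is stated on the RTN scale; for a
    Likert type it is attenuated by the exact ratio first.  The base answer
    is the normal-approximation inversion
    ``n = ceil(2 (z_{1-alpha/2} + z_power)^2 / d^2)``; with ``refine=True``
    the neighbourhood is scanned with simulated power (step 1).
    """
    cfg = cfg or SimulationConfig()
    if es_rtn <= 0:
        raise UndefinedRatioError("required n undefined for nonpositive effect size")
    design = calibrate_shift(es_rtn, cfg.base_spec(), cfg.merged_n, cfg.merged_n)
    if isinstance(type_, str) and type_.upper() == RTN_LABEL:
        ratio = 1.0
        k = None
    else:
        k = int(str(type_).rstrip("pt"))
        ratio = effect_size_ratio(cfg.scheme(k), design, cfg.base_spec())
    d = es_rtn * ratio
    z_a = sps.norm.isf(cfg.alpha / 2.0)
    z_p = sps.norm.ppf(power_target)
    if not z_a + z_p > 0:
        raise ValueError("unachievable power target")
    n = math.ceil(2.0 * (z_a + z_p) ** 2 / d**2)
    if refine:
        n = _refine_required_n(n, design, k, power_target, cfg)
    return n


def _simulated_power(
    n: int, design: TwoGroupDesign, k: int | None, cfg: SimulationConfig,
    rng: np.random.Generator,
) -> float:
    scheme = cfg.scheme(k) if k is not None else None
    rejections = 0
    for take in _chunks(cfg.n_reps, max(1, cfg.chunk_size * 100 // max(n, 1))):
        g1 = np.clip(rng.standard_normal((take, n)), cfg.lower, cfg.upper)
        g2 = np.clip(
            rng.standard_normal((take, n)) + design.delta, cfg.lower, cfg.upper
        )
        if scheme is not None:
            g1, g2 = discretize(g1, scheme), discretize(g2, scheme)
        pv, _ = welch_p_values(g1, g2)
        rejections += int((pv < cfg.alpha).sum())
    return rejections / cfg.n_reps


def _refine_required_n(
    n0: int, design: TwoGroupDesign, k: int | None, power_target: float,
    cfg: SimulationConfig,
) -> int:
    """Walk the analytic answer by single steps against simulated power."""
    rng = _cell_rng(cfg.seed, _EXP_CURVE, n0)
    n = max(n0, 2)
    if _simulated_power(n, design, k, cfg, rng) >= power_target:
        while n > 2 and _simulated_power(n - 1, design, k, cfg, rng) >= power_target:
            n -= 1
    else:
        while _simulated_power(n + 1, design, k, cfg, rng) < power_target:
            n += 1
        n += 1
    return n
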