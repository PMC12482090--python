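# likertsim

Monte Carlo machinery for a question every survey analyst faces: **how much
is lost by treating a k-point Likert response as a continuous variable?**
Survey instruments in nursing, public health, and the social sciences score
ordinal items 1..k and feed them to t-tests, linear regression, factor
analysis. `likertsim` quantifies the cost of that shortcut under an
explicit latent model, for researchers planning studies (how many points?
how many subjects?) and for methodologists auditing the practice.

## The model

The continuous benchmark is a **rectified normal (RTN)** variable: a latent
normal Z ~ N(μ, σ²) clipped to [−2, 2] (σ = 1, so a centered variable keeps
95.4% of its mass inside the range). Unlike the truncated normal, clipping
leaves point masses at the limits — the model's floor and ceiling effects.
A k-point Likert variable cuts the same range into k equal-width bins and
records the bin index 1..k.

Two-group effects are measured by the heteroscedasticity-aware standardized
mean difference

    d = (μ₁ − μ₂) / √((n₂σ₁² + n₁σ₂²)/(n₁ + n₂)),

always *calibrated on the RTN scale*: the latent shift realizing a target d
is found by bisection on the exact clipped-normal moments. The package then
measures, by exact moment calculations and by simulation, (1) the type-1
error and power of the Welch t-test per variable type, (2) power for total
scores merging correlated items, (3) preservation of the correlation matrix
under discretization (GFI/SRMR), and (4) overall-F power in regression —
plus the effect-size attenuation ratio and required sample sizes per scale
length.

## Worked example

```python
from likertsim import (SimulationConfig, run_single_response_power,
                       calibrate_shift, effect_size_ratio, LikertScheme,
                       required_n_for_power)

# exact attenuation: a 0.2-SD effect on the latent benchmark shrinks to
# 80% on a 2-point scale but survives a 5-point scale almost intact
design = calibrate_shift(0.2)          # latent shift 0.2010
effect_size_ratio(LikertScheme(2), design)   # 0.801
effect_size_ratio(LikertScheme(5), design)   # 0.963

# simulated power of the Welch t-test at n=100/group, 10,000 replicates
cfg = SimulationConfig(effect_sizes=(0.2,), sample_sizes=(100,),
                       likert_points=(2, 5))
print(run_single_response_power(cfg))
```

which prints (power as percent ± Monte Carlo SE):

```
 effect_size  n_per_group type  power_pct  se_pct
         0.2          100  RTN      29.27    0.46
         0.2          100  2pt      22.25    0.42
         0.2          100  5pt      27.47    0.45
```

The 2-point scale throws away about a quarter of the power; the 5-point
scale nearly none. Because power scales as 1/d², the sample size needed for
80% power at the same effect is `required_n_for_power("RTN", 0.2)` → 393
per group for the benchmark, 611 for the 2-point scale, i.e. the 0.801
attenuation ratio costs (1/0.801²− 1) ≈ 56% more subjects.

## Command line

Each subcommand writes a long-format CSV (plus a JSON run manifest) into
`--out-dir`; the same seed reproduces every table byte-for-byte.

```bash
likertsim table1 --seed 1                 # single-response power grid
likertsim table2 --quick                  # merged scores, 1,000 replicates
likertsim all --reps 10000 --out-dir results/
```

`--config grid.yaml` overrides any factor grid (effect sizes, sample sizes,
scale lengths, correlations, merge counts, ...).

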