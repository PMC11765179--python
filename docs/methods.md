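# Methods note

This note records the models, the synthetic-data generator, and the
numerical choices behind `bioinkflow`, together with their known limits.

## System

Hybrid hydrogel bioinks mixing alginate (A), gelatin (G) and
TEMPO-oxidized nano-fibrillated cellulose (T) at a fixed total solid
content of 8 wt%. Eight canonical compositions span alginate
2–5.25 wt%, gelatin 2–5.25 wt% and TO-NFC at 0.5 or 1 wt%. Units follow
the rheometer convention throughout: viscosity in mPa·s, shear stress in
Pa, shear rate in 1/s.

## Rheological models

**Cross model** (flow curve, viscosity vs. shear rate):

    eta(gd) = eta_inf + (eta_0 − eta_inf) / (1 + (t·gd)^m)

with zero-shear plateau `eta_0`, infinite-shear plateau `eta_inf`, time
constant `t` and transition factor `m`. Valid parameters require
`eta_0 > eta_inf > 0`, `t > 0`, `0 < m < 2`; the curve is then strictly
decreasing in shear rate.

**Herschel–Bulkley model** (shear stress vs. shear rate):

    tau(gd) = tau_0 + K·gd^n

with yield stress `tau_0 ≥ 0` (Pa), consistency index `K` stored in
mPa·s^n and converted to Pa·s^n (×10⁻³) inside the stress evaluation,
and flow index `0 < n ≤ 1`.

The characterized parameter sets for the eight canonical compositions
are hard-coded in `bioinkflow.datasets.CANONICAL_SYSTEMS` and act as the
generative ground truth for the whole package.

## Synthetic data generator

No raw rheometer sweeps ship with the package; flow curves are
regenerated from the parameter sets. Defaults reproduce the reference
measurement conditions: 8 compositions × 21 log-spaced shear rates on [0.1, 100] 1/s
(168 rows). Noise is multiplicative log-normal — each viscosity and
stress value is multiplied by `exp(eps)` with
`eps ~ Normal(0, sigma²)`, `sigma = 0.05` by default — so generated
values stay positive and the ln-viscosity targets carry additive
Gaussian noise. `sigma = 0` reproduces the models exactly.

Generator limits: the grid must stay inside the instrument sweep range
[0.1, 100] 1/s; composition labels must be unique; the design has only
8 distinct (A, G, T) points, all on the plane A + G + T = 8. That last
fact matters for the polynomial surrogate (below).

## Model fitting

**Cross fits** minimize squared residuals of *log*-viscosity: the
curves span more than three decades, and raw-space least squares would
be dominated entirely by the zero-shear plateau. Parameters are
optimized as `(log eta_inf, log eta_0, log t, m)` so positivity holds by
construction, with `m` bounded in (0, 2). Initialization takes `eta_0`
from the largest observed viscosity, `eta_inf` from the smallest, and
`t` from the reciprocal shear rate at the midpoint of the log-viscosity
drop, with up to three jittered restarts on non-convergence
(`scipy.optimize.least_squares`, trust-region reflective). A constant
curve is returned as a flagged degenerate fit rather than an error.

**Herschel–Bulkley fits** are done in raw stress space (stress spans
about one decade), with `tau_0 ≥ 0` and `n ≤ 1` as bounds and a
log-log slope/intercept initialization for `n` and `K`.

Adjusted R² is reported on the same scale the fit was performed on. On
noiseless 21-point sweeps, all eight parameter rows are recovered well
inside 0.1% (Cross) and 0.5% (Herschel–Bulkley) relative error.

**Thixotropic recovery** uses the standard three-interval protocol
(rest 0–60 s at 1 1/s, shear 61–65 s at 100 1/s, recovery 66–185 s at
1 1/s). The recovery rate at elapsed time t is the interpolated
recovery-phase viscosity over the mean at-rest viscosity of the last
10 s of the rest interval, in percent.

## Surrogates

All three surrogates map (shear rate, A, G, T) to ln viscosity (mPa·s).

**Polynomial response surface.** Full multivariate basis of all
monomials with total degree ≤ n (C(n+4, 4) terms, graded-lexicographic
order), fitted by least squares after standardizing features. The
canonical design is *structurally rank-deficient* at degree 4 (rank 24
of 70 columns: 8 composition points on one plane cannot identify the
full basis), so the default solver is minimum-norm `lstsq`; a strict
mode (`require_full_rank=True`) instead raises an error naming the
degenerate terms via the SVD null space. Order selection uses
AIC = N·ln(RSS/N) + 2p over candidate degrees, excluding candidates
with p ≥ N.

**Regression tree.** Hand-written CART for regression: exhaustive
best-SSE split search per node using prefix sums over sorted feature
values, midpoint thresholds, ties broken toward the lowest feature
index and then the lowest threshold. Unlimited depth and
single-sample leaves by default; depth can be chosen by 5-fold CV with
the 1-SE rule. Split search agrees with an exhaustive oracle and with
scikit-learn's `DecisionTreeRegressor` training SSE at fixed depth.

**Random forest.** Bagging of unpruned trees (default 200) on bootstrap
resamples, prediction by arithmetic mean, per-tree seeds from
`SeedSequence.spawn`. Feature importances are the normalized total SSE
reduction per feature. Deviation from common forest folklore: the
default considers *all* features at every split (the usual regression
default in scikit-learn) rather than a random subset — with only four
features and shear rate carrying most of the signal, restricting the
per-split candidate set measurably degrades held-out accuracy (mean
holdout R² drops from ≈0.985 to ≈0.964, below the single tree).

**Validation.** Repeated random holdout: 100 iterations, train on
floor(0.8·N) points, evaluate R² and MAE on the rest (135/34 at
N = 169; 134/34 on the default 168-row dataset), report means.
Observed on the default dataset over 100 iterations: polynomial
≈0.88, tree ≈0.975, forest ≈0.985 mean R², preserving the
polynomial ≤ tree ≤ forest ordering. The polynomial's ceiling is
structural — cross-checked against scikit-learn on identical splits
(bit-comparable results) and nearly unchanged at `sigma = 0` — because
the rank-deficient composition design limits what any degree-4
polynomial can express off the training plane.

## Optimization

Objective: `f(x) = (eta_pred(x) − mid)²`, the squared deviation of the
surrogate-predicted ln-viscosity from the midpoint (12.32) of the
structural-integrity window [11.52, 13.12] (ln mPa·s, i.e. 100–500
Pa·s). Penalty: the absolute deviation from the violated window bound,
zero inside; for the high-shear scenario a quadratic floor term
`(50 − gd)²` activates at shear rates at or below 50 1/s, and the
shear-rate box is additionally raised to [50, 100]. Note: a signed
variant of the below-window penalty (which would reward undershoot) is
sometimes written down; it is available via `signed=True` but is not
the default. Minimized F = f + penalty.

**Differential evolution** is hand-written rand/1/bin: population
15×dim, mutation F = 0.8, crossover CR = 0.9, synchronous
generation-based selection, bounds enforced by clipping, stopping when
the population objective spread falls below 1e-8 (relative) or at 1000
generations. The objective is evaluated one batch per generation so
forest surrogates stay fast. Convergence is cross-checked against
`scipy.optimize.differential_evolution` on analytic functions and
against dense grid oracles on tree surrogates.

Outcomes on the default dataset: the free scenario reaches the window
midpoint within ±0.1 at low shear; the high-shear scenario tops out
below the window's lower edge (the ink is too thin at nozzle-tip shear
rates), reported as out-of-window.

## Printability metrics

Diffusion rate DR = FW/ND × 100 (%); pore circularity
C = 4π·Aa/L²; pore printability Pr = L²/(16·Aa). By construction
Pr·C ≡ π/4; a square pore gives Pr = 1, a circle C = 1. Pore
measurements must satisfy the isoperimetric inequality L² ≥ 4π·Aa.
The composition descriptor G/(A·T) tracks filament shape fidelity
(lower is better); reported values are truncated — not rounded — to
two decimals.

## Pipeline and reproducibility

The pipeline runs generate → fit_rheology → train → evaluate → optimize
fail-fast, persisting every artifact as CSV/JSON under
`<out>/<stage>/`. Per-stage seeds are derived from the master seed by
SHA-256 of `"<seed>:<stage>"` (first 4 bytes, mod 2³¹−1), so stages are
independently reproducible and two runs with the same config are
byte-identical.

## Limitations

- All data are synthetic, regenerated from eight characterized
  parameter rows; nothing here validates against raw rheometer sweeps.
- The composition design (8 points on one plane) caps the polynomial
  surrogate's holdout accuracy and makes all surrogates untrustworthy
  off the A + G + T = 8 plane; search bounds are therefore taken from
  the observed data ranges.
- Tree and forest predictions are piecewise constant; optima returned
  on their surfaces identify a region, not a unique point.
- The thixotropy module provides the protocol and a closed-form
  synthetic trace; no measured recovery traces are included.
- Oscillatory characterization (storage/loss moduli), microscopy and
  biological response are out of scope.
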