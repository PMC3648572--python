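# Methods

## Model

Cell density N(t) (cells/mL) of a *Dunaliella salina* culture on a
light:dark photoperiod follows

    dN/dt = γ · I(t) · N · (1 − N / (κ·M))  −  δ · (1 − I(t)) · N

with I(t) a binary square wave (1 in light, 0 in dark; default 13 h:11 h
over a 24-h period, dark fraction 11/24 = 45.8 %). At an instant of
transition the new phase applies (half-open segments `[start, end)`).

The memory variable M implements a ratcheting carrying ceiling: during
darkness M ≡ N (instantaneous tracking), during light M holds the value N
had at dawn, so the daytime logistic ceiling κ·M rises cycle over cycle
while net growth is positive. The reset is modelled as instantaneous
rather than with a finite relaxation rate; a relaxation constant would add
a fourth parameter that count data sampled every 2 h cannot resolve.
Darkness drives simple exponential decay at rate δ, reflecting
programmed-cell-death kinetics of cells with little tolerance to darkness;
there is no coupled state for the archaeal partner or for glycerol inside
the ODE.

### Assumptions

* Growth occurs only in light and death only in dark; the two terms never
  act simultaneously.
* The ceiling is proportional to the dawn density (κ·M), not to an
  internal cell quota.
* The model is linear in N up to the ceiling, which itself scales with N₀;
  fits are therefore invariant to uniform rescaling of the counts.

## Numerics

Both phases have exact solutions — logistic
`N(τ) = K / (1 + (K/N_a − 1)·e^(−γτ))` with `K = κ·M_dawn`, and
exponential `N(τ) = N_b·e^(−δτ)` — so the default integrator walks the
phase segments and evaluates the closed forms; no solver step ever
straddles a light/dark discontinuity. `simulate(..., method="numeric")`
integrates the same piecewise right-hand side with RK45 (rtol 1e-10,
per-segment restart) and is used as an independent cross-check; the two
routes agree to better than 1e-6 relative error across broad random
parameter ranges.

Derived diel quantities are closed-form: dark half-life ln 2/δ, burst
doubling time ln 2/γ, nightly loss fraction 1 − e^(−δ·t_dark). The
per-cycle growth factor is κ·e^(−δ·t_dark) whenever the culture saturates
by dusk (N_dusk ≥ 99 % of the ceiling, checked by simulation); otherwise
the simulated dawn-to-dawn ratio is returned and the analytic value is
flagged as inapplicable. Net doubling time is `period·ln 2 / ln(factor)`.

## Fitting

Each replicate is fit independently. N₀ (and M₀ = N₀) is fixed to the
replicate's first observation — it is an input of the experiment, not a
free parameter — leaving (γ, δ, κ) to bounded nonlinear least squares
(scipy TRF, finite-difference Jacobian) on raw-count residuals, scaled by
the mean count purely for conditioning. Bounds: γ ∈ (0, 5], δ ∈ (0, 2],
κ ∈ (1, 100]. Because the square-wave forcing makes the SSE surface
piecewise in parameter space, each fit uses 5 starts: the configured
initial values plus 4 multiplicatively jittered copies (±20 %, seeded);
the lowest raw-count SSE wins, ties broken by lowest γ. An optional
log-scale loss is available but off by default, matching the raw-count SSE
definition of the fit. Default starting values per condition: pure culture
γ=0.6262, δ=0.0957, κ=12.5813; co-culture γ=0.4940, δ=0.1141, κ=12.5813.

Cross-replicate statistics are computed across the per-replicate point
estimates: mean, sd, sem, and a t-based 95 % interval half-width
`t(0.975, n−1)·sd/√n`, requiring at least two replicates. No
curvature-based (Hessian) intervals are reported, as replicate scatter is
the relevant uncertainty for triplicate cultures. Adjusted R² is
`1 − (1 − R²)(n − 1)/(n − p − 1)` with p = 3 fitted parameters; it is
undefined (raises) when the observed series has zero variance. A Welch
two-sample t-test on per-replicate δ is provided as a convenience for
condition comparisons; it is not part of any validated output.

## Synthetic data generator

The generator emulates the laboratory design the fitting stage assumes:
triplicate cultures, sampling every 2 h, four 24-h cycles, inoculated at
9,000 cells/mL (pure culture) or 12,500 cells/mL (co-culture). Default
generating parameters per condition are the representative fitted values
(pure: γ=0.678 hr⁻¹, δ=0.069 hr⁻¹, κ=8.10; co-culture: γ=0.551 hr⁻¹,
δ=0.119 hr⁻¹, κ=9.93), which produce 2–3 daytime doublings to saturation
and roughly half the population lost per night.

Measurement noise is multiplicative lognormal with median exactly 1
(σ = √ln(1+CV²)), default CV 0.10: counts are positive and cytometry error
scales with abundance. CV 0.10 is a package default, not a measured value.
Poisson counting noise is deliberately omitted because cytometry counts
are large. Replicate r draws from `SeedSequence(seed, spawn_key=(r,))`, so
output is bit-reproducible and adding replicates never perturbs earlier
streams.

What the generator does **not** emulate: day-to-day drift in γ or δ,
autocorrelated (instrument) error, inter-replicate biological variability
in the true parameters, or any archaeal feedback on algal death. Passing
recovery tests therefore demonstrates identifiability of the model under
its own noise assumptions, not robustness to real-data misspecification.

Companion series: nightly death fractions (closed-form 1 − e^(−δ·t_dark)
with the same multiplicative noise, truncated into [0, 1)) and glycerol
series, where the extracellular concentration accumulates the release from
cells lost between successive samples and the intracellular pool is held
constant (default 4 M, optional fractional nighttime dip — reported
intracellular pools are roughly constant with a slight night drop, and the
data do not constrain more structure).

## Glycerol mass balance

Extracellular glycerol released by dying cells:

    C_ext [µM] = c_int [mol/L] · (v_eff·1e-15 L/cell) · (n_dead·1e3 cell/L) · 1e6

With c_int = 4 M and n_dead = 3×10⁵ mL⁻¹, an effective released volume of
58 µm³ per cell yields 69.6 µM — the observed ~70 µM scale. A single 1-µm³
secretory granule per cell is numerically far too small to close this
budget (it would give ~1.2 nM), so v_eff is kept as an explicit free input
with default 58 µm³, the value implied by inverting the budget at 70 µM;
`implied_volume` performs that inversion exactly. OD600 conversion uses
8×10⁸ cells/mL per OD unit (the *H. salinarum* culture calibration).

## Pipeline

`run_pipeline` (and the `dielgrowth report` subcommand) runs
generate → fit → report from a YAML/JSON configuration with a mandatory
seed; unknown configuration keys are rejected before any stage runs.
Outputs: the observation CSV, per-replicate fit JSON, a flat
parameter-summary CSV (initial values, fitted means, CI95 half-widths),
fitted-model trajectory CSVs, a derived-quantity summary, and a run
manifest recording seeds and versions (no timestamps, so repeat runs are
byte-identical). Exit codes: 2 for input/configuration errors, 3 for
convergence failure.

## Problem sizes and known limitations

Simulation grids in tests and examples use 2-h sampling over 4–8 cycles
(49–97 points); Monte-Carlo recovery checks use 20 seeded triplicate
datasets, which is ample for median-error and interval-coverage checks at
the tolerances tested. Known limitations:

* γ is weakly identified when saturation is reached early in the light
  phase (only the few pre-saturation samples constrain it); δ and κ are
  the robustly identified parameters under the default design.
* The per-cycle growth factor's analytic form assumes saturation by dusk;
  the non-saturating branch falls back to simulation and flags itself.
* Aggregating ln 2/γ across replicates is not the same as ln 2/(mean γ)
  (Jensen's inequality); summary doubling times computed from mean rates
  can differ from means of per-replicate doubling times. The package
  computes quantities from the aggregated means and does not attempt to
  reconcile the two conventions.
* Adjusted R² of fits to real cytometry data depends on the actual error
  structure; the synthetic generator cannot validate those figures.
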