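# dielgrowth

Diel population dynamics of the halophilic alga *Dunaliella salina*:
simulation and fitting of a light-forced birth–death model, plus the
glycerol mass balance that links nightly programmed cell death (PCD) to
dissolved organic matter release in hypersaline cultures.

The package is for microbial ecologists and modellers who want to simulate
or fit diurnally forced growth/death kinetics from replicate cell-count
time series (e.g. flow-cytometry counts of laboratory cultures on a
light:dark cycle).

## The model

Cell density N (cells/mL) obeys a single piecewise ODE driven by a binary
square-wave irradiance I(t) (13 h light : 11 h dark by default, so dark
occupies 45.8 % of each period):

```
dN/dt = γ · I · N · (1 − N / (κ·M))  −  δ · (1 − I) · N
```

* **γ** — burst growth rate in light (hr⁻¹); low-density doubling time ln 2/γ.
* **δ** — dark-phase death rate (hr⁻¹); population half-life ln 2/δ,
  nightly loss fraction 1 − e^(−δ·t_dark).
* **κ** — saturation scaling factor (> 1); the daytime carrying ceiling is κ·M.
* **M** — a "memory" variable: constant during light at the density observed
  at dawn, equal to N throughout darkness. The ceiling therefore ratchets up
  with each diurnal cycle while net growth is positive.

Both phases have exact solutions (logistic / exponential), so trajectories
are computed segment-by-segment in closed form, with an adaptive
Runge–Kutta route available as an independent cross-check. In the
saturating regime the dawn-to-dawn growth factor is exactly
κ·e^(−δ·t_dark), giving a net doubling time of `period·ln 2 / ln(factor)`.

Fitting minimises the sum of squared errors between the simulated N(t) and
observed counts, per replicate, with N₀ fixed to the first observation
(bounded nonlinear least squares with seeded multi-start). Cross-replicate
means and t-based 95 % confidence intervals summarise each parameter.

A mass-balance module converts dying-cell density, intracellular glycerol
molarity, and an effective per-cell released volume into extracellular
glycerol (µM), and inverts that relation.

## Worked example

```python
import dielgrowth as dg

params = dg.condition_parameters("pure")       # γ=0.678, δ=0.069, κ=8.10, N0=9000
obs = dg.generate_counts(params, noise=dg.NoiseModel(cv=0.10, seed=1))
report = dg.fit_observation_set(obs, random_state=1)
agg = report.aggregate
for name in ("gamma", "delta", "kappa"):
    a = agg[name]
    print(f"{name}: {a['mean']:.3f} +/- {a['ci95_half_width']:.3f} (CI95, n={a['n']})")

summary = dg.derived_summary(agg["gamma"]["mean"], agg["delta"]["mean"],
                             agg["kappa"]["mean"], params.n0)
for k, v in summary.items():
    print(f"{k}: {v:.3f}" if isinstance(v, float) else f"{k}: {v}")
```

prints

```
gamma: 0.673 +/- 0.209 (CI95, n=3)
delta: 0.073 +/- 0.011 (CI95, n=3)
kappa: 8.224 +/- 1.614 (CI95, n=3)
half_life_h: 9.471
burst_doubling_time_h: 1.030
per_cycle_growth_factor: 3.677
saturating_regime: True
net_doubling_time_h: 12.777
nightly_death_fraction: 0.553
```

Three synthetic triplicate cultures (10 % lognormal measurement noise,
2-h sampling, four diurnal cycles) were generated from the pure-culture
parameter preset and re-fitted: the recovered rates bracket the generating
values, the population halves in roughly 9.5 h of darkness, loses ~55 % of
cells per night, and still nets one doubling every ~12.8 h across full
cycles because each day ends at the ratcheting saturation ceiling.

The same flow is available from the shell:

```sh
dielgrowth generate --seed 1 --out obs.csv
dielgrowth fit --input obs.csv --out fit.json --table fit.csv
dielgrowth budget --c-int 4 --v-eff 58 --n-dead 3e5
# {"c_ext_uM": 69.6, "c_int_M": 4.0, "n_dead_per_ml": 300000.0, "v_eff_um3": 58.0}
dielgrowth report --config config.yaml     # full generate -> fit -> report pipeline
```

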