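"""Synthetic replicate datasets emulating the diel culture experiments.

The generator reproduces the statistical structure of the study design the
fitting stage assumes: triplicate cultures sampled every 2 h over several
13 h:11 h diurnal cycles, inoculated near 9,000 (pure culture) or 12,500
(co-culture) cells/mL, growing to saturation during the day and losing
roughly half the population each night. Measurement error is multiplicative
lognormal with median 1 (counts are positive and errors scale with
abundance); Poisson counting noise is deliberately omitted because
cytometry counts are large.

Replicate ``r`` draws from ``SeedSequence(seed, spawn_key=(r,))``, so adding
replicates never perturbs earlier ones and identical seeds give bit-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .budget import released_concentration
from .fitting import ObservationSet, Replicate
from .light import LightSchedule
from .model import GrowthParameters, Trajectory, nightly_death_fraction, simulate

__all__ = [
    "ExperimentDesign",
    "NoiseModel",
    "condition_parameters",
    "generate_counts",
    "generate_death_fraction_series",
    "generate_glycerol_series",
    "sampling_times",
]

#: Representative model parameters for the two culture conditions
#: (burst growth rate hr^-1, death rate hr^-1, saturation factor, inoculum).
_CONDITION_PRESETS = {
    "pure": GrowthParameters(gamma=0.678, delta=0.069, kappa=8.10, n0=9000.0),
    "co-culture": GrowthParameters(gamma=0.551, delta=0.119, kappa=9.93, n0=12500.0),
}


def condition_parameters(condition: str = "pure") -> GrowthParameters:
    """Default generating parameters for ``"pure"`` or ``"co-culture"``."""
    try:
        return _CONDITION_PRESETS[condition]
    except KeyError:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of {sorted(_CONDITION_PRESETS)}"
        ) from None


@dataclass(frozen=True)
class ExperimentDesign:
    """Sampling design of a diel growth experiment.

    Defaults mirror the laboratory design: triplicate cultures, 2-h
    sampling, four diurnal cycles, 9,000 cells/mL inoculum.
    """

    n_replicates: int = 3
    sampling_interval_h: float = 2.0
    n_cycles: int = 4
    condition: str = "pure"
    inoculum: float = 9000.0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.sampling_interval_h <= 0:
            raise ValueError("sampling_interval_h must be > 0")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise specification.

    kind "lognormal" applies multiplicative lognormal noise with median 1
    and the given coefficient of variation; kind "none" disables noise.
    """

    kind: str = "lognormal"
    cv: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("lognormal", "none"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")

    @property
    def sigma(self) -> float:
        """Log-scale standard deviation giving the configured CV."""
        return math.sqrt(math.log1p(self.cv**2))

    def replicate_rng(self, index: int) -> np.random.Generator:
        """Deterministic per-replicate stream: SeedSequence(seed, spawn_key=(index,))."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(index,)))

    def multipliers(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "none" or self.cv == 0:
            return np.ones(size)
        return rng.lognormal(mean=0.0, sigma=self.sigma, size=size)


def sampling_times(design: ExperimentDesign, schedule: LightSchedule = LightSchedule()) -> np.ndarray:
    """Sample grid from first light onset through ``n_cycles`` full periods."""
    span = design.n_cycles * schedule.period_h
    n = int(round(span / design.sampling_interval_h))
    return schedule.t0_h + design.sampling_interval_h * np.arange(n + 1)


def generate_counts(
    params: GrowthParameters,
    schedule: LightSchedule = LightSchedule(),
    design: ExperimentDesign = ExperimentDesign(),
    noise: NoiseModel = NoiseModel(),
) -> ObservationSet:
    """Generate replicate cell-count series ``N_model(t_i) * eps_i``.

    ``eps_i`` is lognormal with median 1 and the configured CV, drawn from
    an independent, deterministically sub-seeded stream per replicate.
    """
    times = sampling_times(design, schedule)
    traj = simulate(params, schedule, times)
    reps = []
    for i in range(design.n_replicates):
        eps = noise.multipliers(noise.replicate_rng(i), times.size)
        reps.append(
            Replicate(
                replicate_id=f"r{i + 1}",
                condition=design.condition,
                times=times.copy(),
                counts=traj.N * eps,
            )
        )
    return ObservationSet(tuple(reps))


def generate_death_fraction_series(
    params: GrowthParameters,
    schedule: LightSchedule = LightSchedule(),
    design: ExperimentDesign = ExperimentDesign(),
    noise: NoiseModel = NoiseModel(),
) -> pd.DataFrame:
    """Per-night fraction of the population lost, one row per replicate-night.

    The noiseless value is ``1 - exp(-delta * dark_h)`` every night;
    multiplicative noise is applied and the result truncated into [0, 1).
    """
    base = nightly_death_fraction(params.delta, schedule.dark_h)
    rows = []
    for i in range(design.n_replicates):
        eps = noise.multipliers(noise.replicate_rng(i), design.n_cycles)
        fractions = np.clip(base * eps, 0.0, np.nextafter(1.0, 0.0))
        for night, frac in enumerate(fractions):
            rows.append(
                {"replicate_id": f"r{i + 1}", "night": night, "death_fraction": float(frac)}
            )
    return pd.DataFrame(rows, columns=["replicate_id", "night", "death_fraction"])


def generate_glycerol_series(
    trajectory: Trajectory,
    c_int: float = 4.0,
    v_eff: float = 58.0,
    night_dip_fraction: float = 0.0,
) -> pd.DataFrame:
    """Companion glycerol series for a simulated trajectory.

    Extracellular glycerol (µM) accumulates as the running total of the
    concentration released by cells lost between successive samples
    (losses occur only in the dark phase, where N decays); intracellular
    glycerol (mol/L) is constant at ``c_int``, optionally dipping by
    ``night_dip_fraction`` during dark samples.

    Parameters
    ----------
    c_int : float
        Intracellular glycerol molarity, mol/L (typically 2-5 M).
    v_eff : float
        Effective released volume per dying cell, µm^3.
    night_dip_fraction : float
        Relative nighttime dip of the intracellular pool in [0, 1).
    """
    if not 0.0 <= night_dip_fraction < 1.0:
        raise ValueError("night_dip_fraction must be in [0, 1)")
    dead = np.maximum(-np.diff(trajectory.N, prepend=trajectory.N[0]), 0.0)
    increments = np.array(
        [released_concentration(c_int, v_eff, d) if d > 0 else 0.0 for d in dead]
    )
    extracellular = np.cumsum(increments)
    intracellular = np.where(
        trajectory.phase == 0, c_int * (1.0 - night_dip_fraction), c_int
    )
    return pd.DataFrame(
        {
            "time_h": trajectory.times,
            "glycerol_intracellular_M": intracellular,
            "glycerol_extracellular_uM": extracellular,
        }
    )
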