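"""Square-wave light forcing for diel culture experiments.

Irradiance is idealised as a binary square wave: ``1`` during the light
phase, ``0`` during the dark phase. The default schedule is the 13 h:11 h
light:dark photoperiod used for hypersaline *Dunaliella salina* cultures,
so dark occupies 11/24 = 45.8 % of each period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LightSchedule", "irradiance"]


@dataclass(frozen=True)
class LightSchedule:
    """A periodic light:dark square wave.

    Parameters
    ----------
    period_h : float
        Full period in hours (default 24).
    light_h : float
        Duration of the light phase (irradiance 1) in hours (default 13).
    dark_h : float
        Duration of the dark phase (irradiance 0) in hours (default 11).
    t0_h : float
        Time of the first light onset in hours (default 0). Light phases
        occupy ``[t0 + k*period, t0 + k*period + light_h)``.
    """

    period_h: float = 24.0
    light_h: float = 13.0
    dark_h: float = 11.0
    t0_h: float = 0.0

    def __post_init__(self) -> None:
        if self.period_h <= 0 or self.light_h <= 0 or self.dark_h <= 0:
            raise ValueError("all schedule durations must be positive")
        if abs(self.light_h + self.dark_h - self.period_h) > 1e-9:
            raise ValueError(
                f"light_h + dark_h must equal period_h "
                f"({self.light_h} + {self.dark_h} != {self.period_h})"
            )

    @property
    def dark_fraction(self) -> float:
        """Fraction of the period spent in darkness (11/24 = 0.458 by default)."""
        return self.dark_h / self.period_h

    def is_light(self, t):
        """Vectorised light-phase indicator at time(s) ``t`` (hours)."""
        t = np.asarray(t, dtype=float)
        phase = np.mod(t - self.t0_h, self.period_h)
        # np.mod can round to exactly period_h for tiny negative arguments
        phase = np.where(phase >= self.period_h, phase - self.period_h, phase)
        return phase < self.light_h


def irradiance(t, schedule: LightSchedule = LightSchedule()):
    """Square-wave irradiance, exactly 0 (dark) or 1 (light).

    Half-open phase convention: at a transition instant the new phase
    applies, so ``irradiance(t0) == 1`` and ``irradiance(t0 + light_h) == 0``.
    Total and periodic in ``t`` with period ``schedule.period_h``.
    """
    out = schedule.is_light(t).astype(int)
    return out if out.ndim else int(out)
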