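"""CSV/JSON input and output for observations, trajectories and fit reports.

Schemas
-------
observations : ``time_h,replicate_id,condition,cells_per_ml``
trajectory   : ``time_h,phase,N_cells_per_ml,M_cells_per_ml``
fit report   : JSON (per-replicate records + aggregate) and a flat CSV with
               one row per parameter per condition (initial, fitted, CI95).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import DEFAULT_INIT, FitReport, ObservationSet, Replicate
from .model import Trajectory

__all__ = [
    "OBSERVATION_COLUMNS",
    "TRAJECTORY_COLUMNS",
    "read_observations",
    "write_observations",
    "read_trajectory",
    "write_trajectory",
    "write_fit_report_json",
    "write_fit_report_csv",
]

OBSERVATION_COLUMNS = ["time_h", "replicate_id", "condition", "cells_per_ml"]
TRAJECTORY_COLUMNS = ["time_h", "phase", "N_cells_per_ml", "M_cells_per_ml"]


class ObservationFormatError(ValueError):
    """Raised when an observation CSV violates the schema."""


def _line(df_index: int) -> int:
    # +2: one for the header row, one for 1-based numbering
    return int(df_index) + 2


def read_observations(path) -> ObservationSet:
    """Read and validate a replicate observation CSV.

    Malformed rows (non-numeric or non-positive counts, unsorted times) are
    reported with their file line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in OBSERVATION_COLUMNS if c not in df.columns]
    if missing:
        raise ObservationFormatError(f"{path}: missing columns {missing}")

    counts = pd.to_numeric(df["cells_per_ml"], errors="coerce")
    bad = df.index[counts.isna()]
    if len(bad):
        raise ObservationFormatError(
            f"{path}: non-numeric cells_per_ml on line(s) {[_line(i) for i in bad]}"
        )
    nonpos = df.index[counts <= 0]
    if len(nonpos):
        raise ObservationFormatError(
            f"{path}: non-positive cells_per_ml on line(s) {[_line(i) for i in nonpos]}"
        )
    times = pd.to_numeric(df["time_h"], errors="coerce")
    badt = df.index[times.isna()]
    if len(badt):
        raise ObservationFormatError(
            f"{path}: non-numeric time_h on line(s) {[_line(i) for i in badt]}"
        )

    reps = []
    for (rep_id, condition), grp in df.groupby(["replicate_id", "condition"], sort=True):
        t = times[grp.index].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            k = int(np.argmax(np.diff(t) <= 0))
            raise ObservationFormatError(
                f"{path}: times not strictly increasing for replicate {rep_id!r} "
                f"near line {_line(grp.index[k + 1])}"
            )
        reps.append(
            Replicate(
                replicate_id=str(rep_id),
                condition=str(condition),
                times=t,
                counts=counts[grp.index].to_numpy(dtype=float),
            )
        )
    if not reps:
        raise ObservationFormatError(f"{path}: no observation rows")
    return ObservationSet(tuple(reps))


def write_observations(observations: ObservationSet, path) -> None:
    frames = [
        pd.DataFrame(
            {
                "time_h": rep.times,
                "replicate_id": rep.replicate_id,
                "condition": rep.condition,
                "cells_per_ml": rep.counts,
            }
        )
        for rep in observations
    ]
    pd.concat(frames, ignore_index=True)[OBSERVATION_COLUMNS].to_csv(path, index=False)


def write_trajectory(trajectory: Trajectory, path) -> None:
    pd.DataFrame(
        {
            "time_h": trajectory.times,
            "phase": trajectory.phase,
            "N_cells_per_ml": trajectory.N,
            "M_cells_per_ml": trajectory.M,
        }
    )[TRAJECTORY_COLUMNS].to_csv(path, index=False)


def read_trajectory(path) -> Trajectory:
    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return Trajectory(
        times=df["time_h"].to_numpy(dtype=float),
        N=df["N_cells_per_ml"].to_numpy(dtype=float),
        M=df["M_cells_per_ml"].to_numpy(dtype=float),
        phase=df["phase"].to_numpy(dtype=int),
    )


def write_fit_report_json(report: FitReport, path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")


def write_fit_report_csv(report: FitReport, path) -> None:
    """Flat per-parameter summary table: initial, fitted mean, CI95 half-width."""
    rows = []
    for cond in sorted({r.condition for r in report.per_replicate}):
        init = DEFAULT_INIT.get(cond, DEFAULT_INIT["pure"])
        for name in ("gamma", "delta", "kappa"):
            agg = report.aggregate.get(name, {})
            rows.append(
                {
                    "condition": cond,
                    "parameter": name,
                    "units": "hr^-1" if name in ("gamma", "delta") else "-",
                    "initial": init[name],
                    "fitted_mean": agg.get("mean", float("nan")),
                    "ci95_half_width": agg.get("ci95_half_width", float("nan")),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")
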