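"""CSV interchange for area curves, force curves and piston trajectories.

Curves travel as long-format CSV with one row per subject-frame::

    subject_id,time_frac,asa_cm2,vsa_endo_cm2,vsa_epi_cm2

Decimal point, comma separator, header required.  Schema violations are
reported with the offending CSV line number (header = line 1).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError
from .geometry_synth import AreaCurve, CyclePhases, SubjectGeometry
from .hydraulics import ForceCurve
from .piston_sim import PistonTrajectory

__all__ = [
    "CURVE_COLUMNS",
    "write_curves_csv",
    "read_curves_csv",
    "write_forces_csv",
    "write_trajectory_csv",
]

log = logging.getLogger(__name__)

CURVE_COLUMNS = ["subject_id", "time_frac", "asa_cm2", "vsa_endo_cm2", "vsa_epi_cm2"]
FORCE_COLUMNS = ["subject_id", "time_frac", "force_endo_N", "force_epi_N"]


def write_curves_csv(cohort: Sequence[SubjectGeometry], path) -> None:
    """Write a cohort's three area curves in long format (6-decimal areas)."""
    frames = []
    for s in cohort:
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": s.subject_id,
                    "time_frac": s.times,
                    "asa_cm2": s.asa.areas,
                    "vsa_endo_cm2": s.vsa_endo.areas,
                    "vsa_epi_cm2": s.vsa_epi.areas,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=CURVE_COLUMNS)
    df.to_csv(path, index=False, float_format="%.10g")


def read_curves_csv(path, phases: CyclePhases | None = None) -> list[SubjectGeometry]:
    """Read subject geometries back from the long-format curve CSV.

    ``phases`` supplies the cycle landmarks (they are configuration, not
    data, and are not stored in the CSV); defaults to the standard phases.
    """
    phases = phases or CyclePhases()
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file, expected header {CURVE_COLUMNS}") from exc
    missing = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        log.warning("%s: header only, returning an empty cohort", path)
        return []

    lines = df.index.to_numpy() + 2  # CSV line numbers (header = line 1)
    for col in CURVE_COLUMNS[1:]:
        bad = ~np.isfinite(pd.to_numeric(df[col], errors="coerce").to_numpy())
        if bad.any():
            raise SchemaError(f"{path} line {lines[bad][0]}: non-numeric value in {col!r}")
    for col in CURVE_COLUMNS[2:]:
        bad = df[col].to_numpy() <= 0
        if bad.any():
            raise SchemaError(f"{path} line {lines[bad][0]}: non-positive area in {col!r}")
    bad = df["vsa_epi_cm2"].to_numpy() < df["vsa_endo_cm2"].to_numpy()
    if bad.any():
        raise SchemaError(
            f"{path} line {lines[bad][0]}: vsa_epi_cm2 smaller than vsa_endo_cm2"
        )

    cohort = []
    for sid, g in df.groupby("subject_id", sort=False):
        t = g["time_frac"].to_numpy(dtype=float)
        if not np.all(np.diff(t) > 0):
            row = int(g.index.to_numpy()[np.argmin(np.diff(t) > 0) + 1]) + 2
            raise SchemaError(f"{path} line {row}: time_frac not strictly increasing "
                              f"for subject {sid!r}")
        curves = {
            col: AreaCurve(subject_id=str(sid), chamber=ch, times=t,
                           areas=g[col].to_numpy(dtype=float))
            for col, ch in (("asa_cm2", "asa"), ("vsa_endo_cm2", "vsa_endo"),
                            ("vsa_epi_cm2", "vsa_epi"))
        }
        cohort.append(
            SubjectGeometry(asa=curves["asa_cm2"], vsa_endo=curves["vsa_endo_cm2"],
                            vsa_epi=curves["vsa_epi_cm2"], phases=phases)
        )
    return cohort


def write_forces_csv(
    cohort: Sequence[SubjectGeometry], force_curves: Sequence[ForceCurve], path
) -> None:
    """Write per-subject diastolic force curves in long format."""
    frames = []
    for s, fc in zip(cohort, force_curves):
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": s.subject_id,
                    "time_frac": fc.times,
                    "force_endo_N": fc.force_endo,
                    "force_epi_N": fc.force_epi,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=FORCE_COLUMNS)
    df.to_csv(path, index=False, float_format="%.10g")


def write_trajectory_csv(traj: PistonTrajectory, path) -> None:
    """Write a piston trajectory (t_s, x_m, v_m_s, h_m, force_N)."""
    traj.to_dataframe().to_csv(path, index=False, float_format="%.10g")
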