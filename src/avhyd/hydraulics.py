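"""Net hydraulic force on the AV plane from Pascal's principle.

During diastole the mitral valve is open, so the left atrium and ventricle
are hydraulically one chamber at a common pressure P.  That pressure acts on
the atrial short-axis area from one side of the AV plane and on the
ventricular short-axis area from the other; because the areas differ, a net
longitudinal force

    F = P_lv * VSA - P_la * ASA

pushes the plane apex-to-base (toward the atrium) whenever the ventricular
side is larger.  Computation is done in SI (Pa, m², N); cm² and mmHg appear
only at the interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, InvalidParameterError
from .geometry_synth import SubjectGeometry

__all__ = [
    "MMHG_TO_PA",
    "CM2_TO_M2",
    "PressureModel",
    "ForceCurve",
    "mmhg_to_pa",
    "pa_to_mmhg",
    "net_hydraulic_force",
    "force_curve",
    "fraction_diastole_positive",
]

#: Exact definition of the conventional millimetre of mercury.
MMHG_TO_PA = 133.322368
CM2_TO_M2 = 1e-4


def mmhg_to_pa(p):
    """Convert pressure from mmHg to Pa (sign-preserving)."""
    return np.asarray(p, dtype=float) * MMHG_TO_PA if np.ndim(p) else float(p) * MMHG_TO_PA


def pa_to_mmhg(p):
    """Convert pressure from Pa to mmHg."""
    return np.asarray(p, dtype=float) / MMHG_TO_PA if np.ndim(p) else float(p) / MMHG_TO_PA


@dataclass(frozen=True)
class PressureModel:
    """Diastolic chamber pressures in mmHg.

    With ``equal_pressure`` set (the default, reflecting an open mitral valve
    and no transmitral gradient during diastasis) the two pressures must
    agree; 10 mmHg is a normal mean LV diastolic pressure.
    """

    p_la: float = 10.0
    p_lv: float = 10.0
    equal_pressure: bool = True

    def __post_init__(self) -> None:
        if self.p_la < 0 or self.p_lv < 0:
            raise InvalidParameterError("chamber pressures must be >= 0 mmHg")
        if self.equal_pressure and self.p_la != self.p_lv:
            raise InvalidParameterError(
                f"equal-pressure mode requires p_la == p_lv, got {self.p_la} and {self.p_lv}"
            )


@dataclass(frozen=True)
class ForceCurve:
    """Longitudinal net force (N) over diastole for both VSA definitions."""

    times: np.ndarray
    force_endo: np.ndarray
    force_epi: np.ndarray
    t_es: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        fe = np.asarray(self.force_endo, float)
        fp = np.asarray(self.force_epi, float)
        for name, arr in (("times", t), ("force_endo", fe), ("force_epi", fp)):
            object.__setattr__(self, name, arr)
        if t.size == 0:
            raise DomainError("force curve must contain at least one frame")
        if fe.shape != t.shape or fp.shape != t.shape:
            raise InvalidParameterError("force arrays must match the time grid")
        if not np.all(np.diff(t) > 0):
            raise InvalidParameterError("times must be strictly increasing")
        if t[0] < self.t_es - 1e-12 or t[-1] > 1.0 + 1e-12:
            raise InvalidParameterError("force-curve times must lie within diastole [t_es, 1]")

    def component(self, which: str) -> np.ndarray:
        if which not in ("endo", "epi"):
            raise DomainError(f"which must be 'endo' or 'epi', got {which!r}")
        return self.force_endo if which == "endo" else self.force_epi


def net_hydraulic_force(vsa, asa, p_lv: float, p_la: float):
    """Net apex-to-base force (N) from areas in cm² and pressures in mmHg.

    Positive values push the AV plane toward the base (aiding filling).
    Accepts scalars or arrays for the areas.
    """
    vsa = np.asarray(vsa, dtype=float)
    asa = np.asarray(asa, dtype=float)
    if np.any(vsa <= 0) or np.any(asa <= 0):
        raise DomainError("short-axis areas must be strictly positive")
    if p_lv < 0 or p_la < 0:
        raise DomainError("pressures must be >= 0 mmHg")
    f = mmhg_to_pa(p_lv) * vsa * CM2_TO_M2 - mmhg_to_pa(p_la) * asa * CM2_TO_M2
    return float(f) if f.ndim == 0 else f


def force_curve(subject: SubjectGeometry, pressures: PressureModel | None = None) -> ForceCurve:
    """Per-frame net hydraulic force over diastole for one subject.

    Diastole is the normalized interval [t_es, 1]; the subject's grid always
    contains t_es, so the curve starts exactly at end systole.
    """
    pressures = pressures or PressureModel()
    t = subject.times
    mask = t >= subject.phases.t_es - 1e-12
    return ForceCurve(
        times=t[mask],
        force_endo=net_hydraulic_force(
            subject.vsa_endo.areas[mask], subject.asa.areas[mask], pressures.p_lv, pressures.p_la
        ),
        force_epi=net_hydraulic_force(
            subject.vsa_epi.areas[mask], subject.asa.areas[mask], pressures.p_lv, pressures.p_la
        ),
        t_es=subject.phases.t_es,
    )


def fraction_diastole_positive(fc: ForceCurve, which: str = "endo") -> float:
    """Fraction of diastolic time with strictly positive net force.

    The sampled force is treated as piecewise linear and zero crossings are
    located by linear interpolation, so the result does not depend on the
    grid resolution beyond the curve's own sampling.
    """
    f = fc.component(which)
    t = fc.times
    if t.size < 2:
        raise DomainError("need at least two frames to measure a duration")
    t0, t1 = t[:-1], t[1:]
    f0, f1 = f[:-1], f[1:]
    dt = t1 - t0
    pos = np.zeros_like(dt)
    both_pos = (f0 > 0) & (f1 > 0)
    pos[both_pos] = dt[both_pos]
    # sign change within a segment: measure the positive sub-interval
    change = (f0 > 0) != (f1 > 0)
    change &= f0 != f1
    with np.errstate(divide="ignore", invalid="ignore"):
        tc = np.where(change, t0 + (0.0 - f0) / np.where(change, f1 - f0, 1.0) * dt, 0.0)
    down = change & (f0 > 0)
    up = change & (f1 > 0)
    pos[down] = tc[down] - t0[down]
    pos[up] = t1[up] - tc[up]
    # boundary-touching segments (one endpoint exactly zero, other positive)
    zero_then_pos = (f0 == 0) & (f1 > 0)
    pos_then_zero = (f0 > 0) & (f1 == 0)
    pos[zero_then_pos] = dt[zero_then_pos]
    pos[pos_then_zero] = dt[pos_then_zero]
    return float(pos.sum() / (t[-1] - t[0]))
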