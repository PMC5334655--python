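"""Synthetic short-axis area curves of the left atrium and ventricle.

The left atrioventricular (AV) plane moves piston-like along the apex–base
axis.  The net hydraulic force acting on it depends on the largest short-axis
cross-sections on either side: the atrial short-axis area (ASA) and the
ventricular short-axis area measured at the endocardial (``vsa_endo``) or
epicardial (``vsa_epi``) border.  This module generates cohorts of
area–time curves over a normalized cardiac cycle (t = 0 at end diastole,
t = 1 at the next end diastole) with the temporal structure seen in healthy
volunteers: the atrium is largest at end systole, the ventricle smallest;
during diastole the endocardial ventricular area crosses above the atrial
area at a configurable fraction of the cycle, while the epicardial area
exceeds the atrial area throughout.

Curves are piecewise half-cosine (cosine-eased) interpolants through a small
set of landmark areas.  Half-cosine segments are monotone between landmarks
and have a closed-form midpoint, which keeps both the physiology and the
tests honest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import GenerationError, InfeasibleAnchorError, InvalidParameterError, DomainError

__all__ = [
    "CyclePhases",
    "ChamberLandmarks",
    "AreaCurve",
    "SubjectGeometry",
    "CohortParams",
    "build_curve",
    "generate_subject",
    "generate_cohort",
    "population_mean_subject",
    "area_at",
    "CHAMBERS",
]

CHAMBERS = ("asa", "vsa_endo", "vsa_epi")

#: End systole derived from two facts about the mean curves: the endocardial
#: crossover sits at 53% of the cycle and spans 75% of diastole, hence
#: (1 - 0.53) / (1 - t_es) = 0.75.
DEFAULT_T_ES = 1.0 - 0.47 / 0.75

_MERGE_TOL = 1e-8  # grid times closer than this are considered duplicates


@dataclass(frozen=True)
class CyclePhases:
    """Normalized-cycle landmarks: end systole, endocardial crossover,
    mid diastasis and atrial-kick onset, all strictly inside (0, 1)."""

    t_es: float = DEFAULT_T_ES
    t_cross_endo: float = 0.53
    t_dd: float = 0.70
    t_ak: float = 0.90

    def __post_init__(self) -> None:
        seq = (0.0, self.t_es, self.t_cross_endo, self.t_dd, self.t_ak, 1.0)
        if not all(a < b for a, b in zip(seq, seq[1:])):
            raise InvalidParameterError(
                "cycle phases must satisfy 0 < t_es < t_cross_endo < t_dd < t_ak < 1, "
                f"got t_es={self.t_es}, t_cross_endo={self.t_cross_endo}, "
                f"t_dd={self.t_dd}, t_ak={self.t_ak}"
            )


@dataclass(frozen=True)
class ChamberLandmarks:
    """Chamber area (cm²) at end diastole, end systole and mid diastasis."""

    a_ed: float
    a_es: float
    a_dd: float

    def __post_init__(self) -> None:
        for name in ("a_ed", "a_es", "a_dd"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise InvalidParameterError(f"landmark {name} must be finite and > 0, got {v}")

    def shifted(self, delta: float) -> "ChamberLandmarks":
        """Landmarks translated by a common level offset (cm²)."""
        return ChamberLandmarks(self.a_ed + delta, self.a_es + delta, self.a_dd + delta)


@dataclass(frozen=True)
class AreaCurve:
    """One chamber's short-axis area (cm²) on a normalized cycle grid.

    ``times`` is strictly increasing, starts at 0 and ends at 1; the curve is
    periodic (same area at t = 0 and t = 1).
    """

    subject_id: str
    chamber: str
    times: np.ndarray
    areas: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.areas, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "areas", a)
        if t.ndim != 1 or t.shape != a.shape or t.size < 2:
            raise InvalidParameterError("times and areas must be 1-d arrays of equal length >= 2")
        if not (t[0] == 0.0 and t[-1] == 1.0):
            raise InvalidParameterError("time grid must start at 0 and end at 1")
        if not np.all(np.diff(t) > 0):
            raise InvalidParameterError("time grid must be strictly increasing")
        if not np.all(a > 0):
            raise InvalidParameterError("areas must be strictly positive")
        if abs(a[0] - a[-1]) > 1e-9 * max(1.0, abs(a[0])):
            raise InvalidParameterError("curve must be periodic: area(0) must equal area(1)")

    def area_at(self, t) -> np.ndarray | float:
        """Linear interpolation on the stored grid; exact at grid points."""
        ts = np.asarray(t, dtype=float)
        if np.any(ts < 0.0) or np.any(ts > 1.0):
            raise DomainError(f"time must lie in [0, 1], got {t}")
        out = np.interp(ts, self.times, self.areas)
        return float(out) if out.ndim == 0 else out


def area_at(curve: AreaCurve, t) -> np.ndarray | float:
    """Functional alias for :meth:`AreaCurve.area_at`."""
    return curve.area_at(t)


@dataclass(frozen=True)
class SubjectGeometry:
    """A subject's three area curves sharing one time grid, plus phases."""

    asa: AreaCurve
    vsa_endo: AreaCurve
    vsa_epi: AreaCurve
    phases: CyclePhases

    def __post_init__(self) -> None:
        if not (
            np.array_equal(self.asa.times, self.vsa_endo.times)
            and np.array_equal(self.asa.times, self.vsa_epi.times)
        ):
            raise InvalidParameterError("all three curves must share the same time grid")
        if np.any(self.vsa_epi.areas < self.vsa_endo.areas - 1e-9):
            raise InvalidParameterError(
                "vsa_epi must be >= vsa_endo at every sample "
                "(the epicardium encloses the endocardium plus wall)"
            )

    @property
    def subject_id(self) -> str:
        return self.asa.subject_id

    @property
    def times(self) -> np.ndarray:
        return self.asa.times

    def curve(self, chamber: str) -> AreaCurve:
        if chamber not in CHAMBERS:
            raise DomainError(f"unknown chamber {chamber!r}; expected one of {CHAMBERS}")
        return getattr(self, chamber)


def _default_landmarks() -> dict[str, ChamberLandmarks]:
    # Absolute levels are plausible healthy-adult values; only the diastasis
    # differences (7.7 and 25.4 cm² above the atrium) are constrained by the
    # force model, so the levels are free configuration parameters.
    return {
        "asa": ChamberLandmarks(a_ed=14.0, a_es=20.0, a_dd=16.0),
        "vsa_endo": ChamberLandmarks(a_ed=26.0, a_es=12.0, a_dd=16.0 + 7.7),
        "vsa_epi": ChamberLandmarks(a_ed=45.0, a_es=38.0, a_dd=16.0 + 25.4),
    }


def _default_subject_sd() -> dict[str, float]:
    # Between-subject sd of the chamber level, cm².  The ventricular values
    # are SEM × sqrt(n) for the printed diastasis-difference SEMs (1.4, 2.3)
    # at n = 10; the atrial level is held fixed so the difference sd equals
    # the ventricular sd.
    return {"asa": 0.0, "vsa_endo": 4.4, "vsa_epi": 7.3}


@dataclass(frozen=True)
class CohortParams:
    """Population-level description of a synthetic cohort."""

    n_subjects: int = 10
    landmarks: Mapping[str, ChamberLandmarks] = field(default_factory=_default_landmarks)
    phases: CyclePhases = field(default_factory=CyclePhases)
    subject_sd: Mapping[str, float] = field(default_factory=_default_subject_sd)
    n_frames: int = 30
    seed: int = 0
    max_redraws: int = 100

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise InvalidParameterError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if self.n_frames < 8:
            raise InvalidParameterError(f"n_frames must be >= 8, got {self.n_frames}")
        missing = [c for c in CHAMBERS if c not in self.landmarks]
        if missing:
            raise InvalidParameterError(f"missing landmarks for chambers: {missing}")
        for c in CHAMBERS:
            sd = self.subject_sd.get(c, 0.0)
            if sd < 0:
                raise InvalidParameterError(f"subject_sd[{c!r}] must be >= 0, got {sd}")
        asa, endo, epi = (self.landmarks[c] for c in CHAMBERS)
        # Sign pattern of the healthy population mean: at end systole the
        # endocardial ventricular area dips below the atrial one while the
        # epicardial stays above; at diastasis both ventricular areas exceed it.
        if not (endo.a_es < asa.a_es < epi.a_es):
            raise InvalidParameterError(
                "population landmarks must satisfy vsa_endo.a_es < asa.a_es < vsa_epi.a_es"
            )
        if not (endo.a_dd > asa.a_dd and epi.a_dd > asa.a_dd):
            raise InvalidParameterError(
                "population landmarks must place both ventricular diastasis areas above the atrial one"
            )

    def sd(self, chamber: str) -> float:
        return float(self.subject_sd.get(chamber, 0.0))


# ---------------------------------------------------------------------------
# curve construction


def _piecewise_cosine(knots: Sequence[tuple[float, float]], t: np.ndarray) -> np.ndarray:
    """Evaluate a piecewise half-cosine interpolant through ``knots`` at ``t``.

    Each segment eases from (t0, v0) to (t1, v1) along
    v0 + (v1 - v0) * (1 - cos(pi * s)) / 2 with s the segment phase, so it is
    monotone between its endpoints and its midpoint value is (v0 + v1) / 2.
    """
    t = np.asarray(t, dtype=float)
    out = np.empty_like(t)
    for (t0, v0), (t1, v1) in zip(knots, knots[1:]):
        mask = (t >= t0 - 1e-15) & (t <= t1 + 1e-15)
        s = np.clip((t[mask] - t0) / (t1 - t0), 0.0, 1.0)
        out[mask] = v0 + (v1 - v0) * 0.5 * (1.0 - np.cos(np.pi * s))
    return out


def _grid(phases: CyclePhases, n_frames: int, extra_times=None) -> np.ndarray:
    base = np.linspace(0.0, 1.0, n_frames + 1)
    pts = [base, [phases.t_es, phases.t_cross_endo, phases.t_dd, phases.t_ak]]
    if extra_times is not None:
        pts.append(np.asarray(extra_times, dtype=float))
    t = np.sort(np.concatenate([np.atleast_1d(np.asarray(p, float)) for p in pts]))
    keep = np.concatenate([[True], np.diff(t) > _MERGE_TOL])
    t = t[keep]
    t[0], t[-1] = 0.0, 1.0
    return t


def build_curve(
    landmarks: ChamberLandmarks,
    phases: CyclePhases,
    n_frames: int = 30,
    anchor: AreaCurve | None = None,
    extra_times=None,
    subject_id: str = "population",
    chamber: str = "asa",
) -> AreaCurve:
    """Build one chamber's area curve through its landmarks.

    The curve passes exactly through ``a_ed`` at t = 0 and t = 1, ``a_es`` at
    end systole and ``a_dd`` at mid diastasis, holds a plateau over diastasis
    (t_dd to t_ak) and returns to ``a_ed`` over the atrial kick.  When
    ``anchor`` (the subject's ASA curve) is given — used for the endocardial
    ventricular curve — an extra knot pins the curve to the anchor's value at
    the crossover time, after which it must exceed the anchor for the rest of
    the cycle.

    Parameters
    ----------
    extra_times
        Additional sample times merged into the uniform grid (the landmark
        times are always included, so interpolation is exact there).
    """
    knots: list[tuple[float, float]] = [(0.0, landmarks.a_ed), (phases.t_es, landmarks.a_es)]
    if anchor is not None:
        a_cross = float(anchor.area_at(phases.t_cross_endo))
        a_ref_es = float(anchor.area_at(phases.t_es))
        if landmarks.a_es >= a_ref_es:
            raise InfeasibleAnchorError(
                "crossover anchor infeasible: end-systolic area "
                f"{landmarks.a_es} is not below the reference curve's {a_ref_es}"
            )
        if a_cross >= landmarks.a_dd:
            raise InfeasibleAnchorError(
                f"crossover anchor infeasible: anchor area {a_cross} at the crossover "
                f"is not below the diastasis landmark {landmarks.a_dd}"
            )
        knots.append((phases.t_cross_endo, a_cross))
    knots += [(phases.t_dd, landmarks.a_dd), (phases.t_ak, landmarks.a_dd), (1.0, landmarks.a_ed)]

    times = _grid(phases, n_frames, extra_times)
    areas = _piecewise_cosine(knots, times)
    curve = AreaCurve(subject_id=subject_id, chamber=chamber, times=times, areas=areas)

    if anchor is not None:
        after = times > phases.t_cross_endo + _MERGE_TOL
        interior = after & (times < 1.0 - _MERGE_TOL)
        if np.any(curve.areas[interior] <= anchor.areas[interior]):
            raise InfeasibleAnchorError(
                "anchored curve does not stay above the reference curve after the crossover"
            )
    return curve


# ---------------------------------------------------------------------------
# subject and cohort generation


def _build_subject(
    landmarks: Mapping[str, ChamberLandmarks],
    phases: CyclePhases,
    n_frames: int,
    subject_id: str,
    extra_times=None,
    anchor_endo: bool = True,
) -> SubjectGeometry:
    asa = build_curve(
        landmarks["asa"], phases, n_frames, subject_id=subject_id, chamber="asa",
        extra_times=extra_times,
    )
    endo = build_curve(
        landmarks["vsa_endo"], phases, n_frames, anchor=asa if anchor_endo else None,
        subject_id=subject_id, chamber="vsa_endo", extra_times=extra_times,
    )
    epi = build_curve(
        landmarks["vsa_epi"], phases, n_frames,
        subject_id=subject_id, chamber="vsa_epi", extra_times=extra_times,
    )
    return SubjectGeometry(asa=asa, vsa_endo=endo, vsa_epi=epi, phases=phases)


def population_mean_subject(params: CohortParams | None = None) -> SubjectGeometry:
    """The noise-free subject built from the population landmarks."""
    params = params or CohortParams()
    return _build_subject(params.landmarks, params.phases, params.n_frames, "population")


def generate_subject(params: CohortParams, subject_index: int) -> SubjectGeometry:
    """Draw one subject: population landmarks plus a per-chamber level effect.

    Each chamber's three landmarks are shifted by a single zero-mean normal
    draw (sd = ``subject_sd[chamber]``), modelling between-subject size
    variation; draws violating a geometric invariant (area positivity, the
    epicardium enclosing the endocardium) are rejected and redrawn, up to
    ``max_redraws`` attempts.  Deterministic given (seed, subject_index).

    The exact-crossover anchor is applied whenever the drawn landmarks permit
    it (always true at zero noise, so sd = 0 reproduces the population curves
    bit for bit); when a draw makes the pinned crossover geometrically
    infeasible the subject keeps the natural crossover its own landmarks
    imply instead of being rejected, so discordant subjects (ventricular
    diastasis area below the atrial one) can occur, as in real cohorts, and
    the configured between-subject sd is not truncated.
    """
    if subject_index < 0:
        raise InvalidParameterError(f"subject_index must be >= 0, got {subject_index}")
    rng = np.random.default_rng((params.seed, subject_index))
    subject_id = f"s{subject_index:03d}"
    for _ in range(params.max_redraws):
        deltas = {c: (rng.normal(0.0, params.sd(c)) if params.sd(c) > 0 else 0.0) for c in CHAMBERS}
        try:
            shifted = {c: params.landmarks[c].shifted(deltas[c]) for c in CHAMBERS}
        except InvalidParameterError:
            continue
        try:
            return _build_subject(shifted, params.phases, params.n_frames, subject_id)
        except InfeasibleAnchorError:
            pass
        except InvalidParameterError:
            continue
        try:
            return _build_subject(shifted, params.phases, params.n_frames, subject_id,
                                  anchor_endo=False)
        except InvalidParameterError:
            continue
    raise GenerationError(
        f"subject {subject_index}: no invariant-satisfying draw in {params.max_redraws} attempts"
    )


def generate_cohort(params: CohortParams) -> list[SubjectGeometry]:
    """Generate ``params.n_subjects`` independent subjects (seeded, reproducible)."""
    return [generate_subject(params, i) for i in range(params.n_subjects)]
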