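"""Peak driving force of LV filling and the hydraulic force's share of it.

The total force accelerating the diastolic inertial load (myocardium plus
blood plus great-vessel roots) is estimated as a literature force-per-unit-
mass (≈25 mN per gram of load in young healthy subjects) times an inertial
load bracket: LV mass ≈ 125 g plus 75–275 g of blood and vessel roots, i.e.
200–400 g, giving a 5–10 N driving-force range.  The net hydraulic force is
then expressed as a fraction of that range.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError, InvalidParameterError

__all__ = [
    "DrivingForceEstimate",
    "inertial_load_range",
    "peak_driving_force",
    "hydraulic_fraction",
    "estimate_driving_force",
]


@dataclass(frozen=True)
class DrivingForceEstimate:
    """Inertial-load bracket (g) and the resulting peak-force bracket (N)."""

    f_per_mass: float  # mN per g of inertial load
    lv_mass: float     # g
    extra_min: float   # g, blood + great-vessel roots, lower bound
    extra_max: float   # g, upper bound
    load_min: float    # g
    load_max: float    # g
    force_min: float   # N
    force_max: float   # N

    def __post_init__(self) -> None:
        vals = (self.f_per_mass, self.lv_mass, self.extra_min, self.extra_max,
                self.load_min, self.load_max, self.force_min, self.force_max)
        if any(v < 0 for v in vals):
            raise InvalidParameterError("all driving-force quantities must be >= 0")
        if not (abs(self.load_min - (self.lv_mass + self.extra_min)) < 1e-9
                and abs(self.load_max - (self.lv_mass + self.extra_max)) < 1e-9):
            raise InvalidParameterError("load bounds must equal lv_mass + extra bounds")
        if self.load_min > self.load_max or self.force_min > self.force_max:
            raise InvalidParameterError("range bounds must be ordered")


def inertial_load_range(lv_mass: float, extra_min: float, extra_max: float) -> tuple[float, float]:
    """Total inertial load bracket in grams: LV mass plus the extra-mass bounds."""
    if lv_mass < 0 or extra_min < 0 or extra_max < 0:
        raise DomainError("masses must be >= 0 g")
    if extra_min > extra_max:
        raise DomainError(f"extra_min ({extra_min}) must not exceed extra_max ({extra_max})")
    return (lv_mass + extra_min, lv_mass + extra_max)


def peak_driving_force(f_per_mass: float, load: float) -> float:
    """Peak driving force in N from mN/g and load in g."""
    if f_per_mass < 0 or load < 0:
        raise DomainError("force-per-mass and load must be >= 0")
    return f_per_mass * load / 1000.0


def hydraulic_fraction(
    fh_min: float, fh_max: float, fd_min: float, fd_max: float
) -> tuple[float, float]:
    """Extreme ratios of the hydraulic-force range to the driving-force range.

    Returns (fh_min / fd_max, fh_max / fd_min): the smallest and largest
    share of the peak driving force the hydraulic force can represent.
    """
    if min(fh_min, fh_max, fd_min, fd_max) <= 0:
        raise DomainError("all forces must be > 0 N")
    if fh_min > fh_max or fd_min > fd_max:
        raise DomainError("range bounds must be ordered")
    return (fh_min / fd_max, fh_max / fd_min)


def estimate_driving_force(
    f_per_mass: float = 25.0,
    lv_mass: float = 125.0,
    extra_min: float = 75.0,
    extra_max: float = 275.0,
) -> DrivingForceEstimate:
    """Bundle the load bracket and force bracket into one estimate."""
    load_min, load_max = inertial_load_range(lv_mass, extra_min, extra_max)
    return DrivingForceEstimate(
        f_per_mass=f_per_mass,
        lv_mass=lv_mass,
        extra_min=extra_min,
        extra_max=extra_max,
        load_min=load_min,
        load_max=load_max,
        force_min=peak_driving_force(f_per_mass, load_min),
        force_max=peak_driving_force(f_per_mass, load_max),
    )
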