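"""Dynamic simulation of the two-area hollow-piston analog of the AV plane.

The rig is a two-chamber housing pressurized by a water column; a hollow
piston separates a small "atrial" end (area ``a_small``) from a large
"ventricular" end (``a_large``).  Because the open conduit through the piston
keeps both chambers at the same pressure, the pressure acting on unequal end
areas yields a net force rho*g*h*(a_large - a_small) toward the small
chamber.  Pulling the piston toward the large chamber plays the role of
systole; on release the hydraulic force alone returns it — the rig's
"diastole".

The piston is a 1-d rigid body between two mechanical stops:

    m * dv/dt = rho*g*h(x)*(a_large - a_small) - f_pull(t) - damping*v

with x = 0 at the systolic stop (piston fully toward the large chamber) and
x = travel at the diastolic stop.  Fluid bookkeeping couples the column
height to the piston position exactly: moving the piston by dx toward the
small chamber draws (a_large - a_small)*dx out of the standpipe, so

    h(x) = h_start - (a_large - a_small) * (x - x_start) / a_column

is enforced as an algebraic constraint (volume is conserved to machine
precision rather than integrator tolerance).  Integration is fixed-step
classical Runge-Kutta with inelastic clamping at the stops (velocity zeroed
on contact).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .errors import DomainError, InvalidParameterError, NumericalFailureError

__all__ = [
    "PistonRig",
    "PistonState",
    "PistonTrajectory",
    "static_net_force",
    "simulate_release",
    "simulate_stroke",
]


@dataclass(frozen=True)
class PistonRig:
    """Geometry and lumped mechanical parameters of the physical analog.

    Defaults give a static hydraulic force of about 10 N under a 1.4 m water
    column (rho*g*h*dA ≈ 1000 * 9.81 * 1.4 * 7.3e-4).  Piston mass, damping
    and travel are plausible bench values; they are exposed because the rig's
    qualitative behaviour, not a specific trajectory, is the point.
    """

    a_small: float = 1.00e-3   # m², atrial-side end
    a_large: float = 1.73e-3   # m², ventricular-side end
    a_column: float = 5.0e-4   # m², standpipe cross-section
    h0: float = 1.4            # m, initial column height above the piston axis
    rho: float = 1000.0        # kg/m³
    g: float = 9.81            # m/s²
    m_piston: float = 0.5      # kg
    damping: float = 50.0      # N·s/m, conduit + seal losses lumped
    travel: float = 0.03       # m, systolic stop to diastolic stop

    def __post_init__(self) -> None:
        # equal areas are admitted as the degenerate zero-force rig
        if self.a_small > self.a_large:
            raise InvalidParameterError(
                f"a_small ({self.a_small}) must not exceed a_large ({self.a_large})"
            )
        positive = {
            "a_small": self.a_small, "a_column": self.a_column, "h0": self.h0,
            "rho": self.rho, "g": self.g, "m_piston": self.m_piston, "travel": self.travel,
        }
        for name, v in positive.items():
            if not v > 0:
                raise InvalidParameterError(f"{name} must be > 0, got {v}")
        if self.damping < 0:
            raise InvalidParameterError(f"damping must be >= 0, got {self.damping}")

    @property
    def delta_area(self) -> float:
        return self.a_large - self.a_small


@dataclass(frozen=True)
class PistonState:
    """Instantaneous piston state: position, velocity, column height, time."""

    x: float
    v: float
    h: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.h < 0:
            raise InvalidParameterError(f"column height must be >= 0, got {self.h}")


@dataclass(frozen=True)
class PistonTrajectory:
    """Time-ordered state history plus exact fluid bookkeeping."""

    t: np.ndarray
    x: np.ndarray
    v: np.ndarray
    h: np.ndarray
    force: np.ndarray          # static net force (hydraulic - external), N
    rig: PistonRig
    displaced_volume: np.ndarray = field(init=False)  # m³ drawn from the column

    def __post_init__(self) -> None:
        for name in ("t", "x", "v", "h", "force"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not np.all(np.diff(self.t) > 0):
            raise InvalidParameterError("trajectory times must be strictly increasing")
        if np.any(self.x < -1e-12) or np.any(self.x > self.rig.travel + 1e-12):
            raise InvalidParameterError("piston position left the [0, travel] range")
        object.__setattr__(self, "displaced_volume", self.rig.a_column * (self.h[0] - self.h))

    @property
    def final(self) -> PistonState:
        return PistonState(x=float(self.x[-1]), v=float(self.v[-1]),
                           h=float(self.h[-1]), t=float(self.t[-1]))

    def dissipated_energy(self) -> float:
        """Energy lost to damping, J (trapezoidal integral of damping * v²)."""
        return float(np.trapezoid(self.rig.damping * self.v**2, self.t))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_s": self.t, "x_m": self.x, "v_m_s": self.v, "h_m": self.h, "force_N": self.force}
        )


def static_net_force(rig: PistonRig, state: PistonState, f_ext: float = 0.0) -> float:
    """Net force toward the small chamber, N.

    Hydrostatic pressure rho*g*h at the piston axis acts on both end faces;
    the imbalance of areas leaves rho*g*h*(a_large - a_small) pushing the
    piston toward the small chamber, minus any external pull ``f_ext``
    (positive toward the large chamber).
    """
    return rig.rho * rig.g * state.h * rig.delta_area - f_ext


def _column_height(rig: PistonRig, h_ref: float, x_ref: float, x: float) -> float:
    return max(0.0, h_ref - rig.delta_area * (x - x_ref) / rig.a_column)


def simulate_stroke(
    rig: PistonRig,
    pull_profile: Callable[[float], float],
    dt: float = 1e-4,
    t_end: float = 1.0,
    x0: float = 0.0,
    v0: float = 0.0,
    h_start: float | None = None,
    record_every: int = 1,
) -> PistonTrajectory:
    """Integrate the piston dynamics under a time-varying external pull.

    ``pull_profile(t)`` is the external force in N directed toward the large
    chamber (the "contraction"); pass a zero function for a free release.
    Fixed-step RK4 with inelastic clamping at the stops: on contact the
    position is clamped and the velocity zeroed, and the piston stays on a
    stop while the net force presses it into the stop.
    """
    if dt <= 0 or t_end <= 0:
        raise DomainError(f"dt and t_end must be > 0, got dt={dt}, t_end={t_end}")
    if not (0.0 <= x0 <= rig.travel):
        raise DomainError(f"x0 must lie in [0, travel={rig.travel}], got {x0}")
    if record_every < 1:
        raise DomainError("record_every must be >= 1")

    h_ref = rig.h0 if h_start is None else h_start
    x_ref = x0
    coeff = rig.rho * rig.g * rig.delta_area

    def accel(t: float, x: float, v: float) -> float:
        h = _column_height(rig, h_ref, x_ref, x)
        return (coeff * h - pull_profile(t) - rig.damping * v) / rig.m_piston

    n_steps = int(round(t_end / dt))
    ts, xs, vs = [0.0], [x0], [v0]
    x, v, t = x0, v0, 0.0
    for k in range(1, n_steps + 1):
        # hold on a stop while the net force presses into it
        f_net = coeff * _column_height(rig, h_ref, x_ref, x) - pull_profile(t)
        on_upper = x >= rig.travel and v <= 0.0 and f_net >= 0.0
        on_lower = x <= 0.0 and v >= 0.0 and f_net <= 0.0
        if (on_upper or on_lower) and v == 0.0:
            t = k * dt
        else:
            k1x, k1v = v, accel(t, x, v)
            k2x, k2v = v + 0.5 * dt * k1v, accel(t + 0.5 * dt, x + 0.5 * dt * k1x, v + 0.5 * dt * k1v)
            k3x, k3v = v + 0.5 * dt * k2v, accel(t + 0.5 * dt, x + 0.5 * dt * k2x, v + 0.5 * dt * k2v)
            k4x, k4v = v + dt * k3v, accel(t + dt, x + dt * k3x, v + dt * k3v)
            x = x + dt / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x)
            v = v + dt / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
            t = k * dt
            if not (np.isfinite(x) and np.isfinite(v)):
                raise NumericalFailureError(f"non-finite state at t={t}: x={x}, v={v}")
            if x >= rig.travel:      # inelastic contact with the diastolic stop
                x, v = rig.travel, 0.0
            elif x <= 0.0:           # systolic stop
                x, v = 0.0, 0.0
        if k % record_every == 0 or k == n_steps:
            ts.append(t), xs.append(x), vs.append(v)

    ts_a, xs_a, vs_a = map(np.asarray, (ts, xs, vs))
    hs = np.maximum(0.0, h_ref - rig.delta_area * (xs_a - x_ref) / rig.a_column)
    forces = coeff * hs - np.asarray([pull_profile(tk) for tk in ts_a])
    return PistonTrajectory(t=ts_a, x=xs_a, v=vs_a, h=hs, force=forces, rig=rig)


def simulate_release(
    rig: PistonRig,
    x0: float = 0.0,
    dt: float = 1e-4,
    t_end: float = 1.0,
    record_every: int = 1,
) -> PistonTrajectory:
    """Free release from ``x0``: hydraulic force alone moves the piston.

    With ``a_large > a_small`` the piston travels monotonically toward the
    small chamber and comes to rest on the diastolic stop — the rig's
    demonstration that filling-direction motion needs no external force.
    """
    return simulate_stroke(rig, lambda _t: 0.0, dt=dt, t_end=t_end, x0=x0,
                           record_every=record_every)
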