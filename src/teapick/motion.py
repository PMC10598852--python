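"""S-curve vertical motion planning for a continuously advancing picker.

The picker rides a carriage that advances along the tea row at a constant
horizontal speed V while the picking head moves vertically between
consecutive picking heights.  To limit vibration, each vertical move is a
three-segment cycle: an S-curve (logistic) acceleration over a fixed
distance S1, a uniform segment at the maximum speed, and a mirrored
S-curve deceleration over S1.  The velocity as a function of distance s on
the acceleration segment is the logistic

    Vl(s) = vl0 + (vlmax - vl0) / (1 + exp(-a (s - b))),

where a sets the steepness and b shifts the curve so it does not linger at
its slow initial growth.  Because the logistic never exactly reaches its
asymptotes, (a, b) are calibrated from the boundary tolerance eps so that
v(0) = eps*vlmax and v(S1) = (1 - eps)*vlmax:

    b = S1 / 2,    a = 2 ln((1 - eps)/eps) / S1.

Defaults follow the rig: vlmax = 0.12 m/s, S1 = 0.04 m (the distance from
the clamp front to the blade), a 10 mm waiting zone in which the head
holds position until the shoot arrives, and a 0.7 s minimum cycle time
matching the frame interval of the recognition loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import log

import numpy as np

__all__ = [
    "SCurveParams",
    "MotionCycle",
    "VelocityProfile",
    "RowGeometry",
    "ScheduleEntry",
    "Schedule",
    "calibrate_sigmoid",
    "sigmoid_velocity",
    "plan_cycle",
    "integrate_profile",
    "schedule_row",
]


def calibrate_sigmoid(S1: float, eps: float = 0.01) -> tuple[float, float]:
    """Closed-form (a, b) pinning the logistic to the segment boundaries.

    With ``b = S1/2`` and ``a = 2 ln((1-eps)/eps) / S1`` the velocity is
    ``eps * vlmax`` at s = 0 and ``(1-eps) * vlmax`` at s = S1 (for zero
    initial velocity), and exactly ``vlmax/2`` at the segment midpoint.
    """
    if S1 <= 0:
        raise ValueError("S1 must be positive")
    if not (0.0 < eps < 0.5):
        raise ValueError("eps must lie strictly between 0 and 0.5")
    b = S1 / 2.0
    a = 2.0 * log((1.0 - eps) / eps) / S1
    return a, b


@dataclass(frozen=True)
class SCurveParams:
    """Parameters of the logistic velocity ramp.

    ``a`` and ``b`` may be supplied explicitly (e.g. to reproduce a
    hand-tuned controller); when left ``None`` they are calibrated from
    ``S1`` and ``eps`` so the ramp meets its boundary conditions.
    """

    vl0: float = 0.0       # initial velocity, m/s
    vlmax: float = 0.12    # maximum vertical speed, m/s
    S1: float = 0.04       # acceleration/deceleration distance, m
    a: float | None = None
    b: float | None = None
    eps: float = 0.01      # boundary tolerance of the calibrated ramp

    def __post_init__(self) -> None:
        if not (0.0 <= self.vl0 < self.vlmax):
            raise ValueError("require 0 <= vl0 < vlmax")
        if self.S1 <= 0:
            raise ValueError("S1 must be positive")
        if not (0.0 < self.eps < 0.5):
            raise ValueError("eps must lie strictly between 0 and 0.5")
        if (self.a is None) != (self.b is None):
            raise ValueError("a and b must be given together or both left None")
        if self.a is None:
            a, b = calibrate_sigmoid(self.S1, self.eps)
            object.__setattr__(self, "a", a)
            object.__setattr__(self, "b", b)
        elif self.a <= 0:
            raise ValueError("a must be positive")


def sigmoid_velocity(s: float | np.ndarray, p: SCurveParams) -> float | np.ndarray:
    """Logistic velocity at distance ``s`` along the acceleration segment."""
    with np.errstate(over="ignore"):  # deep-tail exp overflow -> v == vl0
        out = p.vl0 + (p.vlmax - p.vl0) / (
            1.0 + np.exp(-p.a * (np.asarray(s, dtype=float) - p.b))
        )
    return float(out) if np.isscalar(s) else out


@dataclass
class MotionCycle:
    """One vertical move: acceleration, uniform and deceleration segments."""

    s_total_m: float            # signed vertical travel (positive = down)
    accel_m: float
    uniform_m: float
    decel_m: float
    direction: str              # "up", "down" or "none"
    params: SCurveParams        # ramp parameters used for this cycle
    horizontal_speed_V: float | None = None
    waiting_zone_mm: float = 10.0
    flags: list[str] = field(default_factory=list)

    @property
    def is_null(self) -> bool:
        return self.s_total_m == 0.0

    @property
    def distance_m(self) -> float:
        return abs(self.s_total_m)


def plan_cycle(
    z_current_mm: float,
    z_next_mm: float,
    p: SCurveParams | None = None,
    V: float | None = None,
) -> MotionCycle:
    """Plan the picker's vertical cycle between two picking heights.

    For a standard move (|S| >= 2 S1) the uniform segment is
    ``Sy = |S| - 2 S1``.  Shorter moves never reach full speed: the cycle
    degenerates to symmetric acceleration/deceleration halves of |S|/2
    each, with the ramp re-calibrated to the shortened segment so its peak
    velocity is the logistic midpoint value; such cycles are flagged
    ``"degenerate_short_move"``.  A zero displacement yields a null cycle
    (the picker waits in place).
    """
    p = p or SCurveParams()
    s_total = (z_next_mm - z_current_mm) / 1000.0
    if s_total == 0.0:
        return MotionCycle(0.0, 0.0, 0.0, 0.0, "none", p, V, flags=["null_cycle"])
    direction = "down" if s_total > 0 else "up"
    dist = abs(s_total)
    if dist >= 2.0 * p.S1:
        return MotionCycle(s_total, p.S1, dist - 2.0 * p.S1, p.S1, direction, p, V)
    half = dist / 2.0
    a, b = calibrate_sigmoid(half, p.eps)
    short = replace(p, S1=half, a=a, b=b)
    return MotionCycle(
        s_total, half, 0.0, half, direction, short, V, flags=["degenerate_short_move"]
    )


@dataclass
class VelocityProfile:
    """Sampled (distance, velocity) profile of a cycle and its duration."""

    samples: np.ndarray  # (N, 2) of (s in m from cycle start, v in m/s)
    duration: float      # seconds


def integrate_profile(
    cycle: MotionCycle, p: SCurveParams | None = None, ds: float = 1e-4
) -> VelocityProfile:
    """Sample the cycle's velocity over distance and integrate its duration.

    The acceleration segment follows the logistic ramp, the uniform
    segment runs at ``vlmax``, and the deceleration segment is the
    mirrored logistic ``v(s) = ramp(S1 - s)``.  The duration integral
    ``sum ds / v`` is evaluated by the trapezoidal rule with the velocity
    floored at ``eps * vlmax`` so the dwell at the (near-zero) endpoints
    stays finite.
    """
    if ds <= 0:
        raise ValueError("ds must be positive")
    p = p or cycle.params
    if cycle.is_null:
        return VelocityProfile(samples=np.empty((0, 2)), duration=0.0)
    s1, sy = cycle.accel_m, cycle.uniform_m
    s_acc = np.arange(0.0, s1 + ds / 2, ds)
    v_acc = sigmoid_velocity(s_acc, p)
    parts_s = [s_acc]
    parts_v = [np.asarray(v_acc)]
    if sy > 0:
        s_uni = np.arange(ds, sy + ds / 2, ds)
        parts_s.append(s1 + s_uni)
        parts_v.append(np.full_like(s_uni, p.vlmax))
    s_dec = np.arange(ds, cycle.decel_m + ds / 2, ds)
    v_dec = sigmoid_velocity(cycle.decel_m - s_dec, p)
    parts_s.append(s1 + sy + s_dec)
    parts_v.append(np.asarray(v_dec))
    s = np.concatenate(parts_s)
    v = np.concatenate(parts_v)
    v_floor = np.maximum(v, p.eps * p.vlmax)
    inv = 1.0 / v_floor
    duration = float(np.sum(np.diff(s) * 0.5 * (inv[:-1] + inv[1:])))
    return VelocityProfile(samples=np.column_stack([s, v]), duration=duration)


@dataclass
class RowGeometry:
    """Fixed geometry and timing of the picking row."""

    waiting_zone_mm: float = 10.0     # horizontal standoff where the head holds
    blade_standoff_mm: float = 16.0   # blade height above the window top when parked
    min_cycle_time_s: float = 0.7     # recognition frame interval
    lead_in_mm: float = 200.0         # carriage approach distance before the window


@dataclass
class ScheduleEntry:
    index: int
    x_mm: float
    z_mm: float
    cycle: MotionCycle
    t_vertical_s: float
    t_horizontal_s: float
    feasible: bool
    flags: list[str] = field(default_factory=list)


@dataclass
class Schedule:
    entries: list[ScheduleEntry]
    V: float

    @property
    def feasible_indices(self) -> list[int]:
        return [e.index for e in self.entries if e.feasible]


def _point_xz(point) -> tuple[float, float]:
    world = getattr(point, "world", point)
    return float(world[0]), float(world[1])


def schedule_row(
    points,
    V: float,
    p: SCurveParams | None = None,
    geometry: RowGeometry | None = None,
) -> Schedule:
    """Schedule vertical cycles for a row of picking points.

    ``points`` is a sequence of picking points (objects with a ``world``
    attribute, or plain ``(X_mm, Z_mm)`` pairs) sorted by world X.  For
    each point the horizontal arrival time is ``dX / V`` while the
    vertical cycle duration comes from :func:`integrate_profile`; a
    transition is feasible iff the head finishes its vertical move and the
    waiting-zone dwell before the shoot arrives, and the arrival interval
    respects the minimum cycle time.  Infeasible transitions are flagged
    (the shoot is skipped and the head stays at its previous height),
    mirroring the miss behavior of the physical device.  The first cycle
    starts from the parked blade position above the window top.
    """
    if V <= 0:
        raise ValueError("carriage speed V must be positive")
    p = p or SCurveParams()
    geometry = geometry or RowGeometry()
    xz = [_point_xz(pt) for pt in points]
    if any(b[0] < a[0] for a, b in zip(xz[:-1], xz[1:])):
        raise ValueError("points must be sorted by world X")
    t_wait = geometry.waiting_zone_mm / 1000.0 / V
    entries: list[ScheduleEntry] = []
    z_prev: float | None = None
    x_prev = -geometry.lead_in_mm
    for i, (x, z) in enumerate(xz):
        flags: list[str] = []
        if z_prev is None:
            z_from = -geometry.blade_standoff_mm
        else:
            z_from = z_prev
        cycle = plan_cycle(z_from, z, p, V)
        t_v = integrate_profile(cycle).duration
        dx = x - x_prev
        t_h = dx / 1000.0 / V
        feasible = True
        if dx <= 0 and i > 0:
            feasible = False
            flags.append("no_horizontal_separation")
        if t_v + t_wait > t_h:
            feasible = False
            flags.append("vertical_move_too_slow")
        if i > 0 and t_h < geometry.min_cycle_time_s:
            feasible = False
            flags.append("below_min_cycle_time")
        entries.append(
            ScheduleEntry(
                index=i, x_mm=x, z_mm=z, cycle=cycle,
                t_vertical_s=t_v, t_horizontal_s=t_h,
                feasible=feasible, flags=flags + cycle.flags,
            )
        )
        if feasible:
            z_prev = z
        x_prev = x
    return Schedule(entries=entries, V=V)
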