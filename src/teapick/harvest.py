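"""Scoring of localization and simulated picking against ground truth.

The simulator mirrors the accounting of a field picking trial: out of N
test shoots, the number successfully strip-clamped (here: shoots whose
vertical cycle was feasible, the only simulable analog of the mechanical
clamping event) and the number successfully picked (clamped, cut within
the localization tolerance of the true picking point, and leaving a
residual stalk shorter than 5 mm below the bud).  Success rates are
reported as percentages of the total shoot count with one decimal,
truncated the way the field-trial table prints them (90/98 -> 91.8,
82/98 -> 83.6).

Detection quality is scored with the standard counts: precision
Pc = TP/(TP+FP), recall Rc = TP/(TP+FN) and their harmonic mean
Fc = 2 Pc Rc / (Pc + Rc).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .motion import Schedule
from .scene import SceneTruth

__all__ = [
    "TrialConfig",
    "TrialReport",
    "DetectionCounts",
    "DetectionMetrics",
    "MatchResult",
    "localization_errors",
    "success_rates",
    "run_trial",
    "detection_metrics",
]


@dataclass
class TrialConfig:
    """Success thresholds of a simulated picking trial (lengths in mm)."""

    tolerance_mm: float = 3.0       # max |cut - true pick point| for a valid cut
    stalk_success_mm: float = 5.0   # residual stalk below the bud must be shorter
    match_radius_mm: float = 10.0   # prediction-truth matching radius
    carriage_speed_V: float = 0.03  # m/s
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.tolerance_mm, self.stalk_success_mm, self.match_radius_mm) <= 0:
            raise ValueError("all trial thresholds must be positive")


@dataclass
class MatchResult:
    """Greedy nearest-neighbor matching of predictions to true pick points."""

    matches: list[tuple[int, int, float]]  # (pred index, truth index, distance mm)
    errors_mm: list[float]                 # Euclidean world error per match
    vertical_errors_mm: list[float]        # |dZ| component per match
    unmatched_truth: list[int]
    unmatched_pred: list[int]


def localization_errors(
    predicted, truth: SceneTruth, match_radius_mm: float = 10.0
) -> MatchResult:
    """Match predicted pick points to ground truth and report world errors.

    Matching is greedy on the globally smallest Euclidean distance, with
    matches beyond ``match_radius_mm`` rejected; unmatched true shoots are
    misses and unmatched predictions are spurious.  ``predicted`` holds
    pick points (objects with a ``world`` attribute or ``(X, Z)`` pairs).
    """
    pred = np.array([getattr(p, "world", p) for p in predicted], dtype=float)
    true = np.array([s.true_pick_point for s in truth.shoots], dtype=float)
    matches: list[tuple[int, int, float]] = []
    if len(pred) and len(true):
        d = np.linalg.norm(pred[:, None, :] - true[None, :, :], axis=2)
        free_p = set(range(len(pred)))
        free_t = set(range(len(true)))
        order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
        for i, j in order:
            if d[i, j] > match_radius_mm:
                break
            if i in free_p and j in free_t:
                matches.append((int(i), int(j), float(d[i, j])))
                free_p.discard(int(i))
                free_t.discard(int(j))
    else:
        free_p = set(range(len(pred)))
        free_t = set(range(len(true)))
    vertical = [abs(pred[i][1] - true[j][1]) for i, j, _ in matches]
    return MatchResult(
        matches=matches,
        errors_mm=[dist for _, _, dist in matches],
        vertical_errors_mm=vertical,
        unmatched_truth=sorted(free_t),
        unmatched_pred=sorted(free_p),
    )


def success_rates(n_shoots: int, n_clamped: int, n_picked: int) -> tuple[float, float]:
    """Clamping and picking success rates in percent, one decimal.

    Both rates use the total shoot count as denominator and are truncated
    (not rounded) to one decimal, matching how field-trial tables print
    them: (98, 90, 82) -> (91.8, 83.6).
    """
    if n_shoots <= 0:
        raise ValueError("n_shoots must be positive")
    if not (0 <= n_picked <= n_clamped <= n_shoots):
        raise ValueError("require 0 <= n_picked <= n_clamped <= n_shoots")

    def _pct(count: int) -> float:
        return math.floor(100.0 * count / n_shoots * 10.0 + 1e-9) / 10.0

    return _pct(n_clamped), _pct(n_picked)


@dataclass
class TrialReport:
    """Counts, rates and error statistics of one simulated trial."""

    n_shoots: int
    n_clamped: int
    n_picked: int
    clamp_rate_pct: float
    pick_rate_pct: float
    errors_mm: list[float]
    vertical_errors_mm: list[float]
    infeasible: list[int] = field(default_factory=list)   # skipped truth shoots
    missed: list[int] = field(default_factory=list)       # unmatched truth shoots
    flags: list[str] = field(default_factory=list)


def _residual_stalk_mm(shoot, z_cut: float) -> float:
    """Along-stem distance from the cut height up to the bud base (the tip)."""
    poly = np.asarray(shoot.stem_polyline)
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    z = poly[:, 1]
    if z_cut <= z[0]:
        return 0.0
    return float(np.interp(z_cut, z, cum))


def run_trial(
    truth: SceneTruth,
    schedule: Schedule | None,
    pick_points,
    config: TrialConfig | None = None,
) -> TrialReport:
    """Score one synthetic picking trial.

    A shoot counts as *clamped* when a prediction was matched to it and
    its scheduled vertical cycle was feasible (the head reached the
    waiting zone before the shoot arrived); it counts as *picked* when it
    was clamped, the cut landed within ``tolerance_mm`` of the true
    picking point, and the residual stalk between the cut and the bud base
    is shorter than ``stalk_success_mm``.  When ``schedule`` is ``None``
    every matched shoot is treated as clamped (pure localization scoring).
    """
    config = config or TrialConfig()
    points = list(pick_points)
    if schedule is not None and len(schedule.entries) != len(points):
        raise ValueError(
            f"schedule has {len(schedule.entries)} entries for {len(points)} pick points"
        )
    match = localization_errors(points, truth, config.match_radius_mm)
    feasible = (
        {e.index for e in schedule.entries if e.feasible}
        if schedule is not None
        else set(range(len(points)))
    )
    n_clamped = 0
    n_picked = 0
    infeasible: list[int] = []
    for pred_i, truth_j, err in match.matches:
        if pred_i not in feasible:
            infeasible.append(truth_j)
            continue
        n_clamped += 1
        shoot = truth.shoots[truth_j]
        world = getattr(points[pred_i], "world", points[pred_i])
        z_cut = float(world[1])
        cut_above_bud = z_cut < float(shoot.tip[1])
        residual = _residual_stalk_mm(shoot, z_cut)
        if (
            not cut_above_bud
            and err <= config.tolerance_mm
            and residual < config.stalk_success_mm
        ):
            n_picked += 1
    n = len(truth.shoots)
    clamp_rate, pick_rate = success_rates(n, n_clamped, n_picked)
    return TrialReport(
        n_shoots=n,
        n_clamped=n_clamped,
        n_picked=n_picked,
        clamp_rate_pct=clamp_rate,
        pick_rate_pct=pick_rate,
        errors_mm=match.errors_mm,
        vertical_errors_mm=match.vertical_errors_mm,
        infeasible=sorted(infeasible),
        missed=match.unmatched_truth,
    )


@dataclass(frozen=True)
class DetectionCounts:
    """True/false positive and false negative counts of a detector."""

    TP: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class DetectionMetrics:
    """Precision, recall and their harmonic mean; ``None`` when undefined."""

    precision: float | None
    recall: float | None
    f_score: float | None


def detection_metrics(counts: DetectionCounts) -> DetectionMetrics:
    """Precision Pc, recall Rc and harmonic mean Fc from raw counts.

    Undefined quantities (zero denominators) are reported as ``None``
    rather than silently coerced to zero.
    """
    pc = counts.TP / (counts.TP + counts.FP) if counts.TP + counts.FP > 0 else None
    rc = counts.TP / (counts.TP + counts.FN) if counts.TP + counts.FN > 0 else None
    if pc is None or rc is None or pc + rc == 0:
        fc = None
    else:
        fc = 2.0 * pc * rc / (pc + rc)
    return DetectionMetrics(precision=pc, recall=rc, f_score=fc)
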