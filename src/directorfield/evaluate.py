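"""Precision/recall scoring of model output against scene ground truth.

Both scores use activity magnitudes and positions only (orientation
agreement is not required):

* precision P = (summed |psi| over active sites within ``tol`` of any
  ground-truth contour point, occluded parts included) / (summed |psi| over
  all active sites).  P = 1 means no clutter survives.  P is *undefined*
  (NaN) when nothing is active; undefined points are excluded from curves.
* recall R = fraction of ground-truth contour points (visible and occluded)
  with at least one active site within ``tol``.  R = 1 means the whole
  contour, gaps included, was recovered.

"Active" is a cutoff on |psi|, absolute or relative to the current maximum.
The match tolerance is measured in the Chebyshev metric, default 1 site,
consistent with the one-lattice-spacing band the stimulus paints.

Sweeping cutoffs at each recorded time yields one PR curve per time; the
area under the recall-sorted polyline (trapezoid rule over defined points,
anchored at recall 0 so a perfect curve scores 1) is the fitness used by
the optimizer, and the recorded time with maximal area is the *optimal
time* at which performance peaks before spurious activity takes over.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .field import DirectorField
from .dynamics import Trajectory
from .scenes import Scene

__all__ = [
    "PRPoint",
    "PRCurve",
    "precision",
    "recall",
    "pr_point",
    "pr_curve",
    "optimal_time",
    "best_f1",
    "default_cutoffs",
]


def default_cutoffs(mode: str = "absolute") -> np.ndarray:
    """The standard sweep: 0.05..0.95 step 0.05 (fractions in relative mode)."""
    del mode  # same grid for both conventions
    return np.round(np.arange(0.05, 0.951, 0.05), 10)


@dataclass(frozen=True)
class PRPoint:
    cutoff: float
    mode: str
    time_step: int
    precision: float  # NaN = undefined (no active sites)
    recall: float

    @property
    def defined(self) -> bool:
        return not np.isnan(self.precision)


@dataclass
class PRCurve:
    """PR points sharing one recorded time, with the polyline area."""

    time_step: int
    points: list
    auc: float
    mode: str

    @property
    def defined_points(self) -> list:
        return [p for p in self.points if p.defined]


def _chebyshev_dilate(mask: np.ndarray, tol: int) -> np.ndarray:
    """Dilate a boolean mask by ``tol`` in the Chebyshev metric, periodic."""
    out = mask.copy()
    for _ in range(tol):
        acc = out.copy()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr or dc:
                    acc |= np.roll(np.roll(out, dr, axis=0), dc, axis=1)
        out = acc
    return out


def _truth_mask(truth: Scene, tol: int) -> np.ndarray:
    mask = np.zeros((truth.L, truth.L), dtype=bool)
    pts = truth.truth_points()
    mask[pts[:, 0], pts[:, 1]] = True
    return _chebyshev_dilate(mask, tol)


def precision(f: DirectorField, truth: Scene, cutoff: float, mode: str = "absolute", tol: int = 1) -> float:
    """Activity-weighted precision; NaN when no site is active."""
    return pr_point(f, truth, cutoff, mode, tol, time_step=0).precision


def recall(f: DirectorField, truth: Scene, cutoff: float, mode: str = "absolute", tol: int = 1) -> float:
    """Fraction of ground-truth contour points covered by active sites."""
    return pr_point(f, truth, cutoff, mode, tol, time_step=0).recall


def pr_point(
    f: DirectorField,
    truth: Scene,
    cutoff: float,
    mode: str = "absolute",
    tol: int = 1,
    time_step: int = 0,
    _near_truth: np.ndarray | None = None,
) -> PRPoint:
    if tol < 0:
        raise ValueError("tol must be >= 0")
    near = _truth_mask(truth, tol) if _near_truth is None else _near_truth
    active = f.active_mask(cutoff, mode)
    mag = f.magnitude
    total = float(mag[active].sum())
    p = float(mag[active & near].sum() / total) if total > 0 else np.nan
    covered = _chebyshev_dilate(active, tol)
    pts = truth.truth_points()
    r = float(np.mean(covered[pts[:, 0], pts[:, 1]])) if len(pts) else np.nan
    return PRPoint(float(cutoff), mode, int(time_step), p, r)


def _polyline_auc(points: list) -> float:
    """Area under the recall-sorted precision polyline, defined points only.

    The polyline is anchored at recall 0 with the precision of the
    lowest-recall (highest-cutoff) point, so the area spans [0, max recall]:
    a trajectory holding (P, R) = (1, 1) everywhere scores exactly 1, and a
    single defined point (R, P) scores P * R.
    """
    pts = [p for p in points if p.defined]
    if not pts:
        return 0.0
    order = np.argsort([p.recall for p in pts], kind="stable")
    rr = np.array([0.0] + [pts[i].recall for i in order])
    pp = np.array([pts[order[0]].precision] + [pts[i].precision for i in order])
    return float(np.trapezoid(pp, rr))


def pr_curve(
    traj: Trajectory,
    truth: Scene,
    cutoffs=None,
    mode: str = "absolute",
    tol: int = 1,
) -> list[PRCurve]:
    """One PR curve per recorded time, sweeping the given cutoffs."""
    cutoffs = default_cutoffs(mode) if cutoffs is None else np.asarray(cutoffs, dtype=float)
    if len(cutoffs) == 0:
        raise ValueError("need a non-empty cutoff list")
    near = _truth_mask(truth, tol)
    curves = []
    for t, f in traj:
        points = [pr_point(f, truth, c, mode, tol, time_step=t, _near_truth=near) for c in cutoffs]
        curves.append(PRCurve(int(t), points, _polyline_auc(points), mode))
    return curves


def optimal_time(curves: list[PRCurve]) -> int:
    """Recorded time with maximal PR area; ties go to the earlier time."""
    if len(curves) < 2:
        raise ValueError("need at least two recorded times")
    aucs = [c.auc for c in curves]
    return int(curves[int(np.argmax(aucs))].time_step)


def best_f1(curve: PRCurve) -> float:
    """Best harmonic mean of precision and recall along one curve."""
    best = 0.0
    for p in curve.defined_points:
        if p.precision + p.recall > 0:
            best = max(best, 2 * p.precision * p.recall / (p.precision + p.recall))
    return best
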