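"""Per-class mean response curves: spline interpolation and extrema.

The event-locked mean of each region/class is a set of 12 knots at integer
TR offsets -2..9; a natural cubic interpolating spline through the knots is
the continuous signal used by all downstream observables (peak positions,
chords, areas).  Extremum search runs on a dense 1e-3-TR grid with local
parabolic refinement; flat plateaus are kept as intervals internally and
reported at their left edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .prep import TrialTensor

__all__ = [
    "MeanResponseCurve",
    "Extremum",
    "event_mean",
    "interpolate",
    "class_mean_curves",
    "find_local_extrema",
    "window_peak",
]

GRID_STEP = 1e-3  # TR units; extrema localization grid


@dataclass
class MeanResponseCurve:
    """Mean signal of one region for one event class.

    ``interpolant`` is a continuous function of time in TR units defined on
    ``[knot_times[0], knot_times[-1]]``; it passes through the knots
    exactly.
    """

    region_id: str
    event_class: str
    knot_times: np.ndarray
    knot_values: np.ndarray
    interpolant: object
    n_trials: int = 0

    def __post_init__(self) -> None:
        self.knot_times = np.asarray(self.knot_times, dtype=float)
        self.knot_values = np.asarray(self.knot_values, dtype=float)

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.knot_times[0]), float(self.knot_times[-1])

    def __call__(self, t):
        return self.interpolant(t)

    def dense_sample(self, step: float = 0.01) -> np.ndarray:
        """(t, y) columns for plotting/export."""
        lo, hi = self.domain
        t = np.arange(lo, hi + step / 2, step)
        return np.column_stack([t, self.interpolant(t)])


@dataclass(frozen=True)
class Extremum:
    kind: str  # "max" | "min"
    t: float
    y: float


def event_mean(trials: TrialTensor, event_class: str) -> np.ndarray:
    """Knot matrix (regions x frames): arithmetic mean over trials of a class."""
    mask = trials.mask(event_class)
    if not mask.any():
        raise ValueError(f"no trials of class {event_class!r} in tensor")
    return trials.values[mask].mean(axis=0)


def interpolate(
    knot_times: np.ndarray,
    knot_values: np.ndarray,
    *,
    region_id: str = "",
    event_class: str = "",
    n_trials: int = 0,
) -> MeanResponseCurve:
    """Natural cubic interpolating spline through the mean-signal knots."""
    knot_times = np.asarray(knot_times, dtype=float)
    knot_values = np.asarray(knot_values, dtype=float)
    if knot_times.ndim != 1 or len(knot_times) < 2:
        raise ValueError("need at least two knot times")
    if np.any(np.diff(knot_times) <= 0):
        raise ValueError("knot times must be strictly increasing (no duplicates)")
    spline = CubicSpline(knot_times, knot_values, bc_type="natural")
    return MeanResponseCurve(
        region_id=region_id,
        event_class=event_class,
        knot_times=knot_times,
        knot_values=knot_values,
        interpolant=spline,
        n_trials=n_trials,
    )


def class_mean_curves(
    trials: TrialTensor, event_class: str
) -> dict[str, MeanResponseCurve]:
    """One interpolated mean curve per region for the given class."""
    knots = event_mean(trials, event_class)
    times = trials.frame_offsets.astype(float)
    n = int(trials.mask(event_class).sum())
    return {
        rid: interpolate(times, knots[i], region_id=rid,
                         event_class=event_class, n_trials=n)
        for i, rid in enumerate(trials.region_ids)
    }


# ---------------------------------------------------------------------------
# extrema machinery (shared with the observables module)


def _grid(a: float, b: float, step: float = GRID_STEP) -> np.ndarray:
    n = max(int(round((b - a) / step)), 2)
    return np.linspace(a, b, n + 1)


def _plateau_runs(y: np.ndarray, kind: str) -> list[tuple[int, int]]:
    """Interior extremal plateaus (i_left, i_right), strict on both flanks.

    A run of equal values counts as one extremum; runs touching the array
    ends are discarded (window endpoints never qualify).
    """
    sign = 1.0 if kind == "max" else -1.0
    v = sign * y
    runs: list[tuple[int, int]] = []
    n = len(v)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        if i > 0 and j < n - 1 and v[i - 1] < v[i] and v[j + 1] < v[j]:
            runs.append((i, j))
        i = j + 1
    return runs


def _refine_parabola(curve, grid: np.ndarray, i: int) -> tuple[float, float]:
    """Parabolic refinement through three neighbouring grid points."""
    h = grid[1] - grid[0]
    y0, y1, y2 = float(curve(grid[i - 1])), float(curve(grid[i])), float(curve(grid[i + 1]))
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(grid[i]), y1
    t_star = float(grid[i] + 0.5 * h * (y0 - y2) / denom)
    t_star = min(max(t_star, float(grid[i - 1])), float(grid[i + 1]))
    return t_star, float(curve(t_star))


def find_local_extrema(
    curve,
    window: tuple[float, float],
    kind: str = "max",
    step: float = GRID_STEP,
) -> list[Extremum]:
    """Interior local maxima/minima of a curve within a window, ordered by t.

    The curve may be a :class:`MeanResponseCurve` or any callable of time in
    TR units.  An empty list is a valid result (the curve is monotone, or
    the only extremum sits on a window endpoint).  Flat plateaus are
    reported at their left-most point.
    """
    if kind not in ("max", "min"):
        raise ValueError("kind must be 'max' or 'min'")
    a, b = float(window[0]), float(window[1])
    if b <= a:
        raise ValueError("window must have positive length")
    if isinstance(curve, MeanResponseCurve):
        lo, hi = curve.domain
        if a < lo - 1e-12 or b > hi + 1e-12:
            raise ValueError(f"window {window} outside curve domain {curve.domain}")
    grid = _grid(a, b, step)
    y = np.asarray(curve(grid), dtype=float)
    out = []
    for i_left, i_right in _plateau_runs(y, kind):
        if i_right > i_left:  # flat plateau: report the left edge, no refinement
            out.append(Extremum(kind, float(grid[i_left]), float(y[i_left])))
        else:
            t, v = _refine_parabola(curve, grid, i_left)
            out.append(Extremum(kind, t, v))
    return out


def window_peak(
    curve,
    window: tuple[float, float],
    step: float = GRID_STEP,
) -> tuple[float, float, float] | None:
    """Dominant in-window maximum as ``(t_left, t_right, y)``.

    When several interior maxima exist the one with the largest value wins
    (ties go to the earliest).  For a flat-topped peak the two edges of the
    plateau are returned; for a sharp peak ``t_left == t_right`` at the
    refined location.  Returns None when the window holds no interior
    maximum.
    """
    a, b = float(window[0]), float(window[1])
    grid = _grid(a, b, step)
    y = np.asarray(curve(grid), dtype=float)
    runs = _plateau_runs(y, "max")
    if not runs:
        return None
    best = max(runs, key=lambda r: (y[r[0]], -r[0]))
    i_left, i_right = best
    if i_right > i_left:
        return float(grid[i_left]), float(grid[i_right]), float(y[i_left])
    t, v = _refine_parabola(curve, grid, i_left)
    return t, t, v
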