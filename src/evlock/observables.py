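"""Contrast observables between two class-mean curves.

Two kinds of quantities are computed for a region's pair of interpolated
mean signals y_A, y_B:

* the normalized absolute area between the curves over a window,

      dArea = 1/(T_f - T_i) * integral_{T_i}^{T_f} |y_A(t) - y_B(t)| dt

* chord-based delay statistics for the rising ("leading") or falling
  ("trailing") part of the response.  Each curve's edge is replaced by the
  straight chord joining the preceding minimum (t0, y0) to the in-window
  maximum (t1, y1) (or maximum to following minimum for the trailing edge).
  Parametrizing the chords by signal level y, over the common level range
  [y_-, y_+] with y_- = max(y0^A, y0^B) and y_+ = min(y1^A, y1^B):

      <Dt>    = 1/(y_+ - y_-) * integral (t_B(y) - t_A(y)) dy
      sigma   = sqrt(<Dt^2> - <Dt>^2)
      range   = (y_+ - y_-) / (max(y1^A, y1^B) - min(y0^A, y0^B))

  Since t_B(y) - t_A(y) is linear in y the moments have closed forms; a
  numeric-quadrature path exists in the test suite as the oracle.  The sign
  convention is <Dt> > 0 when B lags A (A is the first-named event of a
  contrast).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import GRID_STEP, MeanResponseCurve, window_peak

__all__ = [
    "ChordError",
    "Chord",
    "EdgeDelay",
    "DelayObservables",
    "delta_area",
    "rising_chord",
    "falling_chord",
    "leading_delay",
    "trailing_delay",
    "delay_observables",
]

MIN_CHORD_HEIGHT = 1e-6  # reject degenerate flat chords
DEFAULT_DOMAIN = (-2.0, 9.0)  # knot span of the event-locked window, TR units
MIN_PROMINENCE = 0.05  # relative back-rise needed to accept a minimum


class ChordError(ValueError):
    """A delay chord cannot be formed (no in-window maximum, or flat chord)."""


@dataclass(frozen=True)
class Chord:
    """Straight line from (t0, y0) to (t1, y1); for a rising chord y1 > y0,
    for a falling chord t1 > t0 with y1 < y0.  ``flagged`` marks a fallback
    anchor at the domain boundary (no resolvable adjacent minimum)."""

    t0: float
    y0: float
    t1: float
    y1: float
    flagged: bool = False

    @property
    def y_lo(self) -> float:
        return min(self.y0, self.y1)

    @property
    def y_hi(self) -> float:
        return max(self.y0, self.y1)

    def t_of_y(self, y):
        """Linear parametrization t(y) along the chord."""
        return self.t0 + (np.asarray(y) - self.y0) * (self.t1 - self.t0) / (
            self.y1 - self.y0
        )


@dataclass(frozen=True)
class EdgeDelay:
    """Delay statistics for one edge (leading or trailing)."""

    edge: str
    mean: float
    sigma: float
    range: float
    defined: bool
    chord_a: Chord | None = None
    chord_b: Chord | None = None
    flagged: bool = False


@dataclass(frozen=True)
class DelayObservables:
    delta_area: float
    leading: EdgeDelay | None
    trailing: EdgeDelay | None
    max_window: tuple[float, float]
    area_window: tuple[float, float]


# ---------------------------------------------------------------------------
# dArea


def _domain(curve) -> tuple[float, float] | None:
    return curve.domain if isinstance(curve, MeanResponseCurve) else None


def delta_area(
    curve_a,
    curve_b,
    t_i: float,
    t_f: float,
    step: float = GRID_STEP,
) -> float:
    """Window-normalized absolute area between two curves (symmetric in A, B).

    Evaluated by trapezoid quadrature on a <= ``step`` TR grid.
    """
    if not t_i < t_f:
        raise ValueError("need T_i < T_f")
    for c in (curve_a, curve_b):
        dom = _domain(c)
        if dom is not None and (t_i < dom[0] - 1e-12 or t_f > dom[1] + 1e-12):
            raise ValueError(f"window [{t_i}, {t_f}] outside curve domain {dom}")
    n = max(int(np.ceil((t_f - t_i) / step)), 1)
    grid = np.linspace(t_i, t_f, n + 1)
    diff = np.abs(
        np.asarray(curve_a(grid), dtype=float) - np.asarray(curve_b(grid), dtype=float)
    )
    return float(np.trapezoid(diff, grid) / (t_f - t_i))


# ---------------------------------------------------------------------------
# chord construction


def _walk_to_minimum(
    curve, t_start: float, direction: int, domain: tuple[float, float],
    step: float,
) -> tuple[float, float, bool]:
    """Descend from a peak to the nearest materially prominent minimum.

    Walking left (direction=-1) from the rising edge's peak or right
    (direction=+1) from the falling edge's, the running minimum is tracked
    and the walk stops once the curve rises back above it by more than
    ``MIN_PROMINENCE`` of the descended height -- shallow sampling-noise
    dips on a slope do not qualify as the minimum.  On a flat stretch (the
    response onset of a noise-free template) the anchor is the near edge of
    the flat; if the walk reaches the domain boundary still descending the
    boundary point is used and flagged.
    """
    lo, hi = domain
    if direction < 0:
        grid = np.arange(t_start, lo - step / 2, -step)
    else:
        grid = np.arange(t_start, hi + step / 2, step)
    grid = np.clip(grid, lo, hi)
    y = np.asarray(curve(grid), dtype=float)
    y_peak = y[0]
    best = 0
    i = 1
    while i < len(grid):
        if y[i] < y[best]:
            best = i
        elif y[i] - y[best] > MIN_PROMINENCE * (y_peak - y[best]):
            break
        i += 1
    flagged = i >= len(grid) and best >= len(grid) - 1
    return float(grid[best]), float(y[best]), flagged


BASIN_HALFWIDTH = 1.0  # TR; one knot spacing, the natural smoothing scale


def _refine_basin(
    curve, t0: float, domain: tuple[float, float],
    bracket: tuple[float, float] | None = None,
    kind: str = "min", step: float = GRID_STEP,
) -> tuple[float, float]:
    """Anchor refinement: vertex of a least-squares parabola over the basin.

    Fitting the interpolant over +-1 knot spacing around the walked-to
    extremum averages out sampling noise in flat basins; under a pure time
    shift of the curve the fit shifts identically, so shift recovery is
    unaffected.  Falls back to the raw point when the fit has the wrong
    curvature.
    """
    lo = max(domain[0], t0 - BASIN_HALFWIDTH)
    hi = min(domain[1], t0 + BASIN_HALFWIDTH)
    if bracket is not None:
        lo, hi = max(lo, bracket[0]), min(hi, bracket[1])
    g = np.arange(lo, hi + step / 2, step)
    if len(g) < 3:
        return t0, float(curve(t0))
    y = np.asarray(curve(g), dtype=float)
    x = g - t0
    coef = np.polynomial.polynomial.polyfit(x, y, 2)
    curv = coef[2] if kind == "min" else -coef[2]
    if curv <= 0:
        return t0, float(curve(t0))
    t_star = float(np.clip(t0 - coef[1] / (2.0 * coef[2]), lo, hi))
    return t_star, float(curve(t_star))


def rising_chord(
    curve, max_window: tuple[float, float], step: float = GRID_STEP,
    domain: tuple[float, float] | None = None,
) -> Chord:
    """Chord from the preceding minimum up to the in-window maximum.

    The maximum follows the largest-peak rule; for a flat-topped peak the
    chord anchors at the left edge of the plateau (where the rise ends).
    """
    dom = domain or _domain(curve) or DEFAULT_DOMAIN
    peak = window_peak(curve, max_window, step)
    if peak is None:
        raise ChordError(f"no interior maximum in window {max_window}")
    t_left, t_right, y_max = peak
    walk_start = t_left
    if t_left == t_right:  # sharp peak: basin-refine; plateaus keep their edge
        t_left, y_max = _refine_basin(curve, t_left, dom, bracket=max_window,
                                      kind="max", step=step)
    t0, y0, flagged = _walk_to_minimum(curve, walk_start, -1, dom, step)
    if not flagged:
        t0, y0 = _refine_basin(curve, t0, (dom[0], walk_start), kind="min",
                               step=step)
    if y_max - y0 < MIN_CHORD_HEIGHT:
        raise ChordError("degenerate rising chord (height below threshold)")
    return Chord(t0=t0, y0=y0, t1=t_left, y1=y_max, flagged=flagged)


def falling_chord(
    curve, max_window: tuple[float, float], step: float = GRID_STEP,
    domain: tuple[float, float] | None = None,
) -> Chord:
    """Chord from the in-window maximum down to the following minimum.

    For a flat-topped peak the chord anchors at the right edge of the
    plateau (where the fall begins)."""
    dom = domain or _domain(curve) or DEFAULT_DOMAIN
    peak = window_peak(curve, max_window, step)
    if peak is None:
        raise ChordError(f"no interior maximum in window {max_window}")
    t_left, t_right, y_max = peak
    walk_start = t_right
    if t_left == t_right:
        t_right, y_max = _refine_basin(curve, t_right, dom, bracket=max_window,
                                       kind="max", step=step)
    t1, y1, flagged = _walk_to_minimum(curve, walk_start, +1, dom, step)
    if not flagged:
        t1, y1 = _refine_basin(curve, t1, (walk_start, dom[1]), kind="min",
                               step=step)
    if y_max - y1 < MIN_CHORD_HEIGHT:
        raise ChordError("degenerate falling chord (height below threshold)")
    return Chord(t0=t_right, y0=y_max, t1=t1, y1=y1, flagged=flagged)


# ---------------------------------------------------------------------------
# closed-form chord delay statistics


def _chord_delay(chord_a: Chord, chord_b: Chord, edge: str) -> EdgeDelay:
    """Closed-form level-averaged delay between two chords.

    With t_X(y) = alpha_X + beta_X * y linear, the difference
    D(y) = t_B(y) - t_A(y) = alpha + beta*y has

        <D>   = alpha + beta*(y_- + y_+)/2
        sigma = |beta| * (y_+ - y_-) / sqrt(12)
    """
    if edge == "leading":
        lo_a, hi_a = chord_a.y0, chord_a.y1   # y0 at the minimum, y1 at the peak
        lo_b, hi_b = chord_b.y0, chord_b.y1
    else:
        lo_a, hi_a = chord_a.y1, chord_a.y0   # falling: y1 at the minimum
        lo_b, hi_b = chord_b.y1, chord_b.y0
    y_minus = max(lo_a, lo_b)
    y_plus = min(hi_a, hi_b)
    full = max(hi_a, hi_b) - min(lo_a, lo_b)
    if y_plus <= y_minus:
        # disjoint level spans: the delay is not computable
        return EdgeDelay(edge=edge, mean=np.nan, sigma=np.nan, range=0.0,
                         defined=False, chord_a=chord_a, chord_b=chord_b,
                         flagged=chord_a.flagged or chord_b.flagged)
    slope_a = (chord_a.t1 - chord_a.t0) / (chord_a.y1 - chord_a.y0)
    slope_b = (chord_b.t1 - chord_b.t0) / (chord_b.y1 - chord_b.y0)
    alpha = (chord_b.t0 - slope_b * chord_b.y0) - (chord_a.t0 - slope_a * chord_a.y0)
    beta = slope_b - slope_a
    mean = alpha + beta * 0.5 * (y_minus + y_plus)
    sigma = abs(beta) * (y_plus - y_minus) / np.sqrt(12.0)
    return EdgeDelay(
        edge=edge,
        mean=float(mean),
        sigma=float(sigma),
        range=float((y_plus - y_minus) / full),
        defined=True,
        chord_a=chord_a,
        chord_b=chord_b,
        flagged=chord_a.flagged or chord_b.flagged,
    )


def leading_delay(
    curve_a, curve_b, max_window: tuple[float, float], step: float = GRID_STEP,
    domain: tuple[float, float] | None = None,
) -> EdgeDelay:
    """Average leading (rising-edge) time delay of B relative to A."""
    return _chord_delay(
        rising_chord(curve_a, max_window, step, domain),
        rising_chord(curve_b, max_window, step, domain),
        "leading",
    )


def trailing_delay(
    curve_a, curve_b, max_window: tuple[float, float], step: float = GRID_STEP,
    domain: tuple[float, float] | None = None,
) -> EdgeDelay:
    """Average trailing (falling-edge) time delay of B relative to A."""
    return _chord_delay(
        falling_chord(curve_a, max_window, step, domain),
        falling_chord(curve_b, max_window, step, domain),
        "trailing",
    )


def delay_observables(
    curve_a,
    curve_b,
    *,
    max_window: tuple[float, float],
    area_window: tuple[float, float],
    step: float = GRID_STEP,
) -> DelayObservables:
    """dArea plus both edge-delay statistics for a region's curve pair.

    Edges whose chords cannot be formed come back as None rather than
    raising, so callers can tabulate partially-defined regions.
    """
    area = delta_area(curve_a, curve_b, area_window[0], area_window[1], step)
    out = {}
    for edge, fn in (("leading", leading_delay), ("trailing", trailing_delay)):
        try:
            out[edge] = fn(curve_a, curve_b, max_window, step)
        except ChordError:
            out[edge] = None
    return DelayObservables(
        delta_area=area,
        leading=out["leading"],
        trailing=out["trailing"],
        max_window=tuple(max_window),
        area_window=tuple(area_window),
    )
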