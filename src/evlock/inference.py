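"""Permutation critical values, bootstrap errors, and region selection.

Multiple comparisons over regions are handled with a max-statistic
permutation test: event labels of the pooled trial collection are shuffled,
the per-region dArea recomputed through the full mean -> spline -> area
pipeline, and the maximum over regions recorded; the empirical 0.95
quantile of those maxima is the family-wise critical value.  Statistical
errors of the delay observables come from a label-preserving bootstrap over
trials; z = point estimate / bootstrap SD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .curves import find_local_extrema, interpolate
from .observables import ChordError, delta_area, leading_delay, trailing_delay
from .prep import TrialTensor

__all__ = [
    "UnreliableBootstrapError",
    "PermutationResult",
    "BootstrapResult",
    "SelectionCriteria",
    "permutation_critical_value",
    "delta_area_by_region",
    "bootstrap_observables",
    "delay_observable",
    "area_observable",
    "select_area_regions",
    "select_delay_regions",
]


class UnreliableBootstrapError(RuntimeError):
    """More than half of the bootstrap resamples were degenerate."""


@dataclass
class PermutationResult:
    null_max_distribution: np.ndarray
    critical_value: float
    n_permutations: int
    quantile: float
    seed: int

    def __post_init__(self) -> None:
        self.null_max_distribution = np.asarray(
            self.null_max_distribution, dtype=float
        )
        if len(self.null_max_distribution) != self.n_permutations:
            raise ValueError("distribution length must equal n_permutations")


@dataclass
class BootstrapResult:
    """Bootstrap spread of one observable.

    ``z`` uses the full-sample point estimate in the numerator; the
    alternative ratio with the bootstrap mean as numerator is stored as
    ``z_boot_mean``.
    """

    point_estimate: float
    boot_std: float
    boot_mean: float
    n_boot: int
    n_degenerate: int
    seed: int

    @property
    def z_defined(self) -> bool:
        # a spread at float-roundoff scale means the resamples were
        # effectively identical; flag the ratio as undefined
        return self.boot_std > 1e-12 and np.isfinite(self.point_estimate)

    @property
    def z(self) -> float:
        return self.point_estimate / self.boot_std if self.z_defined else np.nan

    @property
    def z_boot_mean(self) -> float:
        return self.boot_mean / self.boot_std if self.z_defined else np.nan


@dataclass
class SelectionCriteria:
    """The four region-selection criteria plus window configuration.

    A region is kept when it is relevant (dArea above the permutation
    critical value), its delay is significant (z > z_min), the two edges
    run approximately in parallel (sigma < sigma_max) and the chords
    overlap enough for a reliable estimate (range > range_min).
    """

    z_min: float = 2.0
    sigma_max: float = 0.15
    range_min: float = 0.1
    maxima_window: tuple[float, float] = (1.0, 5.0)
    area_window: tuple[float, float] = (0.0, 5.0)
    edge: str = "leading"
    min_region_size: int = 10

    def __post_init__(self) -> None:
        if min(self.z_min, self.sigma_max, self.range_min) <= 0:
            raise ValueError("thresholds must be positive")
        if self.edge not in ("leading", "trailing"):
            raise ValueError("edge must be 'leading' or 'trailing'")


# ---------------------------------------------------------------------------
# batched dArea on knot matrices


def _batch_delta_area(
    knot_times: np.ndarray,
    knot_diffs: np.ndarray,
    t_i: float,
    t_f: float,
    step: float = 1e-3,
    chunk_elements: int = 40_000_000,
) -> np.ndarray:
    """dArea for many mean-difference knot vectors at once.

    ``knot_diffs`` has shape (..., 12); natural-spline interpolation is
    linear in the knot values, so the spline of the difference equals the
    difference of the splines.  Returns an array of shape ``(...)``.
    """
    lead = knot_diffs.shape[:-1]
    flat = knot_diffs.reshape(-1, knot_diffs.shape[-1])
    n_grid = max(int(math.ceil((t_f - t_i) / step)), 1) + 1
    grid = np.linspace(t_i, t_f, n_grid)
    out = np.empty(flat.shape[0])
    rows_per_chunk = max(chunk_elements // n_grid, 1)
    for start in range(0, flat.shape[0], rows_per_chunk):
        block = flat[start : start + rows_per_chunk]
        spline = CubicSpline(knot_times, block.T, bc_type="natural")
        vals = np.abs(spline(grid))  # (n_grid, rows)
        out[start : start + rows_per_chunk] = (
            np.trapezoid(vals, grid, axis=0) / (t_f - t_i)
        )
    return out.reshape(lead)


def delta_area_by_region(
    trials: TrialTensor,
    classes: tuple[str, str],
    area_window: tuple[float, float],
    step: float = 1e-3,
) -> pd.Series:
    """Observed per-region dArea between the two classes' mean curves."""
    a, b = classes
    mean_a = trials.values[trials.mask(a)].mean(axis=0)
    mean_b = trials.values[trials.mask(b)].mean(axis=0)
    vals = _batch_delta_area(
        trials.frame_offsets.astype(float), mean_a - mean_b,
        area_window[0], area_window[1], step,
    )
    return pd.Series(vals, index=pd.Index(trials.region_ids, name="region"))


# ---------------------------------------------------------------------------
# permutation test


def _nearest_rank_quantile(values: np.ndarray, q: float) -> float:
    """ceil(q*n)-th order statistic."""
    values = np.sort(np.asarray(values, dtype=float))
    k = min(max(int(math.ceil(q * len(values))), 1), len(values))
    return float(values[k - 1])


def permutation_critical_value(
    trials: TrialTensor,
    classes: tuple[str, str],
    area_window: tuple[float, float],
    n_perm: int = 1000,
    quantile: float = 0.95,
    seed: int = 0,
    step: float = 1e-3,
) -> PermutationResult:
    """Max-statistic permutation null for dArea across regions.

    Labels are shuffled globally over the pooled trials of the two classes;
    for each permutation the maximum per-region dArea is recorded and the
    nearest-rank ``quantile`` of the maxima is the critical value.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a stable 0.95 quantile")
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie in (0, 1)")
    pooled = trials.subset(classes)
    n_a = int(pooled.mask(classes[0]).sum())
    n_b = int(pooled.mask(classes[1]).sum())
    if min(n_a, n_b) < 2:
        raise ValueError("each class needs at least two trials")
    rng = np.random.default_rng(seed)
    n = pooled.n_trials
    flat = pooled.values.reshape(n, -1)  # (n, R*12)

    # weight vector turning shuffled labels into a mean difference
    diffs = np.empty((n_perm, flat.shape[1]))
    w = np.empty(n)
    for p in range(n_perm):
        perm = rng.permutation(n)
        w[perm[:n_a]] = 1.0 / n_a
        w[perm[n_a:]] = -1.0 / n_b
        diffs[p] = w @ flat

    knot_diffs = diffs.reshape(n_perm, len(pooled.region_ids), -1)
    areas = _batch_delta_area(
        pooled.frame_offsets.astype(float), knot_diffs,
        area_window[0], area_window[1], step,
    )
    null_max = areas.max(axis=1)
    return PermutationResult(
        null_max_distribution=null_max,
        critical_value=_nearest_rank_quantile(null_max, quantile),
        n_permutations=n_perm,
        quantile=quantile,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# bootstrap


def delay_observable(
    classes: tuple[str, str],
    region: str,
    edge: str = "leading",
    max_window: tuple[float, float] = (1.0, 5.0),
):
    """Observable closure: the edge delay of one region (B lags A positive)."""

    def fn(tensor: TrialTensor) -> float:
        r = tensor.region_ids.index(region)
        times = tensor.frame_offsets.astype(float)
        curves = []
        for cls in classes:
            mask = tensor.mask(cls)
            if not mask.any():
                raise ChordError(f"resample lost class {cls!r}")
            curves.append(interpolate(times, tensor.values[mask, r].mean(axis=0)))
        f = leading_delay if edge == "leading" else trailing_delay
        res = f(curves[0], curves[1], max_window)
        return res.mean if res.defined else np.nan

    return fn


def area_observable(
    classes: tuple[str, str],
    region: str,
    area_window: tuple[float, float] = (0.0, 5.0),
):
    """Observable closure: one region's dArea between the two class means."""

    def fn(tensor: TrialTensor) -> float:
        r = tensor.region_ids.index(region)
        times = tensor.frame_offsets.astype(float)
        means = []
        for cls in classes:
            mask = tensor.mask(cls)
            if not mask.any():
                raise ChordError(f"resample lost class {cls!r}")
            means.append(tensor.values[mask, r].mean(axis=0))
        a = interpolate(times, means[0])
        b = interpolate(times, means[1])
        return delta_area(a, b, area_window[0], area_window[1])

    return fn


def bootstrap_observables(
    trials: TrialTensor,
    classes: tuple[str, str],
    observable_fn,
    n_boot: int = 1000,
    seed: int = 0,
) -> BootstrapResult:
    """Label-preserving bootstrap of an observable over pooled trials.

    Each resample draws N trials with replacement from the pooled
    collection (N = pooled trial count), keeping each trial's label.
    Resamples on which the observable is undefined (NaN or a chord failure)
    are counted and excluded; more than 50% of them raises
    :class:`UnreliableBootstrapError`.
    """
    pooled = trials.subset(classes)
    point = observable_fn(pooled)
    if not np.isfinite(point):
        raise ValueError("observable is undefined on the full sample")
    rng = np.random.default_rng(seed)
    n = pooled.n_trials
    stats = np.full(n_boot, np.nan)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            stats[b] = observable_fn(pooled.take(idx))
        except (ChordError, ValueError):
            stats[b] = np.nan
    good = stats[np.isfinite(stats)]
    n_degenerate = n_boot - len(good)
    if n_degenerate > n_boot / 2:
        raise UnreliableBootstrapError(
            f"{n_degenerate}/{n_boot} degenerate bootstrap resamples"
        )
    return BootstrapResult(
        point_estimate=float(point),
        boot_std=float(good.std()),
        boot_mean=float(good.mean()),
        n_boot=n_boot,
        n_degenerate=n_degenerate,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# selection


def select_area_regions(
    curves: dict[str, tuple],
    critical: float,
    criteria: SelectionCriteria,
    region_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Relevance selection: in-window maxima for BOTH curves and
    dArea > critical (plus the region-size floor when sizes are known).

    ``curves`` maps region id -> (curve_A, curve_B).  Returns a table with
    one row per region and a boolean ``selected`` column.
    """
    rows = []
    for region, (curve_a, curve_b) in curves.items():
        size = None if region_sizes is None else int(region_sizes.get(region, 0))
        has_max = all(
            len(find_local_extrema(c, criteria.maxima_window, "max")) > 0
            for c in (curve_a, curve_b)
        )
        area = delta_area(
            curve_a, curve_b, criteria.area_window[0], criteria.area_window[1]
        )
        size_ok = True if size is None else size >= criteria.min_region_size
        rows.append(
            {
                "region": region,
                "size": size,
                "delta_area": area,
                "has_maxima": has_max,
                "size_ok": size_ok,
                "selected": bool(has_max and size_ok and area > critical),
            }
        )
    return pd.DataFrame(rows).set_index("region")


def select_delay_regions(
    area_table: pd.DataFrame,
    delays: dict[str, "EdgeDelay"],
    bootstraps: dict[str, BootstrapResult],
    criteria: SelectionCriteria,
) -> pd.DataFrame:
    """Apply the four delay criteria; emit a report in the style of the
    delay tables (region, size, <Dt> +- bootstrap error, z, sigma, range)."""
    rows = []
    for region, delay in delays.items():
        if region not in area_table.index:
            continue
        relevant = bool(area_table.loc[region, "selected"])
        boot = bootstraps.get(region)
        z = boot.z if boot is not None else np.nan
        ok = (
            relevant
            and delay is not None
            and delay.defined
            and np.isfinite(z)
            and z > criteria.z_min
            and delay.sigma < criteria.sigma_max
            and delay.range > criteria.range_min
        )
        rows.append(
            {
                "region": region,
                "size": area_table.loc[region, "size"],
                "delta_area": area_table.loc[region, "delta_area"],
                "mean_delay": np.nan if delay is None else delay.mean,
                "boot_std": np.nan if boot is None else boot.boot_std,
                "z": z,
                "sigma": np.nan if delay is None else delay.sigma,
                "range": np.nan if delay is None else delay.range,
                "relevant": relevant,
                "selected": bool(ok),
            }
        )
    columns = ["region", "size", "delta_area", "mean_delay", "boot_std",
               "z", "sigma", "range", "relevant", "selected"]
    df = pd.DataFrame(rows, columns=columns).set_index("region")
    return df.sort_values("mean_delay", ascending=False)
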