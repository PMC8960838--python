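"""Synthetic event-related parcellated BOLD generator.

Emulates a rapid event-related recognition-memory experiment (a short-term
DRM task): four response classes (POScorr, LURfalse, NEGcorr, LURcorr) with
the study's trial totals, jittered inter-trial intervals, HRF-shaped region
responses with configurable amplitude / onset / trailing contrasts, and
AR(1) noise.  Ground truth (the per-region, per-class response template) is
stored with the dataset so every downstream stage can be tested by recovery.

Event classes
-------------
POScorr  correct "old" response to a studied probe
LURfalse false "old" response to a similar lure probe
NEGcorr  correct rejection of an unrelated new probe
LURcorr  correct rejection of a lure probe
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats

from .prep import EventTable, ParcellatedTimeSeries, TrialTensor

__all__ = [
    "CapacityError",
    "IntervalSpec",
    "TaskDesign",
    "ResponseTemplate",
    "NoiseSpec",
    "SimulatedDataset",
    "canonical_hrf",
    "hrf_peak_location",
    "template_curve",
    "template_knots",
    "sample_event_onsets",
    "simulate_dataset",
    "sample_trials",
    "sample_null_trials",
    "null_templates",
    "write_dataset",
]

STUDY_TRIAL_COUNTS = {
    "POScorr": 2159,
    "LURfalse": 903,
    "NEGcorr": 1060,
    "LURcorr": 1747,
}


class CapacityError(ValueError):
    """A session is too short to host the requested trials."""


# ---------------------------------------------------------------------------
# timing distributions


@dataclass(frozen=True)
class IntervalSpec:
    """Bounded interval distribution with an optional target mean.

    With a target mean the distribution is a truncated exponential shifted
    to ``lo`` and scaled so that its mean matches ``mean`` (the task reports
    only min / max / mean, and jittered event-related designs conventionally
    use exponential-like ITI distributions).  Without a mean it is uniform.
    """

    lo: float
    hi: float
    mean: float | None = None

    def __post_init__(self) -> None:
        if self.hi < self.lo:
            raise ValueError("hi must be >= lo")
        if self.mean is not None and not (self.lo <= self.mean <= self.hi):
            raise ValueError("mean must lie within [lo, hi]")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.hi == self.lo:
            return np.full(n, self.lo)
        if self.mean is None:
            return rng.uniform(self.lo, self.hi, size=n)
        scale = _truncexp_scale(self.hi - self.lo, self.mean - self.lo)
        draws = stats.truncexpon.rvs(
            b=(self.hi - self.lo) / scale, loc=self.lo, scale=scale,
            size=n, random_state=rng,
        )
        return draws


@lru_cache(maxsize=32)
def _truncexp_scale(span: float, target_mean: float) -> float:
    """Scale of an exponential truncated at ``span`` with the given mean."""
    if not 0 < target_mean < span / 2:
        raise ValueError(
            "truncated-exponential mean must lie in (0, span/2); "
            f"got {target_mean} for span {span}"
        )

    def mean_of(s: float) -> float:
        if span / s > 50:  # truncation negligible on this branch
            return s
        return s - span / np.expm1(span / s)

    return float(optimize.brentq(lambda s: mean_of(s) - target_mean,
                                 1e-6 * span, 1e4 * span))


# ---------------------------------------------------------------------------
# design / template / noise types


@dataclass(frozen=True)
class TaskDesign:
    """Experiment layout: TR, trial totals, interval distributions, sizes.

    Defaults follow the study conditions: TR 1.8 s, trial totals
    2159 / 903 / 1060 / 1747 over 65 subjects x 2 sessions, ITI in
    [6, 15] s with mean 8.403 s, second ISI in [2, 16] s with mean 6.097 s,
    718 regions.
    """

    tr_seconds: float = 1.8
    n_trials_per_class: dict[str, int] = field(
        default_factory=lambda: dict(STUDY_TRIAL_COUNTS)
    )
    iti_seconds: IntervalSpec = IntervalSpec(6.0, 15.0, 8.403)
    isi2_seconds: IntervalSpec = IntervalSpec(2.0, 16.0, 6.097)
    n_subjects: int = 65
    n_sessions: int = 2
    n_regions: int = 718
    session_frames: int | None = None
    lock_to_tr: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if any(c <= 0 for c in self.n_trials_per_class.values()):
            raise ValueError("trial counts must be positive")
        if min(self.n_subjects, self.n_sessions, self.n_regions) < 1:
            raise ValueError("n_subjects, n_sessions, n_regions must be >= 1")

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(self.n_trials_per_class)

    @property
    def region_ids(self) -> list[str]:
        return [f"R{i:03d}" for i in range(self.n_regions)]

    @property
    def n_runs(self) -> int:
        return self.n_subjects * self.n_sessions


@dataclass(frozen=True)
class ResponseTemplate:
    """Noise-free response of one region to one event class.

    ``amplitude`` is the peak height in z-units; ``onset_shift`` shifts the
    whole response in TR units; ``trailing_shift`` delays only the falling
    edge (the rising edge and peak value are untouched); ``peak_time``
    (TR units post event) overrides the canonical 6 s peak; the optional
    late component is a Gaussian bump used for late-window (5-9 TR)
    effects; the optional initial dip (negative ``dip_amplitude``) is the
    brief pre-peak undershoot seen in measured BOLD responses, which gives
    the response a well-defined preceding minimum.  Both Gaussian
    components ride with ``onset_shift``.
    """

    region_id: str
    event_class: str
    amplitude: float = 1.0
    onset_shift: float = 0.0
    trailing_shift: float = 0.0
    peak_time: float | None = None
    late_amplitude: float = 0.0
    late_peak: float = 7.0
    late_width: float = 1.0
    dip_amplitude: float = 0.0
    dip_peak: float = -0.3
    dip_width: float = 0.8

    def __post_init__(self) -> None:
        if self.peak_time is not None and self.peak_time <= 0:
            raise ValueError("peak_time must be positive (TR units)")
        if self.trailing_shift < 0:
            raise ValueError("trailing_shift must be non-negative")
        if self.late_width <= 0 or self.dip_width <= 0:
            raise ValueError("component widths must be positive")


@dataclass(frozen=True)
class NoiseSpec:
    """AR(1) region noise plus per-subject amplitude heterogeneity.

    The noise process is n_t = ar1_coeff * n_{t-1} + eps_t with white
    innovations of SD ``white_sd`` (marginal SD white_sd / sqrt(1-ar1^2)).
    ``amp_jitter_sigma`` is the sigma of a lognormal per-subject multiplier
    on all template amplitudes (about +-10% at the 0.1 default).
    """

    ar1_coeff: float = 0.3
    white_sd: float = 1.0
    amp_jitter_sigma: float = 0.1

    def __post_init__(self) -> None:
        if not abs(self.ar1_coeff) < 1:
            raise ValueError("|ar1_coeff| must be < 1 for stationarity")
        if self.white_sd < 0 or self.amp_jitter_sigma < 0:
            raise ValueError("noise scales must be non-negative")

    @classmethod
    def none(cls) -> "NoiseSpec":
        return cls(ar1_coeff=0.0, white_sd=0.0, amp_jitter_sigma=0.0)


@dataclass
class SimulatedDataset:
    """Sessions + event tables + the ground-truth templates that made them."""

    sessions: list[ParcellatedTimeSeries]
    events: list[EventTable]
    truth: dict[str, dict[str, ResponseTemplate]]
    design: TaskDesign
    noise: NoiseSpec

    def __post_init__(self) -> None:
        for pts, ev in zip(self.sessions, self.events):
            frames = ev.onset_frames
            if len(frames) and (frames.min() < 0 or
                                frames.max() + 10 > pts.n_frames):
                raise ValueError(
                    "event onset without >= 10 frames of tail inside its session"
                )


# ---------------------------------------------------------------------------
# canonical HRF


def canonical_hrf(
    time_grid: np.ndarray,
    peak: float = 6.0,
    undershoot: float = 16.0,
    ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Double-gamma canonical HRF, normalized to unit peak amplitude.

    ``h(t) = g(t; peak) - ratio * g(t; undershoot)`` where ``g`` is a gamma
    density whose mode sits at the named time (seconds).  The curve is zero
    at t <= 0, peaks near ``peak`` and decays towards zero with a late
    undershoot.
    """
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("time_grid must be a strictly increasing 1-D array")
    return _hrf_values(t, peak, undershoot, ratio)


def _hrf_values(t: np.ndarray, peak: float, undershoot: float,
                ratio: float) -> np.ndarray:
    raw = (
        stats.gamma.pdf(t, peak + 1.0)
        - ratio * stats.gamma.pdf(t, undershoot + 1.0)
    )
    return raw / _hrf_peak(peak, undershoot, ratio)[1]


@lru_cache(maxsize=32)
def _hrf_peak(peak: float, undershoot: float, ratio: float) -> tuple[float, float]:
    """(argmax, max) of the un-normalized double gamma on a dense grid."""
    grid = np.arange(0.0, 2.0 * undershoot, 1e-3)
    raw = (
        stats.gamma.pdf(grid, peak + 1.0)
        - ratio * stats.gamma.pdf(grid, undershoot + 1.0)
    )
    i = int(np.argmax(raw))
    return float(grid[i]), float(raw[i])


def hrf_peak_location(peak: float = 6.0, undershoot: float = 16.0,
                      ratio: float = 1.0 / 6.0) -> float:
    """Time (seconds) of the HRF maximum (slightly off ``peak`` because of
    the undershoot term)."""
    return _hrf_peak(peak, undershoot, ratio)[0]


def template_curve(template: ResponseTemplate, tr_seconds: float = 1.8,
                   undershoot: float = 16.0, ratio: float = 1.0 / 6.0):
    """Continuous noise-free response curve, time in TR units post event.

    The trailing shift is realized as a time warp pivoted at the HRF
    maximum: the rising edge and peak are unchanged while every later time
    is mapped back by ``trailing_shift`` TR (a flat top of that width joins
    the two edges), so the falling edge is delayed by exactly that amount.
    """
    peak_s = 6.0 if template.peak_time is None else template.peak_time * tr_seconds
    pivot_s = hrf_peak_location(peak_s, undershoot, ratio)
    tau_s = template.trailing_shift * tr_seconds

    def curve(t):
        t = np.asarray(t, dtype=float)
        tt = t - template.onset_shift
        s = tt * tr_seconds
        if tau_s > 0:
            s = np.where(s <= pivot_s, s, np.maximum(pivot_s, s - tau_s))
        y = template.amplitude * np.where(
            s > 0, _hrf_values(np.clip(s, 0.0, None), peak_s, undershoot, ratio), 0.0
        )
        if template.late_amplitude:
            y = y + template.late_amplitude * np.exp(
                -0.5 * ((tt - template.late_peak) / template.late_width) ** 2
            )
        if template.dip_amplitude:
            y = y + template.dip_amplitude * np.exp(
                -0.5 * ((tt - template.dip_peak) / template.dip_width) ** 2
            )
        return y

    return curve


def template_knots(template: ResponseTemplate, tr_seconds: float = 1.8,
                   offsets: np.ndarray | None = None) -> np.ndarray:
    """Template sampled at integer TR offsets (default -2..9)."""
    if offsets is None:
        offsets = np.arange(-2, 10)
    return template_curve(template, tr_seconds)(np.asarray(offsets, dtype=float))


# ---------------------------------------------------------------------------
# template books


def null_templates(design: TaskDesign,
                   base: ResponseTemplate | None = None
                   ) -> dict[str, dict[str, ResponseTemplate]]:
    """Identical templates for every region and class (no contrast)."""
    book: dict[str, dict[str, ResponseTemplate]] = {}
    for rid in design.region_ids:
        book[rid] = {}
        for cls in design.classes:
            proto = base or ResponseTemplate(region_id=rid, event_class=cls)
            book[rid][cls] = replace(proto, region_id=rid, event_class=cls)
    return book


# ---------------------------------------------------------------------------
# onset sampling


def sample_event_onsets(
    design: TaskDesign,
    rng_seed: int | np.random.Generator,
    *,
    counts: dict[str, int] | None = None,
    first_onset: float | None = None,
) -> EventTable:
    """Sample one session's chronologically ordered event table.

    Successive retrieval events are separated by ITI draws; class labels
    are randomly interleaved with exact per-class counts.  With
    ``design.lock_to_tr`` onsets are snapped down to the TR grid.
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    counts = dict(design.n_trials_per_class if counts is None else counts)
    if any(c < 0 for c in counts.values()) or sum(counts.values()) == 0:
        raise ValueError("counts must be non-negative with a positive total")
    n = sum(counts.values())

    labels = np.concatenate([np.full(c, cls, dtype=object)
                             for cls, c in counts.items()])
    rng.shuffle(labels)

    if first_onset is None:
        first_onset = float(design.iti_seconds.sample(1, rng)[0])
    itis = design.iti_seconds.sample(n - 1, rng) if n > 1 else np.array([])
    onsets = first_onset + np.concatenate([[0.0], np.cumsum(itis)])
    if design.lock_to_tr:
        onsets = np.floor(onsets / design.tr_seconds) * design.tr_seconds

    if design.session_frames is not None:
        last_ok = (design.session_frames - 10) * design.tr_seconds
        if onsets[-1] > last_ok:
            raise CapacityError(
                f"session of {design.session_frames} frames cannot host {n} "
                f"trials (last onset {onsets[-1]:.1f}s, limit {last_ok:.1f}s)"
            )
    return EventTable(
        pd.DataFrame(
            {"onset": onsets, "duration": 2.0, "trial_type": labels}
        ),
        tr_seconds=design.tr_seconds,
    )


def _split_counts(design: TaskDesign) -> list[dict[str, int]]:
    """Split the per-class totals over subject x session runs (near-even,
    remainders to the earliest runs)."""
    runs = design.n_runs
    per_run = [dict() for _ in range(runs)]
    for cls, total in design.n_trials_per_class.items():
        base, rem = divmod(total, runs)
        for i in range(runs):
            per_run[i][cls] = base + (1 if i < rem else 0)
    return per_run


# ---------------------------------------------------------------------------
# dataset simulation


def _ar1_noise(shape: tuple[int, int], noise: NoiseSpec,
               rng: np.random.Generator) -> np.ndarray:
    if noise.white_sd == 0:
        return np.zeros(shape)
    eps = rng.normal(0.0, noise.white_sd, size=shape)
    a = noise.ar1_coeff
    if a == 0:
        return eps
    # inflating the first innovation starts the recursion in its
    # stationary distribution
    eps[..., 0] /= np.sqrt(1.0 - a * a)
    return signal.lfilter([1.0], [1.0, -a], eps, axis=-1)


def _session_signal(
    design: TaskDesign,
    templates: dict[str, dict[str, ResponseTemplate]],
    events: EventTable,
    n_frames: int,
    amp_scale: float,
) -> np.ndarray:
    """Sum of template responses over events, sampled on the frame grid."""
    tr = design.tr_seconds
    frame_times = np.arange(n_frames) * tr
    out = np.zeros((design.n_regions, n_frames))
    region_index = {rid: i for i, rid in enumerate(design.region_ids)}

    # evaluate each distinct template shape once on a fine offset grid,
    # then place it per event with np.interp (support -2..14 TR)
    grid = np.arange(-2.0, 14.0 + 1e-9, 0.01)
    shape_cache: dict[tuple, np.ndarray] = {}

    for rid, per_class in templates.items():
        if rid not in region_index:
            raise KeyError(f"template references unknown region {rid!r}")
        r = region_index[rid]
        for cls, tpl in per_class.items():
            if cls not in design.classes:
                raise KeyError(f"template references unknown class {cls!r}")
            key = (
                tpl.amplitude, tpl.onset_shift, tpl.trailing_shift,
                tpl.peak_time, tpl.late_amplitude, tpl.late_peak, tpl.late_width,
            )
            if key not in shape_cache:
                shape_cache[key] = template_curve(tpl, tr)(grid)
            curve = shape_cache[key]
            for onset in events.onsets[events.trial_types == cls]:
                rel = (frame_times - onset) / tr
                lo, hi = np.searchsorted(rel, [grid[0], grid[-1]])
                if hi > lo:
                    out[r, lo:hi] += amp_scale * np.interp(
                        rel[lo:hi], grid, curve
                    )
    return out


def simulate_dataset(
    design: TaskDesign,
    templates: dict[str, dict[str, ResponseTemplate]] | None = None,
    noise: NoiseSpec | None = None,
    rng_seed: int | None = None,
) -> SimulatedDataset:
    """Simulate all subject/session runs of the task.

    Every region/class pair needs a template (regions without an entry get
    a flat zero response).  Each session matrix is the sum of event-locked
    template responses plus AR(1) noise; the truth book is stored on the
    returned dataset.
    """
    noise = NoiseSpec() if noise is None else noise
    if templates is None:
        templates = null_templates(design)
    for rid, per_class in templates.items():
        missing = set(per_class) - set(design.classes)
        if missing:
            raise KeyError(f"template for region {rid!r} names unknown classes {missing}")
    seed = design.rng_seed if rng_seed is None else rng_seed
    root = np.random.default_rng(seed)
    per_run_counts = _split_counts(design)

    amp = {
        s: (float(np.exp(root.normal(0.0, noise.amp_jitter_sigma)))
            if noise.amp_jitter_sigma > 0 else 1.0)
        for s in range(design.n_subjects)
    }

    sessions, event_tables = [], []
    run = 0
    for subj in range(design.n_subjects):
        for sess in range(design.n_sessions):
            ev = sample_event_onsets(design, root, counts=per_run_counts[run])
            run += 1
            if design.session_frames is not None:
                n_frames = design.session_frames
            else:
                n_frames = int(np.floor(ev.onsets[-1] / design.tr_seconds)) + 11
            sig = _session_signal(design, templates, ev, n_frames, amp[subj])
            sig = sig + _ar1_noise((design.n_regions, n_frames), noise, root)
            sessions.append(
                ParcellatedTimeSeries(
                    subject_id=f"sub-{subj:03d}",
                    session_id=f"ses-{sess}",
                    region_ids=design.region_ids,
                    tr_seconds=design.tr_seconds,
                    values=sig,
                )
            )
            event_tables.append(ev)
    return SimulatedDataset(
        sessions=sessions, events=event_tables, truth=templates,
        design=design, noise=noise,
    )


# ---------------------------------------------------------------------------
# fast paths: draw event-locked trial windows directly


def sample_trials(
    class_means: dict[str, np.ndarray],
    n_per_class: dict[str, int],
    noise: NoiseSpec,
    rng_seed: int | np.random.Generator,
    *,
    region_ids: list[str] | None = None,
    tr_seconds: float = 1.8,
    frame_offsets: np.ndarray | None = None,
) -> TrialTensor:
    """Draw event-locked windows directly: trial = class mean + AR(1) noise.

    ``class_means[cls]`` is a (regions x frames) array.  This bypasses the
    session machinery (no window overlap between trials) and is the
    workhorse for calibration studies where thousands of replicates are
    needed.
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    classes = list(n_per_class)
    shapes = {np.asarray(class_means[c]).shape for c in classes}
    if len(shapes) != 1:
        raise ValueError("all class mean patterns must share one shape")
    (n_regions, n_frames), = shapes
    if frame_offsets is None:
        frame_offsets = np.arange(-2, n_frames - 2)
    values, labels = [], []
    for cls in classes:
        n = n_per_class[cls]
        block = np.broadcast_to(
            np.asarray(class_means[cls], dtype=float), (n, n_regions, n_frames)
        ).copy()
        block += _ar1_noise((n * n_regions, n_frames), noise, rng).reshape(
            n, n_regions, n_frames
        )
        values.append(block)
        labels.append(np.full(n, cls, dtype=object))
    order = rng.permutation(sum(n_per_class.values()))
    return TrialTensor(
        values=np.concatenate(values)[order],
        frame_offsets=frame_offsets,
        labels=np.concatenate(labels)[order],
        region_ids=region_ids or [f"R{i:03d}" for i in range(n_regions)],
        tr_seconds=tr_seconds,
    )


def sample_null_trials(
    n_per_class: dict[str, int],
    n_regions: int,
    noise: NoiseSpec,
    rng_seed: int | np.random.Generator,
    *,
    tr_seconds: float = 1.8,
    n_frames: int = 12,
) -> TrialTensor:
    """Exchangeable-null windows: labels carry no signal at all."""
    zeros = np.zeros((n_regions, n_frames))
    return sample_trials(
        {cls: zeros for cls in n_per_class}, n_per_class, noise, rng_seed,
        tr_seconds=tr_seconds,
    )


# ---------------------------------------------------------------------------
# on-disk form


def write_dataset(dataset: SimulatedDataset, out_dir) -> None:
    """Write sessions as TSV matrices, events as BIDS TSV, plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for pts, ev in zip(dataset.sessions, dataset.events):
        stem = f"{pts.subject_id}_{pts.session_id}"
        pts.to_tsv(out / f"{stem}_timeseries.tsv")
        ev.to_tsv(out / f"{stem}_events.tsv")
    lines = [
        f"tr_seconds\t{dataset.design.tr_seconds}",
        f"rng_seed\t{dataset.design.rng_seed}",
        f"n_subjects\t{dataset.design.n_subjects}",
        f"n_sessions\t{dataset.design.n_sessions}",
        f"n_regions\t{dataset.design.n_regions}",
        f"noise_ar1\t{dataset.noise.ar1_coeff}",
        f"noise_white_sd\t{dataset.noise.white_sd}",
        f"noise_amp_jitter\t{dataset.noise.amp_jitter_sigma}",
    ]
    for rid, per_class in dataset.truth.items():
        for cls, tpl in per_class.items():
            if (tpl.amplitude, tpl.onset_shift, tpl.trailing_shift,
                    tpl.late_amplitude) != (1.0, 0.0, 0.0, 0.0):
                lines.append(
                    f"truth\t{rid}\t{cls}\tamp={tpl.amplitude}"
                    f"\tonset={tpl.onset_shift}\ttrail={tpl.trailing_shift}"
                    f"\tlate={tpl.late_amplitude}"
                )
    (out / "manifest.txt").write_text("\n".join(lines) + "\n")
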