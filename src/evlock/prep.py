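"""Session normalization, parcellation, dataset standardization and trial epoching.

The preparation pipeline has a fixed order: within-session channel
normalization -> parcellation -> across-dataset region standardization ->
event-locked window extraction.  The first two steps do not commute (the
mean of z-scored channels is not the z-score of the channel mean), so the
order is part of the contract.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DegenerateChannelError",
    "ParcellatedTimeSeries",
    "Parcellation",
    "EventTable",
    "TrialTensor",
    "normalize_within_session",
    "parcellate",
    "standardize_across_dataset",
    "extract_trial_windows",
    "extract_dataset",
]

EVENT_CLASSES = ("POScorr", "LURfalse", "NEGcorr", "LURcorr")


class DegenerateChannelError(ValueError):
    """A channel (or region) has zero variance and cannot be standardized."""


@dataclass
class ParcellatedTimeSeries:
    """Region-by-frame signal matrix for one subject/session.

    ``values`` has shape (n_regions, n_frames); after the standardization
    steps the entries are in z-units.
    """

    subject_id: str
    session_id: str
    region_ids: list[str]
    tr_seconds: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (regions x frames) matrix")
        if self.values.shape[0] != len(self.region_ids):
            raise ValueError(
                f"{self.values.shape[0]} rows but {len(self.region_ids)} region ids"
            )
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not np.isfinite(self.values).all():
            raise ValueError("values contain non-finite entries")

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.tr_seconds

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            self.values,
            index=pd.Index(self.region_ids, name="region"),
            columns=[f"{t:.6f}" for t in self.frame_times],
        )
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, *, subject_id: str = "", session_id: str = "",
                 tr_seconds: float | None = None) -> "ParcellatedTimeSeries":
        df = pd.read_csv(path, sep="\t", index_col=0)
        times = np.array([float(c) for c in df.columns])
        if tr_seconds is None:
            if len(times) < 2:
                raise ValueError("cannot infer TR from a single frame")
            tr_seconds = float(np.diff(times).mean())
        return cls(
            subject_id=subject_id,
            session_id=session_id,
            region_ids=[str(r) for r in df.index],
            tr_seconds=tr_seconds,
            values=df.to_numpy(dtype=float),
        )


@dataclass
class Parcellation:
    """Mapping from region id to member channel ids.

    Regions with fewer than ``min_size`` members are flagged as excluded and
    dropped by :func:`parcellate`.
    """

    regions: dict[str, list[str]]
    min_size: int = 10

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rid, members in self.regions.items():
            dup = seen.intersection(members)
            if dup:
                raise ValueError(f"channels {sorted(dup)} appear in more than one region")
            seen.update(members)

    @property
    def excluded(self) -> list[str]:
        return [r for r, m in self.regions.items() if len(m) < self.min_size]

    @property
    def included(self) -> list[str]:
        return [r for r, m in self.regions.items() if len(m) >= self.min_size]

    def sizes(self) -> dict[str, int]:
        return {r: len(m) for r, m in self.regions.items()}


@dataclass
class EventTable:
    """Event timing table (BIDS-convention columns onset/duration/trial_type).

    ``onset_frame`` follows the floor convention: the event is locked to the
    TR frame whose interval contains its onset.
    """

    frame: pd.DataFrame
    tr_seconds: float

    REQUIRED = ("onset", "duration", "trial_type")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"event table missing columns {missing}")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        self.frame = (
            self.frame.sort_values("onset", kind="stable").reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def onsets(self) -> np.ndarray:
        return self.frame["onset"].to_numpy(dtype=float)

    @property
    def trial_types(self) -> np.ndarray:
        return self.frame["trial_type"].to_numpy(dtype=object)

    @property
    def onset_frames(self) -> np.ndarray:
        return np.floor(self.onsets / self.tr_seconds).astype(int)

    def to_tsv(self, path) -> None:
        self.frame[list(self.REQUIRED)].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, tr_seconds: float) -> "EventTable":
        return cls(pd.read_csv(path, sep="\t"), tr_seconds)


@dataclass
class TrialTensor:
    """Event-locked trial windows: trials x regions x frames.

    Frames are labelled by integer offsets relative to the event frame
    (default -2..9).  ``provenance`` carries one row per trial with subject,
    session and onset of the originating event.
    """

    values: np.ndarray
    frame_offsets: np.ndarray
    labels: np.ndarray
    region_ids: list[str]
    tr_seconds: float
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.frame_offsets = np.asarray(self.frame_offsets, dtype=int)
        self.labels = np.asarray(self.labels, dtype=object)
        n, r, f = self.values.shape
        if f != len(self.frame_offsets):
            raise ValueError("frame axis does not match frame_offsets")
        if r != len(self.region_ids):
            raise ValueError("region axis does not match region_ids")
        if n != len(self.labels):
            raise ValueError("trial axis does not match labels")
        if len(self.provenance) == 0:
            self.provenance = pd.DataFrame(index=range(n))

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    def class_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.labels.astype(str), return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def mask(self, event_class: str) -> np.ndarray:
        return self.labels.astype(str) == event_class

    def subset(self, classes) -> "TrialTensor":
        keep = np.isin(self.labels.astype(str), list(classes))
        return self.take(np.flatnonzero(keep))

    def take(self, indices) -> "TrialTensor":
        indices = np.asarray(indices, dtype=int)
        return TrialTensor(
            values=self.values[indices],
            frame_offsets=self.frame_offsets,
            labels=self.labels[indices],
            region_ids=self.region_ids,
            tr_seconds=self.tr_seconds,
            provenance=self.provenance.iloc[indices].reset_index(drop=True),
        )

    def save(self, path) -> None:
        """Lossless single-file container plus a JSON index sidecar."""
        path = str(path)
        np.savez(
            path if path.endswith(".npz") else path + ".npz",
            values=self.values,
            frame_offsets=self.frame_offsets,
            labels=self.labels.astype(str),
            **{
                f"prov_{c}": (
                    arr.astype(str) if arr.dtype == object else arr
                )
                for c in self.provenance.columns
                for arr in [self.provenance[c].to_numpy()]
            },
        )
        sidecar = {
            "region_ids": list(self.region_ids),
            "tr_seconds": self.tr_seconds,
            "n_trials": int(self.n_trials),
            "class_counts": self.class_counts(),
            "provenance_columns": list(map(str, self.provenance.columns)),
        }
        base = path[:-4] if path.endswith(".npz") else path
        with open(base + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def load(cls, path) -> "TrialTensor":
        path = str(path)
        base = path[:-4] if path.endswith(".npz") else path
        with open(base + ".json") as fh:
            sidecar = json.load(fh)
        with np.load(base + ".npz", allow_pickle=False) as npz:
            prov = {
                c: npz[f"prov_{c}"] for c in sidecar["provenance_columns"]
            }
            return cls(
                values=npz["values"],
                frame_offsets=npz["frame_offsets"],
                labels=npz["labels"].astype(object),
                region_ids=sidecar["region_ids"],
                tr_seconds=sidecar["tr_seconds"],
                provenance=pd.DataFrame(prov),
            )


# ---------------------------------------------------------------------------
# operations


def normalize_within_session(raw: np.ndarray) -> np.ndarray:
    """Demean each channel and scale it to unit standard deviation.

    Raises :class:`DegenerateChannelError` for zero-variance channels rather
    than silently emitting NaN.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[1] < 2:
        raise ValueError("need a channels x frames matrix with >= 2 frames")
    mean = raw.mean(axis=1, keepdims=True)
    sd = raw.std(axis=1, keepdims=True)
    dead = np.flatnonzero(sd[:, 0] == 0)
    if dead.size:
        raise DegenerateChannelError(
            f"zero-variance channel(s) at row index {dead.tolist()}"
        )
    return (raw - mean) / sd


def parcellate(
    normalized: np.ndarray,
    channel_ids,
    parc: Parcellation,
    *,
    subject_id: str = "",
    session_id: str = "",
    tr_seconds: float = 1.8,
) -> tuple[ParcellatedTimeSeries, list[str]]:
    """Average member channels into region signals (unweighted mean).

    Regions smaller than ``parc.min_size`` are dropped; the list of dropped
    region ids is returned as the exclusion log.
    """
    normalized = np.asarray(normalized, dtype=float)
    index = {str(c): i for i, c in enumerate(channel_ids)}
    kept = parc.included
    if not kept:
        raise ValueError("no region survives the min_size exclusion filter")
    rows = []
    for rid in kept:
        members = parc.regions[rid]
        try:
            idx = [index[str(m)] for m in members]
        except KeyError as exc:
            raise KeyError(f"region {rid!r} references unknown channel {exc}") from None
        rows.append(normalized[idx].mean(axis=0))
    pts = ParcellatedTimeSeries(
        subject_id=subject_id,
        session_id=session_id,
        region_ids=list(kept),
        tr_seconds=tr_seconds,
        values=np.vstack(rows),
    )
    return pts, parc.excluded


def standardize_across_dataset(
    sessions: list[ParcellatedTimeSeries],
) -> list[ParcellatedTimeSeries]:
    """Divide each region by its SD over the concatenation of all sessions.

    This equalizes regions of different size across the whole dataset;
    per-session SDs are deliberately left free.  Applying the function twice
    is a no-op because the concatenated SD is exactly one afterwards.
    """
    if not sessions:
        raise ValueError("no sessions given")
    region_ids = sessions[0].region_ids
    for s in sessions[1:]:
        if s.region_ids != region_ids:
            raise ValueError("all sessions must share an identical region order")
    concat = np.concatenate([s.values for s in sessions], axis=1)
    sd = concat.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise DegenerateChannelError(
            f"zero concatenated variance for region(s) {[region_ids[i] for i in dead]}"
        )
    return [
        ParcellatedTimeSeries(
            subject_id=s.subject_id,
            session_id=s.session_id,
            region_ids=region_ids,
            tr_seconds=s.tr_seconds,
            values=s.values / sd[:, None],
        )
        for s in sessions
    ]


def extract_trial_windows(
    series: ParcellatedTimeSeries,
    events: EventTable,
    pre: int = 2,
    post: int = 10,
) -> tuple[TrialTensor, int]:
    """Cut ``pre + post`` frames around each event (default 12: offsets -2..9).

    Windows that would leave the session are dropped, not an error; the
    number of dropped trials is returned alongside the tensor.
    """
    if pre < 0 or post < 0:
        raise ValueError("pre and post must be non-negative")
    offsets = np.arange(-pre, post)
    onset_frames = events.onset_frames
    ok = (onset_frames - pre >= 0) & (onset_frames + post - 1 < series.n_frames)
    n_dropped = int((~ok).sum())
    idx = np.flatnonzero(ok)
    windows = np.empty((idx.size, len(series.region_ids), pre + post), dtype=float)
    for j, i in enumerate(idx):
        f0 = onset_frames[i] - pre
        windows[j] = series.values[:, f0 : f0 + pre + post]
    tensor = TrialTensor(
        values=windows,
        frame_offsets=offsets,
        labels=events.trial_types[idx],
        region_ids=series.region_ids,
        tr_seconds=series.tr_seconds,
        provenance=pd.DataFrame(
            {
                "subject": series.subject_id,
                "session": series.session_id,
                "onset": events.onsets[idx],
            }
        ),
    )
    return tensor, n_dropped


def extract_dataset(
    sessions: list[ParcellatedTimeSeries],
    event_tables: list[EventTable],
    pre: int = 2,
    post: int = 10,
) -> tuple[TrialTensor, int]:
    """Extract and concatenate trial windows over many sessions."""
    if len(sessions) != len(event_tables):
        raise ValueError("sessions and event tables must pair up")
    tensors, dropped = [], 0
    for s, ev in zip(sessions, event_tables):
        t, d = extract_trial_windows(s, ev, pre=pre, post=post)
        tensors.append(t)
        dropped += d
    first = tensors[0]
    return (
        TrialTensor(
            values=np.concatenate([t.values for t in tensors]),
            frame_offsets=first.frame_offsets,
            labels=np.concatenate([t.labels for t in tensors]),
            region_ids=first.region_ids,
            tr_seconds=first.tr_seconds,
            provenance=pd.concat(
                [t.provenance for t in tensors], ignore_index=True
            ),
        ),
        dropped,
    )
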