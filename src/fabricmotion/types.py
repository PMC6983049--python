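"""Core containers for paired accelerometry analysis.

An :class:`AccelSeries` is a uniformly sampled tri-axial acceleration
stream in units of g.  Sensors are worn in pairs — one strapped to the
body, one sewn to the garment over the same site — captured here as a
:class:`SensorPair`.  A hand-kept activity diary becomes an
:class:`ActivityLog`.

Timing convention: after parsing, sample ``i`` of a series is at
``t0 + i / fs``; per-row clock jitter from raw exports is discarded
because the devices are clock-synchronised at initialisation and all
downstream computations assume uniform sampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

ACTIVITY_LABELS = ("walking", "running", "sitting", "bus_ride", "standing", "other")
GAIT_LABELS = ("walking", "running")
SITES = ("waist", "thigh", "ankle")
MOUNTS = ("body", "clothing")
AXIS_NAMES = ("x", "y", "z")

_EPOCH = pd.Timestamp("1970-01-01 00:00:00")


def normalise_label(label: str, *, warn_unknown: bool = True) -> str:
    """Map a free-text diary label onto the activity vocabulary.

    Unknown labels become ``"other"`` (with a warning), mirroring how a
    hand-kept log with idiosyncratic entries is annotated in practice.
    """
    norm = str(label).strip().lower().replace(" ", "_").replace("-", "_")
    if norm in ACTIVITY_LABELS:
        return norm
    if warn_unknown:
        warnings.warn(f"unknown activity label {label!r}; recording as 'other'")
    return "other"


@dataclass
class AccelSeries:
    """Uniformly sampled tri-axial acceleration stream.

    Parameters
    ----------
    data:
        Array of shape ``(n, 3)`` — acceleration along x, y, z in g.
        The y axis is nominally the gravity axis (sensor worn so that
        y points along gravity when upright).
    fs:
        Sampling rate in Hz (50 Hz for the wGT3X-BT protocol modelled).
    t0:
        Timestamp of the first sample.
    """

    data: np.ndarray
    fs: float
    t0: pd.Timestamp = _EPOCH
    sensor_id: str = ""
    site: str | None = None
    mount: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[1] != 3:
            raise ValidationError(
                f"data must have shape (n, 3); got {self.data.shape}"
            )
        if self.data.shape[0] == 0:
            raise ValidationError("series must contain at least one sample")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("series contains non-finite values")
        self.fs = float(self.fs)
        if not self.fs > 0:
            raise ValidationError(f"fs must be positive; got {self.fs}")
        self.t0 = pd.Timestamp(self.t0)
        if self.site is not None and self.site not in SITES:
            raise ValidationError(f"site must be one of {SITES}; got {self.site!r}")
        if self.mount is not None and self.mount not in MOUNTS:
            raise ValidationError(f"mount must be one of {MOUNTS}; got {self.mount!r}")

    # -- basic geometry -------------------------------------------------
    @property
    def n(self) -> int:
        return self.data.shape[0]

    def __len__(self) -> int:
        return self.n

    @property
    def duration(self) -> float:
        """Recording span in seconds (n / fs)."""
        return self.n / self.fs

    def time_seconds(self) -> np.ndarray:
        return np.arange(self.n) / self.fs

    def timestamps(self) -> pd.DatetimeIndex:
        return self.t0 + pd.to_timedelta(self.time_seconds(), unit="s")

    def axis(self, name: str) -> np.ndarray:
        """Return one axis ('x' | 'y' | 'z') or the Euclidean 'magnitude'."""
        if name == "magnitude":
            return self.magnitude()
        try:
            return self.data[:, AXIS_NAMES.index(name)]
        except ValueError:
            raise ValidationError(f"unknown axis {name!r}") from None

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.data, axis=1)

    # -- derived series -------------------------------------------------
    def with_data(self, data: np.ndarray) -> "AccelSeries":
        return replace(self, data=np.asarray(data, dtype=np.float64))

    def slice(self, start: int, stop: int) -> "AccelSeries":
        """Sample-index slice with t0 advanced accordingly."""
        if not (0 <= start < stop <= self.n):
            raise ValidationError(f"invalid slice [{start}:{stop}] of {self.n} samples")
        return replace(
            self,
            data=self.data[start:stop],
            t0=self.t0 + pd.to_timedelta(start / self.fs, unit="s"),
        )

    def index_at(self, when: pd.Timestamp) -> int:
        """Nearest sample index for an absolute timestamp (may be out of range)."""
        return int(round((pd.Timestamp(when) - self.t0).total_seconds() * self.fs))


@dataclass
class SensorPair:
    """A body-worn and a clothing-mounted stream over the same wear period."""

    body: AccelSeries
    clothing: AccelSeries

    def __post_init__(self) -> None:
        if abs(self.body.fs - self.clothing.fs) > 1e-9:
            raise ValidationError(
                f"sampling rates differ: body {self.body.fs} Hz, "
                f"clothing {self.clothing.fs} Hz"
            )

    @property
    def fs(self) -> float:
        return self.body.fs

    @property
    def n_overlap(self) -> int:
        return min(self.body.n, self.clothing.n)

    def trimmed(self) -> "SensorPair":
        """Trim both streams to their common length."""
        n = self.n_overlap
        return SensorPair(
            self.body if self.body.n == n else self.body.slice(0, n),
            self.clothing if self.clothing.n == n else self.clothing.slice(0, n),
        )


@dataclass(frozen=True)
class ActivityEntry:
    label: str
    start: pd.Timestamp
    end: pd.Timestamp

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", pd.Timestamp(self.start))
        object.__setattr__(self, "end", pd.Timestamp(self.end))
        if not self.start < self.end:
            raise ValidationError(
                f"activity entry {self.label!r}: start {self.start} not before end {self.end}"
            )

    @property
    def duration(self) -> float:
        return (self.end - self.start).total_seconds()


@dataclass
class ActivityLog:
    """Chronological, non-overlapping diary annotations."""

    entries: list[ActivityEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entries = sorted(self.entries, key=lambda e: e.start)
        for prev, cur in zip(self.entries, self.entries[1:]):
            if cur.start < prev.end:
                raise ValidationError(
                    f"overlapping activity entries: {prev.label!r} ends {prev.end}, "
                    f"{cur.label!r} starts {cur.start}"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterable[ActivityEntry]:
        return iter(self.entries)

    def for_label(self, label: str) -> list[ActivityEntry]:
        label = normalise_label(label, warn_unknown=False)
        return [e for e in self.entries if e.label == label]

    def rebase(self, date: pd.Timestamp) -> "ActivityLog":
        """Move all entries onto the given calendar date, keeping times of day."""
        date = pd.Timestamp(date).normalize()
        return ActivityLog(
            [
                ActivityEntry(
                    e.label,
                    date + (e.start - e.start.normalize()),
                    date + (e.end - e.end.normalize()),
                )
                for e in self.entries
            ]
        )

    def sample_spans(self, series: AccelSeries) -> list[tuple[int, int, str]]:
        """Entries as clipped (start_idx, stop_idx, label) spans on a series."""
        spans = []
        for e in self.entries:
            i0 = max(0, series.index_at(e.start))
            i1 = min(series.n, series.index_at(e.end))
            if i1 > i0:
                spans.append((i0, i1, e.label))
        return spans


def make_log(
    schedule: Sequence[tuple[str, float]], t0: pd.Timestamp
) -> ActivityLog:
    """Build a log from a (label, duration-seconds) schedule starting at t0."""
    t = pd.Timestamp(t0)
    entries = []
    for label, dur in schedule:
        if not dur > 0:
            raise ValidationError(f"schedule duration must be positive; got {dur}")
        end = t + pd.to_timedelta(float(dur), unit="s")
        entries.append(ActivityEntry(normalise_label(label), t, end))
        t = end
    return ActivityLog(entries)
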