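"""Core in-memory containers for one synchronized walking trial.

Conventions
-----------
* Time is seconds as floats. The *session clock* starts at the first aligned
  gait sample (TTL start pulse); ``start_time`` fields place each stream on
  that clock.
* Annotation intervals are half-open ``[onset, offset)``.
* Marker positions are millimetres in the lab frame with the third column (Z)
  vertical; neural samples are microvolts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ChannelRole",
    "MarkerTrace",
    "NeuralRecording",
    "FogAnnotation",
    "QualityGrade",
    "SyncedSession",
]


class ChannelRole(str, Enum):
    """Role of a neural channel in the implant montage."""

    STRIP = "strip"
    DEPTH_LEFT = "depth_left"
    DEPTH_RIGHT = "depth_right"
    SYNC = "sync"


@dataclass
class MarkerTrace:
    """One motion-capture marker's 3-D position series.

    Parameters
    ----------
    marker_name : str
        e.g. ``"right_heel"``.
    rate_hz : float
        Sampling rate, typically 200 Hz.
    positions : ndarray, shape (T, 3)
        x, y, z in mm; z (column 2) is vertical.
    start_time : float
        Time of the first sample on the session clock.
    """

    marker_name: str
    rate_hz: float
    positions: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.rate_hz <= 0:
            raise ValueError(f"rate_hz must be positive, got {self.rate_hz}")
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError(
                f"positions must be (T, 3), got shape {self.positions.shape}"
            )

    @property
    def n_samples(self) -> int:
        return self.positions.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate_hz

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.rate_hz

    @property
    def z(self) -> np.ndarray:
        """Vertical component (mm)."""
        return self.positions[:, 2]

    def crop(self, t0: float, t1: float) -> "MarkerTrace":
        """Restrict to session-clock interval ``[t0, t1)``."""
        i0 = max(0, int(np.ceil((t0 - self.start_time) * self.rate_hz - 1e-9)))
        i1 = min(self.n_samples, int(np.ceil((t1 - self.start_time) * self.rate_hz - 1e-9)))
        if i1 <= i0:
            raise ValueError(f"crop [{t0}, {t1}) leaves no samples")
        return replace(
            self,
            positions=self.positions[i0:i1].copy(),
            start_time=self.start_time + i0 / self.rate_hz,
        )


@dataclass
class NeuralRecording:
    """Multichannel iEEG block (subdural strip + depth leads + sync).

    ``data`` is channels x samples in microvolts (the sync channel keeps its
    native volts). ``montage`` is ``"referential"`` as acquired or
    ``"bipolar"`` after successive-contact re-referencing.
    """

    labels: list[str]
    roles: list[ChannelRole]
    rate_hz: float
    data: np.ndarray
    montage: str = "referential"
    hardware_band: tuple[float, float] = (0.08, 660.0)
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.roles = [ChannelRole(r) for r in self.roles]
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.labels) != self.data.shape[0] or len(self.roles) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels / {len(self.roles)} roles for "
                f"{self.data.shape[0]} data rows"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if self.montage not in ("referential", "bipolar"):
            raise ValueError(f"unknown montage {self.montage!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate_hz

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.rate_hz

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.labels.index(label)
        except ValueError:
            raise KeyError(f"no channel labelled {label!r}; have {self.labels}") from None
        return self.data[idx]

    def channels_with_role(self, role: ChannelRole) -> list[str]:
        role = ChannelRole(role)
        return [lab for lab, r in zip(self.labels, self.roles) if r == role]

    def sync_channel(self) -> np.ndarray:
        sync = self.channels_with_role(ChannelRole.SYNC)
        if not sync:
            raise ValueError(
                "no sync channel in recording; TTL alignment is impossible "
                f"(labels: {self.labels})"
            )
        return self.channel(sync[0])

    def crop(self, t0: float, t1: float) -> "NeuralRecording":
        """Restrict to session-clock interval ``[t0, t1)``."""
        i0 = max(0, int(np.ceil((t0 - self.start_time) * self.rate_hz - 1e-9)))
        i1 = min(self.n_samples, int(np.ceil((t1 - self.start_time) * self.rate_hz - 1e-9)))
        if i1 <= i0:
            raise ValueError(f"crop [{t0}, {t1}) leaves no samples")
        return replace(
            self,
            data=self.data[:, i0:i1].copy(),
            start_time=self.start_time + i0 / self.rate_hz,
        )


@dataclass
class FogAnnotation:
    """Manually labelled (or ground-truth) freezing-of-gait intervals."""

    intervals: list[tuple[float, float]]
    source: str = "manual"

    def __post_init__(self) -> None:
        ivs = [(float(a), float(b)) for a, b in self.intervals]
        for a, b in ivs:
            if not a < b:
                raise ValueError(f"interval onset must precede offset, got ({a}, {b})")
        ivs = sorted(ivs)
        for (a0, b0), (a1, b1) in zip(ivs, ivs[1:]):
            if a1 < b0:
                raise ValueError(f"overlapping intervals ({a0},{b0}) and ({a1},{b1})")
        self.intervals = ivs

    def contains(self, times: np.ndarray | float) -> np.ndarray:
        """Boolean mask: which times fall in any interval (half-open)."""
        t = np.atleast_1d(np.asarray(times, dtype=float))
        mask = np.zeros(t.shape, dtype=bool)
        for a, b in self.intervals:
            mask |= (t >= a) & (t < b)
        return mask

    @property
    def total_duration(self) -> float:
        return float(sum(b - a for a, b in self.intervals))

    def complement(self, t0: float, t1: float) -> list[tuple[float, float]]:
        """Non-FOG intervals inside ``[t0, t1)``."""
        out: list[tuple[float, float]] = []
        cursor = t0
        for a, b in self.intervals:
            a, b = max(a, t0), min(b, t1)
            if b <= t0 or a >= t1:
                continue
            if a > cursor:
                out.append((cursor, a))
            cursor = max(cursor, b)
        if cursor < t1:
            out.append((cursor, t1))
        return out


@dataclass
class QualityGrade:
    """Manual 5-level grade of signal contamination; 1 = clean, 5 = unusable.

    Levels 1-2 are considered analyzable.
    """

    level: int
    note: str = ""

    def __post_init__(self) -> None:
        if int(self.level) not in (1, 2, 3, 4, 5):
            raise ValueError(f"quality level must be 1-5, got {self.level}")
        self.level = int(self.level)


@dataclass
class SyncedSession:
    """One walking trial with gait and neural streams on a common clock."""

    subject_id: str
    trial_id: str
    markers: list[MarkerTrace]
    neural: NeuralRecording | None
    annotation: FogAnnotation
    quality: QualityGrade = field(default_factory=lambda: QualityGrade(1))
    sync_offset: float = 0.0
    """Gait clock minus neural clock, i.e. neural time of the start pulse."""

    def marker(self, name: str) -> MarkerTrace:
        for m in self.markers:
            if m.marker_name == name:
                return m
        raise KeyError(
            f"no marker named {name!r}; have {[m.marker_name for m in self.markers]}"
        )

    @property
    def duration(self) -> float:
        """Duration of the gait stream (the walking trial) in seconds."""
        if self.markers:
            return max(m.start_time + m.duration for m in self.markers)
        if self.neural is not None:
            return self.neural.start_time + self.neural.duration
        return 0.0
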