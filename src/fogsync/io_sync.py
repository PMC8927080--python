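"""Reading, writing and TTL alignment of gait and neural streams.

On-disk formats
---------------
* markers: long CSV with columns ``time, marker, x, y, z`` (seconds / mm),
  or the C3D motion-capture standard when ``ezc3d`` is available;
* neural: wide CSV with a ``time`` column plus one column per channel
  (microvolts), with roles resolved from a ``channels.json`` sidecar or
  inferred from the label prefixes used throughout the package
  (``RStrip*``, ``RDepth*``, ``LDepth*``, ``SYNC``); EDF is read through
  MNE's built-in reader;
* annotations: JSON ``{"intervals": [[onset, offset], ...], "source": ...}``;
* a whole session round-trips through a directory via
  :func:`write_session` / :func:`read_session`.

Alignment maps gait time zero onto the first upward TTL threshold crossing of
the recorded sync channel (10 ms refractory); a second pulse, when present,
marks the recording stop and both streams are cropped to the pulse pair.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from fogsync.session import (
    ChannelRole,
    FogAnnotation,
    MarkerTrace,
    NeuralRecording,
    QualityGrade,
    SyncedSession,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_markers",
    "write_markers",
    "read_neural",
    "write_neural",
    "read_annotation",
    "write_annotation",
    "detect_pulses",
    "align_streams",
    "screen_quality",
    "write_session",
    "read_session",
]

_ROLE_PATTERNS: list[tuple[re.Pattern, ChannelRole]] = [
    (re.compile(r"^(RStrip|Right\s*Strip)", re.I), ChannelRole.STRIP),
    (re.compile(r"^(RDepth|Right\s*Depth)", re.I), ChannelRole.DEPTH_RIGHT),
    (re.compile(r"^(LDepth|Left\s*Depth)", re.I), ChannelRole.DEPTH_LEFT),
    (re.compile(r"^(SYNC|TTL|Trig)", re.I), ChannelRole.SYNC),
]


def _infer_role(label: str, role_map: Mapping[str, str] | None) -> ChannelRole:
    if role_map is not None and label in role_map:
        return ChannelRole(role_map[label])
    for pat, role in _ROLE_PATTERNS:
        if pat.match(label):
            return role
    raise ValueError(
        f"channel label {label!r} has no role mapping; provide role_map or use "
        "RStrip*/RDepth*/LDepth*/SYNC label conventions"
    )


def _rate_from_times(t: np.ndarray, what: str) -> float:
    dt = np.diff(t)
    if len(dt) == 0:
        raise ValueError(f"{what}: need at least two samples to infer a rate")
    if not np.allclose(dt, dt[0], rtol=1e-4, atol=1e-9):
        raise ValueError(f"{what}: non-uniform sampling (dt range {dt.min()}..{dt.max()})")
    return 1.0 / float(np.mean(dt))


# ---------------------------------------------------------------------------
# markers


def read_markers(path: str | Path, format: str = "csv") -> list[MarkerTrace]:
    """Read marker trajectories; one :class:`MarkerTrace` per labelled marker."""
    path = Path(path)
    if format == "csv":
        df = pd.read_csv(path)
        required = {"time", "marker", "x", "y", "z"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"marker CSV must have columns {sorted(required)}, got {list(df.columns)}"
            )
        traces = []
        for name, g in df.groupby("marker", sort=False):
            t = g["time"].to_numpy(float)
            rate = _rate_from_times(t, f"marker {name!r}")
            traces.append(
                MarkerTrace(
                    marker_name=str(name),
                    rate_hz=rate,
                    positions=g[["x", "y", "z"]].to_numpy(float),
                    start_time=float(t[0]),
                )
            )
        if not traces:
            raise ValueError(f"no markers found in {path}")
        return traces
    if format == "c3d":
        try:
            import ezc3d  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "reading C3D requires the optional 'ezc3d' package; "
                "export the trial to the CSV layout instead"
            ) from exc
        c3d = ezc3d.c3d(str(path))  # pragma: no cover
        labels = c3d["parameters"]["POINT"]["LABELS"]["value"]  # pragma: no cover
        rate = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])  # pragma: no cover
        points = c3d["data"]["points"]  # pragma: no cover
        return [  # pragma: no cover
            MarkerTrace(marker_name=lab, rate_hz=rate, positions=points[:3, i, :].T)
            for i, lab in enumerate(labels)
        ]
    raise ValueError(f"unknown marker format {format!r}")


def write_markers(traces: Sequence[MarkerTrace], path: str | Path) -> None:
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "time": tr.times,
                    "marker": tr.marker_name,
                    "x": tr.positions[:, 0],
                    "y": tr.positions[:, 1],
                    "z": tr.positions[:, 2],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# neural


def read_neural(
    path: str | Path,
    format: str = "csv",
    role_map: Mapping[str, str] | None = None,
) -> NeuralRecording:
    """Read a multichannel neural recording in referential montage."""
    path = Path(path)
    if format == "csv":
        sidecar = path.with_name("channels.json")
        if role_map is None and sidecar.exists():
            meta = json.loads(sidecar.read_text())
            role_map = {c["label"]: c["role"] for c in meta.get("channels", [])}
        df = pd.read_csv(path)
        if "time" not in df.columns:
            raise ValueError("neural CSV must have a 'time' column")
        t = df["time"].to_numpy(float)
        rate = _rate_from_times(t, "neural recording")
        labels = [c for c in df.columns if c != "time"]
        roles = [_infer_role(lab, role_map) for lab in labels]
        return NeuralRecording(
            labels=labels,
            roles=roles,
            rate_hz=rate,
            data=df[labels].to_numpy(float).T,
            montage="referential",
            start_time=float(t[0]),
        )
    if format == "edf":
        import mne

        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        labels = list(raw.ch_names)
        roles = [_infer_role(lab, role_map) for lab in labels]
        return NeuralRecording(
            labels=labels,
            roles=roles,
            rate_hz=float(raw.info["sfreq"]),
            data=raw.get_data() * 1e6,  # MNE stores volts
            montage="referential",
        )
    raise ValueError(f"unknown neural format {format!r}")


def write_neural(rec: NeuralRecording, path: str | Path) -> None:
    """Write a recording as wide CSV plus a ``channels.json`` role sidecar."""
    path = Path(path)
    df = pd.DataFrame({"time": rec.times})
    for lab, row in zip(rec.labels, rec.data):
        df[lab] = row
    df.to_csv(path, index=False)
    sidecar = path.with_name("channels.json")
    sidecar.write_text(
        json.dumps(
            {
                "rate_hz": rec.rate_hz,
                "montage": rec.montage,
                "channels": [
                    {"label": lab, "role": role.value}
                    for lab, role in zip(rec.labels, rec.roles)
                ],
            },
            indent=1,
        )
    )


# ---------------------------------------------------------------------------
# annotations


def read_annotation(path: str | Path) -> FogAnnotation:
    obj = json.loads(Path(path).read_text())
    return FogAnnotation(
        intervals=[tuple(iv) for iv in obj["intervals"]],
        source=obj.get("source", "manual"),
    )


def write_annotation(ann: FogAnnotation, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({"intervals": [list(iv) for iv in ann.intervals], "source": ann.source})
    )


# ---------------------------------------------------------------------------
# alignment


def detect_pulses(
    sync: np.ndarray, rate_hz: float, threshold: float, refractory_s: float = 0.01
) -> np.ndarray:
    """Sample indices of upward threshold crossings with a refractory period."""
    above = sync >= threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if above[0]:
        crossings = np.insert(crossings, 0, 0)
    keep: list[int] = []
    last = -np.inf
    for c in crossings:
        if c - last >= refractory_s * rate_hz:
            keep.append(int(c))
            last = c
    return np.asarray(keep, dtype=int)


def align_streams(
    markers: Sequence[MarkerTrace],
    neural: NeuralRecording,
    pulse_threshold: float = 2.5,
    annotation: FogAnnotation | None = None,
    quality: QualityGrade | None = None,
    subject_id: str = "",
    trial_id: str = "",
) -> SyncedSession:
    """Map gait time zero onto the first TTL pulse and crop to the overlap.

    The returned session uses the gait clock: the neural stream is cropped to
    start at the pulse (and to end at the stop pulse when two pulses are
    present) and ``sync_offset`` records the pulse time on the neural clock.
    """
    sync = neural.sync_channel()
    pulses = detect_pulses(sync, neural.rate_hz, pulse_threshold)
    if len(pulses) == 0:
        peak = float(sync.max()) if sync.size else float("nan")
        raise ValueError(
            f"no sync pulse: no upward crossing of threshold {pulse_threshold} "
            f"(sync channel peak {peak:.3g})"
        )
    if len(pulses) > 2:
        times = (pulses / neural.rate_hz + neural.start_time).round(4).tolist()
        raise ValueError(f"ambiguous sync pulses: {len(pulses)} crossings at t={times}")

    t_start = neural.start_time + pulses[0] / neural.rate_hz
    sync_offset = t_start  # gait clock minus neural clock (neural time of gait zero)
    if len(pulses) == 2:
        t_stop = neural.start_time + pulses[1] / neural.rate_hz
    else:
        t_stop = neural.start_time + neural.duration

    cropped = neural.crop(t_start, t_stop)
    cropped.start_time = 0.0  # re-zero onto the gait/session clock
    gait_end = min(t_stop - t_start, max(m.start_time + m.duration for m in markers))
    out_markers = [m.crop(0.0, gait_end) for m in markers]
    cropped = cropped.crop(0.0, gait_end) if cropped.duration > gait_end else cropped

    ann = annotation if annotation is not None else FogAnnotation([], source="manual")
    if ann.intervals:
        last = max(b for _a, b in ann.intervals)
        if last > gait_end + 1e-6:
            raise ValueError(
                f"annotation extends to {last:.3f} s beyond the aligned overlap "
                f"({gait_end:.3f} s)"
            )
    return SyncedSession(
        subject_id=subject_id,
        trial_id=trial_id,
        markers=out_markers,
        neural=cropped,
        annotation=ann,
        quality=quality if quality is not None else QualityGrade(1),
        sync_offset=float(sync_offset),
    )


def screen_quality(
    sessions: Sequence[SyncedSession], max_level: int = 2
) -> list[SyncedSession]:
    """Retain sessions graded at or below ``max_level`` (1-2 = analyzable)."""
    kept = [s for s in sessions if s.quality.level <= max_level]
    logger.info(
        "quality screen: retained %d/%d sessions at level <= %d",
        len(kept),
        len(sessions),
        max_level,
    )
    return kept


# ---------------------------------------------------------------------------
# whole-session round trip


def write_session(session: SyncedSession, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_markers(session.markers, directory / "markers.csv")
    if session.neural is not None:
        write_neural(session.neural, directory / "neural.csv")
    write_annotation(session.annotation, directory / "annotation.json")
    (directory / "meta.json").write_text(
        json.dumps(
            {
                "subject_id": session.subject_id,
                "trial_id": session.trial_id,
                "quality": {"level": session.quality.level, "note": session.quality.note},
                "sync_offset": session.sync_offset,
            },
            indent=1,
        )
    )
    return directory


def read_session(directory: str | Path) -> SyncedSession:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    markers = read_markers(directory / "markers.csv")
    neural = None
    if (directory / "neural.csv").exists():
        neural = read_neural(directory / "neural.csv")
        sidecar = json.loads((directory / "channels.json").read_text())
        neural.montage = sidecar.get("montage", "referential")
    return SyncedSession(
        subject_id=meta["subject_id"],
        trial_id=meta["trial_id"],
        markers=markers,
        neural=neural,
        annotation=read_annotation(directory / "annotation.json"),
        quality=QualityGrade(**meta["quality"]),
        sync_offset=float(meta["sync_offset"]),
    )
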