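"""Neural preprocessing and FOG vs non-FOG band-power contrasts.

Preprocessing follows the standard intracranial pipeline: anti-alias
decimation to 1000 Hz, zero-phase notch filtering of the 50 Hz mains and its
harmonics, and re-referencing to a bipolar montage of successive contacts
within each electrode (strip 1-2 ... 7-8; each depth lead 1-2, 2-3, 3-4) to
suppress the shared reference and common-mode artifacts.

Time-frequency power uses a complex Morlet wavelet transform on a 38-point
log-spaced frequency grid spanning 1-170 Hz; band averages over seven
canonical bands (delta 1-3, theta 4-7, alpha 8-12, beta1 13-20, beta2 21-35,
gamma 36-69, high gamma 70-170 Hz) are compared between walking states with
a paired t-test per band, pooling depth channels as STN-LFP and strip
channels as ECoG.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.signal
import scipy.stats

from fogsync.session import ChannelRole, FogAnnotation, NeuralRecording

logger = logging.getLogger(__name__)

__all__ = [
    "BandScheme",
    "PAPER7",
    "CLASSIFIER6",
    "TfDecomposition",
    "default_frequencies",
    "preprocess",
    "artifact_screen",
    "morlet_tf",
    "band_average",
    "band_contrast",
]


@dataclass
class BandScheme:
    """Named ordered list of (label, low Hz, high Hz) frequency bands."""

    name: str
    bands: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        labels = [b[0] for b in self.bands]
        if len(set(labels)) != len(labels):
            raise ValueError("band labels must be unique")
        for lab, low, high in self.bands:
            if not 0 < low < high:
                raise ValueError(f"band {lab!r}: need 0 < low < high, got ({low}, {high})")

    def __iter__(self):
        return iter(self.bands)


#: Seven-band scheme used for the walking-state power contrast.
PAPER7 = BandScheme(
    "paper7",
    [
        ("delta", 1.0, 3.0),
        ("theta", 4.0, 7.0),
        ("alpha", 8.0, 12.0),
        ("beta1", 13.0, 20.0),
        ("beta2", 21.0, 35.0),
        ("gamma", 36.0, 69.0),
        ("high_gamma", 70.0, 170.0),
    ],
)

#: Six-band scheme used for classifier epoch features.
CLASSIFIER6 = BandScheme(
    "classifier6",
    [
        ("delta", 1.0, 3.0),
        ("theta", 3.0, 8.0),
        ("alpha", 8.0, 13.0),
        ("beta", 13.0, 30.0),
        ("gamma", 30.0, 60.0),
        ("hfo", 60.0, 300.0),
    ],
)


def default_frequencies(n: int = 38, low: float = 1.0, high: float = 170.0) -> np.ndarray:
    """Log-spaced Morlet frequency grid, ``f_k = low * (high/low)^((k-1)/(n-1))``."""
    return np.geomspace(low, high, n)


@dataclass
class TfDecomposition:
    """Morlet power per channel x frequency x time, with an edge-validity mask."""

    labels: list[str]
    roles: list[ChannelRole]
    frequencies: np.ndarray
    power: np.ndarray  # (C, F, T), a.u.^2
    rate_hz: float
    times: np.ndarray  # session clock, length T
    valid: np.ndarray  # (F, T) bool; False within one wavelet half-length of an edge

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")


def preprocess(rec: NeuralRecording) -> NeuralRecording:
    """Decimate to 1000 Hz, notch 50 Hz + harmonics, re-reference to bipolar.

    Accepts the acquisition rates 2000 Hz (decimated by 2 with a zero-phase
    FIR anti-alias filter) or 1000 Hz (passed through). The sync channel is
    consumed by alignment and dropped here. Raises on already-bipolar input.
    """
    if rec.montage == "bipolar":
        raise ValueError("recording is already in bipolar montage")
    if rec.rate_hz not in (2000.0, 1000.0):
        raise ValueError(f"expected 2000 or 1000 Hz input, got {rec.rate_hz}")

    keep = [i for i, r in enumerate(rec.roles) if r != ChannelRole.SYNC]
    labels = [rec.labels[i] for i in keep]
    roles = [rec.roles[i] for i in keep]
    data = rec.data[keep]

    rate = rec.rate_hz
    if rate == 2000.0:
        data = scipy.signal.decimate(data, q=2, ftype="fir", zero_phase=True, axis=-1)
        rate = 1000.0

    for f0 in np.arange(50.0, 451.0, 50.0):
        b, a = scipy.signal.iirnotch(w0=f0, Q=35.0, fs=rate)
        data = scipy.signal.filtfilt(b, a, data, axis=-1)

    # successive-contact bipolar pairs within each electrode
    def contact_no(label: str) -> int:
        m = re.search(r"(\d+)\s*$", label)
        return int(m.group(1)) if m else 0

    bi_labels: list[str] = []
    bi_roles: list[ChannelRole] = []
    bi_rows: list[np.ndarray] = []
    for role in (ChannelRole.STRIP, ChannelRole.DEPTH_RIGHT, ChannelRole.DEPTH_LEFT):
        idx = [i for i, r in enumerate(roles) if r == role]
        idx.sort(key=lambda i: contact_no(labels[i]))
        for a_i, b_i in zip(idx, idx[1:]):
            bi_labels.append(f"{labels[a_i]}-{labels[b_i]}")
            bi_roles.append(role)
            bi_rows.append(data[a_i] - data[b_i])
    if not bi_rows:
        raise ValueError("no strip/depth channels available for bipolar montage")

    return NeuralRecording(
        labels=bi_labels,
        roles=bi_roles,
        rate_hz=rate,
        data=np.vstack(bi_rows),
        montage="bipolar",
        hardware_band=rec.hardware_band,
        start_time=rec.start_time,
    )


def artifact_screen(
    rec: NeuralRecording,
    max_abs_uv: float = 2000.0,
    max_drift_uv_per_s: float = 100.0,
) -> tuple[bool, list[str]]:
    """Amplitude + linear-drift screen standing in for manual artifact review.

    Returns ``(ok, reasons)``; a channel fails on peak absolute amplitude
    above ``max_abs_uv`` or on a fitted linear drift steeper than
    ``max_drift_uv_per_s``.
    """
    reasons: list[str] = []
    t = rec.times
    for lab, row in zip(rec.labels, rec.data):
        peak = float(np.abs(row).max())
        if peak > max_abs_uv:
            reasons.append(f"{lab}: peak {peak:.0f} uV > {max_abs_uv}")
            continue
        slope = float(np.polyfit(t, row, 1)[0])
        if abs(slope) > max_drift_uv_per_s:
            reasons.append(f"{lab}: drift {slope:.1f} uV/s > {max_drift_uv_per_s}")
    return (len(reasons) == 0, reasons)


def morlet_tf(
    rec: NeuralRecording,
    frequencies: np.ndarray | None = None,
    n_cycles: float = 7.0,
    decim: int = 1,
) -> TfDecomposition:
    """Morlet wavelet power of every channel.

    Power is ``|convolution with a complex Morlet wavelet|^2`` per channel and
    frequency (MNE's ``tfr_array_morlet``). Samples within one wavelet
    half-length (``n_cycles / (2 f)`` seconds) of either edge are marked
    invalid in ``valid`` and excluded from band averages.
    """
    from mne.time_frequency import tfr_array_morlet

    freqs = default_frequencies() if frequencies is None else np.asarray(frequencies, float)
    nyq = rec.rate_hz / 2.0
    if np.any(freqs >= nyq):
        raise ValueError(f"frequencies {freqs[freqs >= nyq]} at or above Nyquist ({nyq} Hz)")
    power = tfr_array_morlet(
        rec.data[np.newaxis],
        sfreq=rec.rate_hz,
        freqs=freqs,
        n_cycles=n_cycles,
        output="power",
        decim=decim,
        verbose="error",
    )[0]
    times = rec.times[::decim]
    half = n_cycles / (2.0 * freqs)  # seconds, per frequency
    rel = times - rec.start_time
    dur = rec.n_samples / rec.rate_hz
    valid = (rel[np.newaxis, :] >= half[:, np.newaxis]) & (
        rel[np.newaxis, :] <= dur - half[:, np.newaxis]
    )
    return TfDecomposition(
        labels=list(rec.labels),
        roles=list(rec.roles),
        frequencies=freqs,
        power=power,
        rate_hz=rec.rate_hz / decim,
        times=times,
        valid=valid,
    )


_GROUP_OF_ROLE = {
    ChannelRole.STRIP: "ECoG",
    ChannelRole.DEPTH_LEFT: "STN",
    ChannelRole.DEPTH_RIGHT: "STN",
}


def band_average(
    tf: TfDecomposition,
    scheme: BandScheme = PAPER7,
    annotation: FogAnnotation | None = None,
    trial_id: str = "",
) -> pd.DataFrame:
    """Mean power per (channel, band, state) as a tidy table.

    Band membership is the closed interval ``[low, high]`` on grid
    frequencies; the state of a time sample is FOG when it falls inside an
    annotated interval. Invalid (edge) samples are excluded per frequency.
    Raises if a band contains no grid frequency.
    """
    annotation = annotation or FogAnnotation([], source="ground_truth")
    in_fog = annotation.contains(tf.times)
    states = [("FOG", in_fog), ("nonFOG", ~in_fog)]
    rows = []
    for band_label, low, high in scheme:
        fmask = (tf.frequencies >= low) & (tf.frequencies <= high)
        if not fmask.any():
            raise ValueError(
                f"band {band_label!r} ({low}-{high} Hz) contains no grid frequency"
            )
        for ci, (ch, role) in enumerate(zip(tf.labels, tf.roles)):
            for state, smask in states:
                sel = tf.valid[fmask][:, smask]  # (F_band, T_state) validity
                vals = tf.power[ci][fmask][:, smask]
                n = int(sel.sum())
                value = float(vals[sel].mean()) if n else np.nan
                rows.append(
                    {
                        "trial": trial_id,
                        "channel": ch,
                        "group": _GROUP_OF_ROLE.get(role, "other"),
                        "band": band_label,
                        "state": state,
                        "value": value,
                        "n_samples": n,
                    }
                )
    return pd.DataFrame(rows)


def band_contrast(table: pd.DataFrame, log_transform: bool = True) -> pd.DataFrame:
    """Paired t-test of FOG vs non-FOG band power across trials.

    Depth channels pool as the STN-LFP group and strip channels as ECoG;
    within a trial, channel values are averaged per (group, band, state).
    Power is log10-transformed by default before the paired test. Trials
    missing either state for a cell are excluded with a warning.
    """
    df = table.dropna(subset=["value"])
    cell = (
        df.groupby(["trial", "group", "band", "state"], sort=False)["value"]
        .mean()
        .reset_index()
    )
    if log_transform:
        cell["value"] = np.log10(cell["value"])
    out = []
    for (group, band), g in cell.groupby(["group", "band"], sort=False):
        wide = g.pivot(index="trial", columns="state", values="value")
        if "FOG" not in wide.columns or "nonFOG" not in wide.columns:
            continue
        incomplete = wide.isna().any(axis=1)
        if incomplete.any():
            logger.warning(
                "band_contrast %s/%s: excluding %d single-state trial(s)",
                group,
                band,
                int(incomplete.sum()),
            )
        wide = wide.dropna()
        if len(wide) < 2:
            continue
        t, p = scipy.stats.ttest_rel(wide["FOG"], wide["nonFOG"])
        out.append(
            {
                "group": group,
                "band": band,
                "t": float(t),
                "p": float(p),
                "mean_fog": float(wide["FOG"].mean()),
                "mean_nonfog": float(wide["nonFOG"].mean()),
                "n_trials": int(len(wide)),
            }
        )
    return pd.DataFrame(out)
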