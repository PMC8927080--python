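"""Freeze-index (FI) computation from the heel vertical trace.

The FI quantifies freezing of gait from lower-limb acceleration as the ratio
of spectral power in the freeze band (3-8 Hz, trembling-in-place) to the
locomotor band (0.5-3 Hz, stepping); high FI indicates freezing. Because the
motion-capture system records position rather than acceleration, the vertical
trace is first baseline-corrected by morphological opening (grayscale erosion
followed by dilation, so a constant offset maps to zero) and twice
differentiated to instantaneous acceleration. Power is then estimated per
Hann-tapered short-time-FFT window and the band ratio is reported at each
window centre.

Windows whose locomotor-band power is exactly zero yield ``+inf`` and are
flagged rather than dropped, so degenerate inputs stay visible downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import scipy.ndimage
import scipy.signal
import scipy.stats

from fogsync.session import FogAnnotation, MarkerTrace

logger = logging.getLogger(__name__)

__all__ = [
    "FiParams",
    "FreezeIndexSeries",
    "PairedContrast",
    "erode_baseline",
    "second_derivative",
    "freeze_index",
    "fi_contrast",
]


@dataclass
class FiParams:
    """Bands and short-time-FFT geometry for the freeze index.

    ``window_s`` must resolve the lowest locomotor frequency (two full cycles
    of the band's low edge fit in one window).
    """

    locomotor_band: tuple[float, float] = (0.5, 3.0)
    freeze_band: tuple[float, float] = (3.0, 8.0)
    window_s: float = 4.0
    step_s: float = 0.5
    erosion_element_s: float = 2.0

    def __post_init__(self) -> None:
        lo_l, hi_l = self.locomotor_band
        lo_f, hi_f = self.freeze_band
        if not (0 < lo_l < hi_l and 0 < lo_f < hi_f):
            raise ValueError("bands must be positive with low < high")
        if hi_l > lo_f:
            raise ValueError(
                f"locomotor band {self.locomotor_band} overlaps freeze band "
                f"{self.freeze_band}"
            )
        if self.window_s < 2.0 / lo_l:
            raise ValueError(
                f"window_s={self.window_s} cannot resolve the {lo_l} Hz locomotor "
                f"band edge; need >= {2.0 / lo_l} s"
            )
        if self.step_s <= 0 or self.erosion_element_s <= 0:
            raise ValueError("step_s and erosion_element_s must be positive")


@dataclass
class FreezeIndexSeries:
    """Windowed FI values at window-centre times (session clock)."""

    times: np.ndarray
    fi: np.ndarray
    params: FiParams
    flagged: np.ndarray = field(default=None)  # type: ignore[assignment]
    """True where locomotor power was zero and FI was set to +inf."""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fi = np.asarray(self.fi, dtype=float)
        if self.flagged is None:
            self.flagged = ~np.isfinite(self.fi)
        if len(self.times) != len(self.fi):
            raise ValueError("times and fi must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.fi[~self.flagged] < 0):
            raise ValueError("FI values must be non-negative")


def erode_baseline(trace: MarkerTrace, element_s: float = 2.0) -> MarkerTrace:
    """Baseline-correct the vertical component by morphological opening.

    The opening (grayscale erosion then dilation with a flat structuring
    element of ``element_s`` seconds) tracks the lower envelope of the trace;
    subtracting it removes slow drift and any constant offset while keeping
    oscillations faster than ``1/element_s`` Hz. The result is >= 0 everywhere
    because an opening never exceeds its input.
    """
    size = int(round(element_s * trace.rate_hz))
    if size < 1:
        raise ValueError(f"element_s={element_s} is shorter than one sample")
    if size > trace.n_samples:
        raise ValueError(
            f"structuring element ({size} samples) longer than trace "
            f"({trace.n_samples} samples)"
        )
    z = trace.z
    opened = scipy.ndimage.grey_opening(z, size=size, mode="nearest")
    corrected = z - opened
    positions = trace.positions.copy()
    positions[:, 2] = corrected
    return replace(trace, positions=positions)


def second_derivative(trace: MarkerTrace) -> np.ndarray:
    """Instantaneous vertical acceleration (mm/s^2) by second differences.

    Interior samples use the central second difference; the endpoints reuse
    the one-sided second difference of their nearest interior neighbour, so
    the output length equals the input length and quadratics are exact.
    """
    if trace.n_samples < 3:
        raise ValueError("need at least 3 samples for a second derivative")
    z = trace.z
    r2 = trace.rate_hz**2
    acc = np.empty_like(z)
    acc[1:-1] = (z[:-2] - 2 * z[1:-1] + z[2:]) * r2
    acc[0] = (z[0] - 2 * z[1] + z[2]) * r2
    acc[-1] = (z[-3] - 2 * z[-2] + z[-1]) * r2
    return acc


def _band_power(power: np.ndarray, freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    """Sum FFT power over bins whose centre lies in the half-open band."""
    mask = (freqs >= band[0]) & (freqs < band[1])
    return power[..., mask].sum(axis=-1)


def freeze_index(
    accel: np.ndarray,
    rate_hz: float,
    params: FiParams | None = None,
    start_time: float = 0.0,
) -> FreezeIndexSeries:
    """Windowed freeze index of an acceleration series.

    Each Hann-tapered window of ``params.window_s`` seconds (hop
    ``params.step_s``) contributes one value
    ``FI = sum power in freeze_band / sum power in locomotor_band``,
    with band membership on half-open bins ``[low, high)``. Window centres
    are reported on the session clock.
    """
    params = params or FiParams()
    accel = np.asarray(accel, dtype=float)
    n = int(round(params.window_s * rate_hz))
    hop = int(round(params.step_s * rate_hz))
    if accel.size < n:
        raise ValueError(
            f"signal of {accel.size / rate_hz:.2f} s shorter than one "
            f"{params.window_s} s window"
        )
    n_win = 1 + (accel.size - n) // hop
    window = scipy.signal.get_window("hann", n, fftbins=True)
    starts = np.arange(n_win) * hop
    segs = np.lib.stride_tricks.sliding_window_view(accel, n)[starts]
    spec = np.fft.rfft(segs * window, axis=1)
    power = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(n, 1.0 / rate_hz)
    p_freeze = _band_power(power, freqs, params.freeze_band)
    p_loco = _band_power(power, freqs, params.locomotor_band)
    flagged = p_loco == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        fi = np.where(flagged, np.inf, p_freeze / np.where(flagged, 1.0, p_loco))
    if flagged.any():
        logger.warning("freeze_index: %d window(s) with zero locomotor power", flagged.sum())
    times = start_time + (starts + n / 2.0) / rate_hz
    return FreezeIndexSeries(times=times, fi=fi, params=params, flagged=flagged)


@dataclass
class PairedContrast:
    """Result of a paired FOG vs non-FOG comparison across trials."""

    mean_fog: float
    mean_nonfog: float
    t: float
    p: float
    n_trials: int
    per_trial: "np.ndarray | None" = None  # (n_trials, 2) FOG / non-FOG means

    def as_dict(self) -> dict:
        return {
            "mean_fog": self.mean_fog,
            "mean_nonfog": self.mean_nonfog,
            "t": self.t,
            "p": self.p,
            "n_trials": self.n_trials,
        }


def fi_contrast(
    trials: Sequence[tuple[FreezeIndexSeries, FogAnnotation]],
) -> PairedContrast:
    """Paired t-test of per-trial mean FI, FOG vs non-FOG windows.

    A window belongs to the FOG state when its centre lies inside any
    annotated interval. Trials lacking either state (or whose windows are all
    flagged) are excluded with a warning; at least two contributing trials
    are required.
    """
    rows = []
    for series, annotation in trials:
        valid = ~series.flagged
        in_fog = annotation.contains(series.times) & valid
        in_non = ~annotation.contains(series.times) & valid
        if not in_fog.any() or not in_non.any():
            logger.warning(
                "fi_contrast: trial excluded (windows FOG=%d, nonFOG=%d)",
                int(in_fog.sum()),
                int(in_non.sum()),
            )
            continue
        rows.append((series.fi[in_fog].mean(), series.fi[in_non].mean()))
    if len(rows) < 2:
        raise ValueError(
            f"paired FI contrast needs >= 2 trials with both states, got {len(rows)}"
        )
    arr = np.asarray(rows)
    t, p = scipy.stats.ttest_rel(arr[:, 0], arr[:, 1])
    return PairedContrast(
        mean_fog=float(arr[:, 0].mean()),
        mean_nonfog=float(arr[:, 1].mean()),
        t=float(t),
        p=float(p),
        n_trials=len(rows),
        per_trial=arr,
    )
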