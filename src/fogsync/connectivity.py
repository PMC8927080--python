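"""Cortico-subthalamic coherence with surrogate-based significance.

Coherence between a cortical (strip) and a subthalamic (depth) bipolar
channel is the magnitude of the segment-averaged cross-spectrum normalized by
the averaged auto-spectra,

    C(f) = |E[Sxy]| / sqrt(E[Sxx] * E[Syy]),

with Welch segmentation (Hann taper, 1 s segments, 50% overlap by default)
and the result interpolated onto the 1-200 Hz integer grid. Note this is
*magnitude* coherence, not magnitude-squared; ``squared=True`` gives the
conventional squared variant.

Significance is calibrated against shuffled surrogates that preserve each
channel's spectrum while destroying cross-channel alignment (random circular
time-shift of one channel by at least one segment, or segment-order
shuffling). Frequency-wise exceedance p-values are combined by cluster-based
permutation (clusters of contiguous supra-threshold frequencies, max-cluster
null from the surrogates themselves), mapped to named bands, and corrected
across channel pairs by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.signal
import scipy.stats
from statsmodels.stats.multitest import multipletests

from fogsync.session import FogAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "CoherenceResult",
    "DEFAULT_BANDS",
    "coherence_pair",
    "shuffled_surrogates",
    "band_significance",
    "laterality_contrast",
    "state_coherence_contrast",
    "coherence_by_state",
]

#: Bands reported by the surrogate comparison.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "high_beta": (20.0, 35.0),
    "high_gamma": (145.0, 195.0),
}

FREQ_GRID = np.arange(1.0, 201.0)  # 1..200 Hz, 1 Hz step


@dataclass
class CoherenceResult:
    """Coherence spectrum for one channel pair on the 1-200 Hz grid."""

    pair: tuple[str, str, str]  # (cortical label, depth label, "ipsi"|"contra")
    frequencies: np.ndarray
    coherence: np.ndarray
    n_segments: int
    surrogate_null: np.ndarray | None = None  # (n_surrogates, n_freqs)
    significance: pd.DataFrame | None = None
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.coherence = np.asarray(self.coherence, dtype=float)
        if np.any(self.coherence < -1e-12) or np.any(self.coherence > 1 + 1e-12):
            raise ValueError("coherence must lie in [0, 1]")

    def band_mean(self, band: tuple[float, float]) -> float:
        low, high = band
        mask = (self.frequencies >= low) & (self.frequencies <= high)
        return float(self.coherence[mask].mean())


def _segment_ffts(
    x: np.ndarray, rate_hz: float, segment_s: float, overlap: float
) -> tuple[np.ndarray, np.ndarray]:
    """Hann-tapered, mean-detrended rFFTs of Welch segments: (K, F) and freqs."""
    nper = int(round(segment_s * rate_hz))
    hop = nper - int(round(overlap * nper))
    if hop < 1:
        raise ValueError(f"overlap {overlap} leaves no hop")
    if len(x) < nper:
        raise ValueError(f"signal shorter than one {segment_s} s segment")
    n_seg = 1 + (len(x) - nper) // hop
    starts = np.arange(n_seg) * hop
    segs = np.lib.stride_tricks.sliding_window_view(np.asarray(x, float), nper)[starts]
    segs = segs - segs.mean(axis=1, keepdims=True)
    window = scipy.signal.get_window("hann", nper, fftbins=True)
    F = np.fft.rfft(segs * window, axis=1)
    freqs = np.fft.rfftfreq(nper, 1.0 / rate_hz)
    return F, freqs


def _coherence_from_ffts(Fx: np.ndarray, Fy: np.ndarray, squared: bool) -> np.ndarray:
    sxy = (Fx * np.conj(Fy)).mean(axis=0)
    sxx = (np.abs(Fx) ** 2).mean(axis=0)
    syy = (np.abs(Fy) ** 2).mean(axis=0)
    denom = np.sqrt(sxx * syy)
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.where(denom > 0, np.abs(sxy) / denom, 0.0)
    coh = np.clip(coh, 0.0, 1.0)
    return coh**2 if squared else coh


def coherence_pair(
    x: np.ndarray,
    y: np.ndarray,
    rate_hz: float,
    segment_s: float = 1.0,
    overlap: float = 0.5,
    squared: bool = False,
    pair: tuple[str, str, str] = ("x", "y", "ipsi"),
    trial_id: str = "",
    freq_grid: np.ndarray | None = None,
) -> CoherenceResult:
    """Segment-averaged coherence of two aligned signals on the 1-200 Hz grid.

    Requires at least two segments (one segment's coherence is identically 1).
    """
    if len(x) != len(y):
        raise ValueError(f"signals must have equal length ({len(x)} vs {len(y)})")
    Fx, freqs = _segment_ffts(x, rate_hz, segment_s, overlap)
    Fy, _ = _segment_ffts(y, rate_hz, segment_s, overlap)
    if Fx.shape[0] < 2:
        raise ValueError(
            f"coherence needs >= 2 segments, got {Fx.shape[0]} "
            f"({len(x) / rate_hz:.2f} s at {segment_s} s segments)"
        )
    grid = FREQ_GRID if freq_grid is None else np.asarray(freq_grid, float)
    if grid.max() > freqs.max():
        raise ValueError(
            f"grid extends to {grid.max()} Hz but segments resolve only "
            f"{freqs.max()} Hz"
        )
    coh = _coherence_from_ffts(Fx, Fy, squared)
    return CoherenceResult(
        pair=pair,
        frequencies=grid,
        coherence=np.interp(grid, freqs, coh),
        n_segments=int(Fx.shape[0]),
        trial_id=trial_id,
    )


def shuffled_surrogates(
    x: np.ndarray,
    y: np.ndarray,
    rate_hz: float,
    n_surrogates: int = 200,
    method: str = "circular_shift",
    segment_s: float = 1.0,
    overlap: float = 0.5,
    squared: bool = False,
    seed: int | np.random.Generator = 0,
    freq_grid: np.ndarray | None = None,
) -> np.ndarray:
    """Null coherence spectra with cross-channel alignment destroyed.

    ``circular_shift`` rolls ``y`` by a random offset of at least one segment
    length before re-segmenting (each channel's spectrum is untouched);
    ``segment_shuffle`` permutes the order of ``y``'s Welch segments, which
    reuses the per-segment FFTs and is much faster. Returns an
    ``(n_surrogates, n_freqs)`` array on the same grid as
    :func:`coherence_pair`.
    """
    if n_surrogates < 100:
        raise ValueError(f"need >= 100 surrogates for stable nulls, got {n_surrogates}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid = FREQ_GRID if freq_grid is None else np.asarray(freq_grid, float)
    nper = int(round(segment_s * rate_hz))
    Fx, freqs = _segment_ffts(x, rate_hz, segment_s, overlap)
    null = np.empty((n_surrogates, len(grid)))
    if method == "segment_shuffle":
        Fy, _ = _segment_ffts(y, rate_hz, segment_s, overlap)
        k = Fy.shape[0]
        for s in range(n_surrogates):
            coh = _coherence_from_ffts(Fx, Fy[rng.permutation(k)], squared)
            null[s] = np.interp(grid, freqs, coh)
        return null
    if method == "circular_shift":
        n = len(y)
        if n < 2 * nper:
            raise ValueError(
                f"signal of {n} samples too short for a >= 1 segment "
                f"({nper} samples) circular shift"
            )
        for s in range(n_surrogates):
            shift = int(rng.integers(nper, n - nper + 1))
            Fy, _ = _segment_ffts(np.roll(y, shift), rate_hz, segment_s, overlap)
            coh = _coherence_from_ffts(Fx, Fy, squared)
            null[s] = np.interp(grid, freqs, coh)
        return null
    raise ValueError(f"unknown surrogate method {method!r}")


def _clusters(mask: np.ndarray) -> list[np.ndarray]:
    """Index arrays of contiguous True runs."""
    out = []
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return out
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    return [c for c in np.split(idx, splits)]


def band_significance(
    results: Sequence[CoherenceResult],
    bands: Mapping[str, tuple[float, float]] = DEFAULT_BANDS,
    alpha: float = 0.05,
    n_permutations: int | None = None,
) -> pd.DataFrame:
    """Cluster-permutation + FDR verdicts per (pair, band).

    Per frequency, ``p = (1 + #{null >= observed}) / (1 + S)`` against each
    pair's surrogate null. Contiguous frequencies with ``p < alpha`` form
    clusters scored by the summed exceedance over the null mean; the null of
    maximum cluster scores is built by passing each surrogate through the same
    clustering. Cluster p-values from all pairs are corrected together by
    Benjamini-Hochberg FDR at ``alpha``, and a band verdict is significant
    when a surviving cluster overlaps the band. Pairs with no supra-threshold
    frequency simply yield non-significant verdicts.
    """
    cluster_rows: list[dict] = []
    for ri, res in enumerate(results):
        if res.surrogate_null is None:
            raise ValueError(f"result {res.pair} carries no surrogate null")
        null = res.surrogate_null
        S = null.shape[0] if n_permutations is None else min(n_permutations, null.shape[0])
        null = null[:S]
        null_mean = null.mean(axis=0)
        # frequency-wise exceedance threshold at alpha
        crit = np.quantile(null, 1.0 - alpha, axis=0)
        obs_mask = res.coherence > crit
        obs_clusters = _clusters(obs_mask)
        # max-cluster null: each surrogate scored against the same threshold
        max_null = np.zeros(S)
        for s in range(S):
            best = 0.0
            for c in _clusters(null[s] > crit):
                best = max(best, float((null[s][c] - null_mean[c]).sum()))
            max_null[s] = best
        for c in obs_clusters:
            score = float((res.coherence[c] - null_mean[c]).sum())
            p_cluster = (1.0 + np.sum(max_null >= score)) / (1.0 + S)
            cluster_rows.append(
                {
                    "result_index": ri,
                    "pair": res.pair,
                    "freq_lo": float(res.frequencies[c[0]]),
                    "freq_hi": float(res.frequencies[c[-1]]),
                    "score": score,
                    "p": float(p_cluster),
                }
            )

    if cluster_rows:
        pvals = np.array([r["p"] for r in cluster_rows])
        reject, p_fdr, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        for row, rej, q in zip(cluster_rows, reject, p_fdr):
            row["p_fdr"] = float(q)
            row["significant"] = bool(rej)

    verdicts = []
    for ri, res in enumerate(results):
        for band_name, (low, high) in bands.items():
            hits = [
                r
                for r in cluster_rows
                if r["result_index"] == ri
                and r["freq_hi"] >= low
                and r["freq_lo"] <= high
            ]
            sig_hits = [r for r in hits if r["significant"]]
            verdicts.append(
                {
                    "cortical": res.pair[0],
                    "depth": res.pair[1],
                    "laterality": res.pair[2],
                    "band": band_name,
                    "significant": bool(sig_hits),
                    "p_cluster": min((r["p"] for r in hits), default=np.nan),
                    "p_fdr": min((r["p_fdr"] for r in sig_hits), default=np.nan)
                    if sig_hits
                    else min((r["p_fdr"] for r in hits), default=np.nan),
                }
            )
    return pd.DataFrame(verdicts)


def laterality_contrast(
    trials: Mapping[str, Sequence[CoherenceResult]],
    band: tuple[float, float] = DEFAULT_BANDS["high_beta"],
) -> dict:
    """Paired t-test of ipsi- vs contralateral band coherence across trials.

    ``trials`` maps trial id to that trial's coherence results; band-mean
    coherence is averaged within each laterality class per trial. Raises if
    any trial lacks a laterality class.
    """
    ipsi, contra = [], []
    for trial_id, results in trials.items():
        by_side: dict[str, list[float]] = {"ipsi": [], "contra": []}
        for res in results:
            if res.pair[2] not in by_side:
                raise ValueError(f"unknown laterality {res.pair[2]!r} in trial {trial_id}")
            by_side[res.pair[2]].append(res.band_mean(band))
        if not by_side["ipsi"] or not by_side["contra"]:
            raise ValueError(
                f"trial {trial_id!r} lacks a laterality class "
                f"(ipsi={len(by_side['ipsi'])}, contra={len(by_side['contra'])})"
            )
        ipsi.append(np.mean(by_side["ipsi"]))
        contra.append(np.mean(by_side["contra"]))
    t, p = scipy.stats.ttest_rel(ipsi, contra)
    return {
        "mean_ipsi": float(np.mean(ipsi)),
        "mean_contra": float(np.mean(contra)),
        "t": float(t),
        "p": float(p),
        "n_trials": len(ipsi),
    }


def coherence_by_state(
    x: np.ndarray,
    y: np.ndarray,
    rate_hz: float,
    annotation: FogAnnotation,
    start_time: float = 0.0,
    segment_s: float = 1.0,
    overlap: float = 0.5,
    squared: bool = False,
    pair: tuple[str, str, str] = ("x", "y", "ipsi"),
    trial_id: str = "",
) -> dict[str, CoherenceResult | None]:
    """Coherence computed separately from FOG and non-FOG Welch segments.

    Segments are kept for a state only when they lie entirely inside (FOG) or
    entirely outside (non-FOG) the annotated intervals; a state with fewer
    than two segments yields ``None`` with a warning (short freezing episodes
    make the FOG estimate underpowered by construction).
    """
    nper = int(round(segment_s * rate_hz))
    hop = nper - int(round(overlap * nper))
    n_seg = 1 + max(0, (len(x) - nper)) // hop
    starts = np.arange(n_seg) * hop
    t0 = start_time + starts / rate_hz
    t1 = t0 + segment_s
    fog_mask = np.zeros(n_seg, dtype=bool)
    non_mask = np.ones(n_seg, dtype=bool)
    for a, b in annotation.intervals:
        inside = (t0 >= a) & (t1 <= b)
        overlaps = (t0 < b) & (t1 > a)
        fog_mask |= inside
        non_mask &= ~overlaps
    Fx, freqs = _segment_ffts(x, rate_hz, segment_s, overlap)
    Fy, _ = _segment_ffts(y, rate_hz, segment_s, overlap)
    out: dict[str, CoherenceResult | None] = {}
    for state, mask in (("FOG", fog_mask), ("nonFOG", non_mask)):
        k = int(mask.sum())
        if k < 2:
            logger.warning(
                "coherence_by_state %s/%s: %d segment(s) in state %s; excluded",
                trial_id,
                pair,
                k,
                state,
            )
            out[state] = None
            continue
        coh = _coherence_from_ffts(Fx[mask], Fy[mask], squared)
        out[state] = CoherenceResult(
            pair=pair,
            frequencies=FREQ_GRID.copy(),
            coherence=np.interp(FREQ_GRID, freqs, coh),
            n_segments=k,
            trial_id=trial_id,
        )
    return out


def state_coherence_contrast(
    trials: Sequence[Mapping[str, CoherenceResult | None]],
    band: tuple[float, float] = DEFAULT_BANDS["high_beta"],
) -> dict:
    """Paired FOG vs non-FOG band-coherence comparison across trials.

    Trials missing either state are excluded (already warned about upstream);
    the result reports segment counts per state so power limitations of short
    freezing episodes stay visible.
    """
    fog_vals, non_vals, n_fog_segs, n_non_segs = [], [], [], []
    for by_state in trials:
        rf, rn = by_state.get("FOG"), by_state.get("nonFOG")
        if rf is None or rn is None:
            continue
        fog_vals.append(rf.band_mean(band))
        non_vals.append(rn.band_mean(band))
        n_fog_segs.append(rf.n_segments)
        n_non_segs.append(rn.n_segments)
    if len(fog_vals) < 2:
        raise ValueError(
            f"state contrast needs >= 2 trials with both states, got {len(fog_vals)}"
        )
    t, p = scipy.stats.ttest_rel(fog_vals, non_vals)
    return {
        "mean_fog": float(np.mean(fog_vals)),
        "mean_nonfog": float(np.mean(non_vals)),
        "t": float(t),
        "p": float(p),
        "n_trials": len(fog_vals),
        "n_segments_fog": n_fog_segs,
        "n_segments_nonfog": n_non_segs,
    }
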