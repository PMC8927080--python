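"""Synthetic synchronized gait + iEEG sessions with known ground truth.

The generator emulates the study conditions of a Timed-Up-and-Go walking
trial in a Parkinson's patient with freezing of gait (FOG):

* heel-marker vertical trace: slow baseline drift plus a locomotor-band
  stepping sinusoid (``step_freq``, 0.5-3 Hz) outside FOG intervals, replaced
  by a freeze-band trembling sinusoid (``tremble_freq``, 3-8 Hz) inside them,
  cross-faded with a cosine taper, plus white measurement noise;
* neural channels (8-contact subdural strip, 2 x 4-contact STN depth leads):
  1/f background plus white noise; depth channels carry a 13-35 Hz beta
  oscillation whose amplitude is multiplied by ``beta_boost`` inside FOG;
  narrowband components shared between strip and depth channels implement
  cortico-subthalamic coupling, with right-hemisphere (ipsilateral) depth
  pairs coupled more strongly by ``laterality``; 50 Hz line noise on every
  channel; a dedicated sync channel carries 5 V TTL pulses at gait start and
  stop;
* per-subject random effects: one Gaussian offset per subject on the log
  band power of all neural channels (equivalently a multiplicative amplitude
  gain), the random-intercept structure the MERF classifier assumes.

Everything is deterministic given ``(config, subject_id, trial_id)``:
per-session random streams are derived from the config seed and CRC32 hashes
of the identifiers.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from fogsync.session import (
    ChannelRole,
    FogAnnotation,
    MarkerTrace,
    NeuralRecording,
    QualityGrade,
    SyncedSession,
)

__all__ = ["SimConfig", "GroundTruth", "generate_session", "generate_cohort"]

#: (low Hz, high Hz, coupling strength in [0,1], laterality factor >= 1)
CouplingBand = tuple[float, float, float, float]


@dataclass
class SimConfig:
    """Generative parameters for one synthetic cohort.

    Amplitudes are mm (gait) or microvolts (neural). Defaults are the fixed
    study conditions used throughout the test suite; channel counts, trial
    duration and ``include_neural`` are problem-size knobs only.
    """

    n_subjects: int = 8
    trials_per_subject: int = 5
    trial_duration: float = 60.0
    gait_rate_hz: float = 200.0
    neural_rate_hz: float = 2000.0
    step_freq: float = 2.0
    step_amplitude: float = 30.0
    tremble_freq: float = 5.0
    tremble_amplitude: float = 10.0
    fog_episodes_per_trial: int = 2
    fog_duration_range: tuple[float, float] = (5.0, 12.0)
    beta_boost: float = 1.5
    coupling_bands: list[CouplingBand] = field(
        default_factory=lambda: [(20.0, 35.0, 0.6, 1.5), (145.0, 195.0, 0.6, 1.0)]
    )
    line_noise_amp: float = 5.0
    noise_sd: float = 2.0
    subject_effect_sd: float = 0.2
    seed: int = 0
    # secondary shape/size parameters
    drift_amplitude: float = 10.0
    drift_freq: float = 0.08
    background_amp: float = 10.0
    beta_amp: float = 5.0
    coupling_amp: float = 5.0
    transition_s: float = 0.5
    edge_margin_s: float = 3.0
    min_gap_s: float = 4.0
    pad_s: float = 1.0
    n_strip_contacts: int = 8
    n_depth_contacts: int = 4
    include_neural: bool = True

    def __post_init__(self) -> None:
        if min(self.gait_rate_hz, self.neural_rate_hz) <= 0:
            raise ValueError("sampling rates must be positive")
        if self.trial_duration <= 0:
            raise ValueError("trial_duration must be positive")
        if not self.tremble_freq > self.step_freq:
            raise ValueError(
                f"tremble_freq ({self.tremble_freq}) must exceed step_freq "
                f"({self.step_freq})"
            )
        lo, hi = self.fog_duration_range
        if not 0 < lo <= hi:
            raise ValueError(f"bad fog_duration_range {self.fog_duration_range}")
        for low, high, strength, lat in self.coupling_bands:
            if not 0 < low < high:
                raise ValueError(f"bad coupling band ({low}, {high})")
            if not 0.0 <= strength <= 1.0:
                raise ValueError(f"coupling strength {strength} outside [0, 1]")
            if lat < 1.0:
                raise ValueError(f"laterality factor {lat} must be >= 1")
        if self.fog_episodes_per_trial > 0:
            need = (
                2 * self.edge_margin_s
                + self.fog_episodes_per_trial * hi
                + (self.fog_episodes_per_trial - 1) * self.min_gap_s
            )
            if need > self.trial_duration:
                raise ValueError(
                    f"{self.fog_episodes_per_trial} FOG episodes of up to {hi} s "
                    f"cannot be placed without overlap in a "
                    f"{self.trial_duration} s trial"
                )


@dataclass
class GroundTruth:
    """What was injected into one session (the oracle for recovery tests)."""

    fog_intervals: list[tuple[float, float]]
    injected_band_effects: dict[str, dict[str, float]]
    coupling_map: dict[tuple[str, str], list[tuple[tuple[float, float], float]]]
    subject_offsets: dict[str, float]


def _session_rng(config: SimConfig, subject_id: str, trial_id: str) -> np.random.Generator:
    key = [
        int(config.seed) % (2**31),
        zlib.crc32(subject_id.encode()),
        zlib.crc32(trial_id.encode()),
    ]
    return np.random.default_rng(np.random.SeedSequence(key))


def _subject_offset(config: SimConfig, subject_id: str) -> float:
    """Per-subject additive offset on log band power, drawn once per subject."""
    if config.subject_effect_sd == 0:
        return 0.0
    rng = np.random.default_rng(
        np.random.SeedSequence(
            [int(config.seed) % (2**31), 0x5EED, zlib.crc32(subject_id.encode())]
        )
    )
    return float(rng.normal(0.0, config.subject_effect_sd))


def _place_fog_intervals(config: SimConfig, rng: np.random.Generator) -> list[tuple[float, float]]:
    k = config.fog_episodes_per_trial
    if k == 0:
        return []
    lo, hi = config.fog_duration_range
    durations = rng.uniform(lo, hi, size=k)
    free = (
        config.trial_duration
        - 2 * config.edge_margin_s
        - durations.sum()
        - (k - 1) * config.min_gap_s
    )
    if free < 0:
        raise ValueError(
            f"cannot place {k} FOG episodes (total {durations.sum():.1f} s) in a "
            f"{config.trial_duration} s trial without overlap"
        )
    # distribute the slack over the k+1 gaps
    extra = rng.dirichlet(np.ones(k + 1)) * free
    intervals = []
    cursor = config.edge_margin_s + extra[0]
    for i in range(k):
        intervals.append((float(cursor), float(cursor + durations[i])))
        cursor += durations[i] + config.min_gap_s + extra[i + 1]
    return intervals


def tapered_mask(
    times: np.ndarray, intervals: Sequence[tuple[float, float]], taper_s: float
) -> np.ndarray:
    """Soft 0/1 indicator of the intervals with cosine ramps of ``taper_s``.

    The ramp is centred on each boundary so the mask reaches 1 ``taper_s/2``
    inside the interval and 0 ``taper_s/2`` outside it.
    """
    env = np.zeros_like(times, dtype=float)
    h = taper_s / 2.0
    for a, b in intervals:
        up = np.clip((times - (a - h)) / max(taper_s, 1e-12), 0.0, 1.0)
        down = np.clip(((b + h) - times) / max(taper_s, 1e-12), 0.0, 1.0)
        ramp_up = 0.5 - 0.5 * np.cos(np.pi * up)
        ramp_down = 0.5 - 0.5 * np.cos(np.pi * down)
        env = np.maximum(env, ramp_up * ramp_down)
    return env


def _one_over_f_noise(n: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD noise with 1/f power spectrum (alpha = 1)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** -0.5
    x = np.fft.irfft(spec * scale, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _band_noise(
    n: int, rate: float, low: float, high: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-SD Gaussian noise band-limited to [low, high] Hz."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    spec[(freqs < low) | (freqs > high)] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _gait_trace(
    config: SimConfig,
    fog: Sequence[tuple[float, float]],
    rng: np.random.Generator,
) -> MarkerTrace:
    n = int(round(config.trial_duration * config.gait_rate_hz))
    t = np.arange(n) / config.gait_rate_hz
    fog_env = tapered_mask(t, fog, config.transition_s)
    walk_env = 1.0 - fog_env
    baseline = config.drift_amplitude * np.sin(
        2 * np.pi * config.drift_freq * t + rng.uniform(0, 2 * np.pi)
    )
    z = (
        baseline
        + config.step_amplitude * walk_env * np.sin(2 * np.pi * config.step_freq * t)
        + config.tremble_amplitude * fog_env * np.sin(2 * np.pi * config.tremble_freq * t)
        + config.noise_sd * rng.standard_normal(n)
    )
    # lateral/forward components are plumbing only: gentle forward progress
    x = 1000.0 * t / max(config.trial_duration, 1e-9) + config.noise_sd * rng.standard_normal(n)
    y = config.noise_sd * rng.standard_normal(n)
    return MarkerTrace(
        marker_name="right_heel",
        rate_hz=config.gait_rate_hz,
        positions=np.column_stack([x, y, z]),
        start_time=0.0,
    )


def _channel_layout(config: SimConfig) -> tuple[list[str], list[ChannelRole]]:
    labels: list[str] = []
    roles: list[ChannelRole] = []
    for i in range(1, config.n_strip_contacts + 1):
        labels.append(f"RStrip{i}")
        roles.append(ChannelRole.STRIP)
    for i in range(1, config.n_depth_contacts + 1):
        labels.append(f"RDepth{i}")
        roles.append(ChannelRole.DEPTH_RIGHT)
    for i in range(1, config.n_depth_contacts + 1):
        labels.append(f"LDepth{i}")
        roles.append(ChannelRole.DEPTH_LEFT)
    labels.append("SYNC")
    roles.append(ChannelRole.SYNC)
    return labels, roles


def _neural_block(
    config: SimConfig,
    fog: Sequence[tuple[float, float]],
    gain: float,
    rng: np.random.Generator,
) -> tuple[NeuralRecording, dict[str, dict[str, float]], dict]:
    rate = config.neural_rate_hz
    n = int(round((config.trial_duration + 2 * config.pad_s) * rate))
    # neural stream starts pad_s before gait time zero (session clock)
    t = -config.pad_s + np.arange(n) / rate
    labels, roles = _channel_layout(config)
    data = np.zeros((len(labels), n))

    beta_band = (13.0, 35.0)
    fog_env = tapered_mask(t, fog, config.transition_s)
    beta_gain = 1.0 + (config.beta_boost - 1.0) * fog_env

    line_phase = rng.uniform(0, 2 * np.pi)
    line = np.sin(2 * np.pi * 50.0 * t + line_phase)

    # Shared coupling sources (one per band) and per-electrode independent
    # counterparts. Sources enter each contact with an alternating spatial
    # gain so successive-contact bipolar differences retain them, and the
    # shared/independent mix is per electrode so the mixing ratio (the
    # coupling strength) survives bipolar re-referencing exactly.
    shared = [
        _band_noise(n, rate, low, high, rng) for (low, high, _s, _l) in config.coupling_bands
    ]
    indep = {
        role: [
            _band_noise(n, rate, low, high, rng)
            for (low, high, _s, _l) in config.coupling_bands
        ]
        for role in (ChannelRole.DEPTH_RIGHT, ChannelRole.DEPTH_LEFT)
    }

    def contact_gain(i: int) -> float:
        return 1.0 + 0.4 * (-1.0) ** i

    coupling_map: dict[tuple[str, str], list[tuple[tuple[float, float], float]]] = {
        ("strip", "depth_right"): [],
        ("strip", "depth_left"): [],
    }
    for (low, high, strength, lat), _src in zip(config.coupling_bands, shared):
        c_right = min(1.0, strength * lat)
        coupling_map[("strip", "depth_right")].append(((low, high), c_right))
        coupling_map[("strip", "depth_left")].append(((low, high), strength))

    contact_counter: dict[ChannelRole, int] = {}
    for idx, (lab, role) in enumerate(zip(labels, roles)):
        if role == ChannelRole.SYNC:
            continue
        contact = contact_counter.get(role, 0)
        contact_counter[role] = contact + 1
        ch = config.background_amp * gain * _one_over_f_noise(n, rate, rng)
        ch += config.noise_sd * rng.standard_normal(n)
        ch += config.line_noise_amp * rng.uniform(0.8, 1.2) * line
        if role in (ChannelRole.DEPTH_LEFT, ChannelRole.DEPTH_RIGHT):
            beta = _band_noise(n, rate, *beta_band, rng)
            ch += config.beta_amp * gain * beta_gain * beta
        g_i = contact_gain(contact)
        for bi, ((low, high, strength, lat), src) in enumerate(
            zip(config.coupling_bands, shared)
        ):
            if role == ChannelRole.STRIP:
                ch += config.coupling_amp * gain * g_i * src
            else:
                c = min(1.0, strength * lat) if role == ChannelRole.DEPTH_RIGHT else strength
                mix = c * src + np.sqrt(max(0.0, 1.0 - c**2)) * indep[role][bi]
                ch += config.coupling_amp * gain * g_i * mix
        data[idx] = ch

    # TTL pulses (5 V, 100 ms) at gait start and stop
    sync = np.zeros(n)
    width = int(round(0.1 * rate))
    for t_pulse in (0.0, config.trial_duration):
        i0 = int(round((t_pulse + config.pad_s) * rate))
        sync[i0 : min(n, i0 + width)] = 5.0
    data[-1] = sync

    rec = NeuralRecording(
        labels=labels,
        roles=roles,
        rate_hz=rate,
        data=data,
        montage="referential",
        start_time=-config.pad_s,
    )
    effects = {
        "depth": {"beta_13_35": float(config.beta_boost)},
        "strip": {},
    }
    return rec, effects, coupling_map


def generate_session(
    config: SimConfig,
    subject_id: str = "S01",
    trial_id: str = "T01",
    subject_offset: float | None = None,
) -> tuple[SyncedSession, GroundTruth]:
    """Generate one synchronized walking trial plus its ground truth.

    ``subject_offset`` (log band-power units) is normally drawn internally,
    deterministically per subject, so all trials of a subject share it.
    """
    rng = _session_rng(config, subject_id, trial_id)
    fog = _place_fog_intervals(config, rng)
    if subject_offset is None:
        subject_offset = _subject_offset(config, subject_id)
    gain = float(np.exp(subject_offset / 2.0))  # additive on log power

    heel = _gait_trace(config, fog, rng)

    neural = None
    effects: dict[str, dict[str, float]] = {}
    coupling: dict = {}
    if config.include_neural:
        neural, effects, coupling = _neural_block(config, fog, gain, rng)

    annotation = FogAnnotation(intervals=list(fog), source="ground_truth")
    session = SyncedSession(
        subject_id=subject_id,
        trial_id=trial_id,
        markers=[heel],
        neural=neural,
        annotation=annotation,
        quality=QualityGrade(1, "synthetic"),
        sync_offset=config.pad_s if config.include_neural else 0.0,
    )
    truth = GroundTruth(
        fog_intervals=list(fog),
        injected_band_effects=effects,
        coupling_map=coupling,
        subject_offsets={subject_id: float(subject_offset)},
    )
    return session, truth


def generate_cohort(config: SimConfig) -> list[tuple[SyncedSession, GroundTruth]]:
    """One session per (subject, trial); subject offsets drawn once per subject."""
    if config.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    out = []
    for s in range(1, config.n_subjects + 1):
        subject_id = f"S{s:02d}"
        offset = _subject_offset(config, subject_id)
        for tr in range(1, config.trials_per_subject + 1):
            trial_id = f"S{s:02d}T{tr:02d}"
            out.append(generate_session(config, subject_id, trial_id, subject_offset=offset))
    return out
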