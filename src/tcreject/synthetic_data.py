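"""Synthetic walking-EEG recordings with known artifact ground truth.

Real walking EEG with a trustworthy artifact ground truth does not
exist: artifact and neural activity are both locked to the stride and
cannot be separated after the fact.  This module therefore builds the
validation data the method needs, by construction:

* a 1/f (power-law) Gaussian background on every channel, mimicking the
  broadband EEG spectrum;
* a small set of oscillatory neural sources (10 Hz alpha and 25 Hz beta
  by default) projected through smooth spatial maps over a concentric
  ring sensor layout on the unit disc;
* a stereotyped heel-strike-locked artifact waveform — two Gaussian
  transients at ~50 ms (impact) and ~300 ms (mid-stance) after each
  contact — added only on a chosen subset of channels, with per-cycle
  timing jitter;
* stride-to-stride duration variability (Gaussian, mean 1.2 s by
  default) and a double-bump vertical ground-reaction force whose first
  15 N crossing marks each contact exactly.

Everything is driven by one integer seed and is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np

from .io_events import EventSeries, ForceSeries, Recording

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "sensor_layout",
    "generate_walking_eeg",
    "generate_grf",
    "generate_ic_mixture",
    "write_ground_truth",
]

#: latencies (s), widths (s) and relative amplitudes of the two
#: artifact transients within each gait cycle
_ARTIFACT_BUMPS = ((0.050, 0.020, 1.0), (0.300, 0.050, 0.6))


@dataclass
class SynthConfig:
    """Parameters of the simulated walking recording.

    ``artifact_channels=None`` selects 10 evenly spaced channels.  Each
    neural source is ``(freq_hz, amp_uv, (cx, cy, width))`` with a 2-D
    Gaussian spatial map centred at ``(cx, cy)`` on the unit disc.
    """

    n_channels: int = 256
    fs: float = 512.0
    n_cycles: int = 500
    cycle_mean_s: float = 1.2
    cycle_sd_s: float = 0.1
    artifact_channels: Optional[Sequence[int]] = None
    artifact_amp_uv: float = 120.0
    artifact_jitter_ms: float = 10.0
    neural_sources: Sequence[Tuple[float, float, Tuple[float, float, float]]] = (
        (10.0, 4.0, (0.0, 0.35, 0.45)),
        (25.0, 2.0, (0.15, -0.25, 0.40)),
    )
    noise_exponent: float = 1.0
    background_std_uv: float = 10.0
    line_freq: float = 0.0
    line_amp_uv: float = 0.0
    stance_fraction: float = 0.6
    pad_s: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        if self.n_cycles < 10:
            raise ValueError("need at least 10 gait cycles")
        if self.cycle_mean_s <= 0:
            raise ValueError("cycle_mean_s must be positive")
        freqs = [f for f, _, _ in self.neural_sources]
        if self.line_freq:
            freqs.append(self.line_freq)
        if freqs and self.fs <= 2.0 * max(freqs):
            raise ValueError(
                f"fs={self.fs} Hz too low for a {max(freqs)} Hz source"
            )
        if self.artifact_channels is not None:
            idx = np.asarray(list(self.artifact_channels), dtype=int)
            if idx.size and (idx.min() < 0 or idx.max() >= self.n_channels):
                raise ValueError("artifact channel index out of range")

    def resolved_artifact_channels(self) -> np.ndarray:
        if self.artifact_channels is not None:
            return np.asarray(sorted(set(self.artifact_channels)), dtype=int)
        k = min(10, self.n_channels)
        return np.unique(
            np.linspace(0, self.n_channels - 1, k).round().astype(int)
        )


@dataclass
class GroundTruth:
    """What the generator put into the recording."""

    artifact_channel_indices: np.ndarray
    event_times_samples: np.ndarray
    artifact_waveform: np.ndarray  # common additive trace, (n_samples,)
    artifact_gains: np.ndarray  # per-artifact-channel multiplier
    cycle_durations_s: np.ndarray
    artifact_ic_indices: Optional[np.ndarray] = None
    neural_ic_indices: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.event_times_samples)
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("ground-truth event times must be strictly increasing")

    def to_dict(self) -> dict:
        return {
            "artifact_channel_indices": np.asarray(
                self.artifact_channel_indices
            ).tolist(),
            "event_times_samples": np.asarray(self.event_times_samples).tolist(),
            "artifact_gains": np.asarray(self.artifact_gains).tolist(),
            "cycle_durations_s": np.asarray(self.cycle_durations_s).tolist(),
            "artifact_ic_indices": None
            if self.artifact_ic_indices is None
            else np.asarray(self.artifact_ic_indices).tolist(),
            "neural_ic_indices": None
            if self.neural_ic_indices is None
            else np.asarray(self.neural_ic_indices).tolist(),
        }


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(truth.to_dict()))
    return path


def sensor_layout(n_channels: int) -> np.ndarray:
    """Concentric-ring layout of ``n_channels`` sensors on the unit disc.

    One sensor sits at the vertex; the remainder are spread over rings
    whose sensor counts grow with radius, approximating the even
    coverage of a high-density electrode net.
    """
    if n_channels == 1:
        return np.zeros((1, 2))
    n_rings = max(1, int(round(np.sqrt(n_channels))))
    radii = np.linspace(0, 1, n_rings + 1)[1:]
    weights = radii / radii.sum()
    counts = np.maximum(1, np.round(weights * (n_channels - 1)).astype(int))
    while counts.sum() > n_channels - 1:
        counts[np.argmax(counts)] -= 1
    while counts.sum() < n_channels - 1:
        counts[np.argmax(radii - counts / counts.sum())] += 1
    pts = [np.zeros((1, 2))]
    for ring, (r, c) in enumerate(zip(radii, counts)):
        theta = 2 * np.pi * np.arange(c) / c + 0.5 * ring  # stagger rings
        pts.append(np.column_stack([r * np.cos(theta), r * np.sin(theta)]))
    return np.vstack(pts)[:n_channels]


def _one_over_f_noise(
    rng: np.random.Generator, shape: Tuple[int, int], fs: float, exponent: float
) -> np.ndarray:
    """Gaussian noise with power spectral density ∝ f^(−exponent),
    normalized to unit standard deviation per channel."""
    n_ch, n = shape
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, n=n, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _gaussian_map(
    positions: np.ndarray, center: Tuple[float, float], width: float
) -> np.ndarray:
    d2 = ((positions[:, :2] - np.asarray(center)) ** 2).sum(axis=1)
    return np.exp(-d2 / (2.0 * width**2))


def _artifact_trace(
    rng: np.random.Generator,
    event_times: np.ndarray,
    n_samples: int,
    fs: float,
    jitter_ms: float,
) -> np.ndarray:
    """Unit-amplitude train of heel-strike-locked double Gaussians."""
    t = np.arange(n_samples) / fs
    trace = np.zeros(n_samples)
    for onset in event_times[:-1]:
        t0 = onset / fs
        jit = rng.normal(0.0, jitter_ms / 1000.0)
        for lat, width, amp in _ARTIFACT_BUMPS:
            c = t0 + lat + jit
            lo = max(0, int((c - 5 * width) * fs))
            hi = min(n_samples, int((c + 5 * width) * fs) + 1)
            if hi <= lo:
                continue
            trace[lo:hi] += amp * np.exp(-((t[lo:hi] - c) ** 2) / (2 * width**2))
    return trace


def _cycle_events(cfg: SynthConfig, rng: np.random.Generator):
    durations = rng.normal(cfg.cycle_mean_s, cfg.cycle_sd_s, size=cfg.n_cycles)
    durations = np.clip(durations, 0.4 * cfg.cycle_mean_s, 1.6 * cfg.cycle_mean_s)
    start = cfg.pad_s
    onsets_s = start + np.concatenate([[0.0], np.cumsum(durations)])
    event_times = np.round(onsets_s * cfg.fs).astype(np.int64)
    # rounding can collapse very short cycles; enforce strict monotonicity
    for i in range(1, event_times.size):
        if event_times[i] <= event_times[i - 1]:
            event_times[i] = event_times[i - 1] + 1
    n_samples = int(event_times[-1] + round(cfg.pad_s * cfg.fs))
    return event_times, durations, n_samples


def generate_walking_eeg(
    config: SynthConfig,
) -> Tuple[Recording, ForceSeries, EventSeries, GroundTruth]:
    """Simulate a multichannel walking-EEG recording.

    Returns the recording (μV), the vertical ground-reaction force whose
    first 15 N upward crossing of each cycle falls on the true contact
    sample, the true contact events (labelled ``RHS``), and the ground
    truth of what was injected where.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    event_times, durations, n_samples = _cycle_events(cfg, rng)
    positions = sensor_layout(cfg.n_channels)

    data = cfg.background_std_uv * _one_over_f_noise(
        rng, (cfg.n_channels, n_samples), cfg.fs, cfg.noise_exponent
    )

    t = np.arange(n_samples) / cfg.fs
    for freq, amp, (cx, cy, width) in cfg.neural_sources:
        phase = rng.uniform(0, 2 * np.pi)
        spatial = _gaussian_map(positions, (cx, cy), width)
        data += np.outer(spatial, amp * np.sin(2 * np.pi * freq * t + phase))

    if cfg.line_freq and cfg.line_amp_uv:
        phase = rng.uniform(0, 2 * np.pi)
        data += cfg.line_amp_uv * np.sin(2 * np.pi * cfg.line_freq * t + phase)

    art_idx = cfg.resolved_artifact_channels()
    waveform = _artifact_trace(
        rng, event_times, n_samples, cfg.fs, cfg.artifact_jitter_ms
    )
    gains = rng.uniform(0.7, 1.3, size=art_idx.size)
    if cfg.artifact_amp_uv:
        data[art_idx] += cfg.artifact_amp_uv * gains[:, None] * waveform[None, :]

    recording = Recording(
        data=data,
        fs=cfg.fs,
        labels=[f"E{i + 1:03d}" for i in range(cfg.n_channels)],
        positions=positions,
        condition="walk",
    )
    force = generate_grf(
        event_times, cfg.fs, cfg.stance_fraction, n_samples=n_samples
    )
    events = EventSeries(event_times, ["RHS"] * event_times.size)
    truth = GroundTruth(
        artifact_channel_indices=art_idx,
        event_times_samples=event_times,
        artifact_waveform=cfg.artifact_amp_uv * waveform,
        artifact_gains=gains,
        cycle_durations_s=durations,
    )
    return recording, force, events, truth


def generate_grf(
    event_times: np.ndarray,
    fs: float,
    stance_fraction: float = 0.6,
    peak_newtons: float = 800.0,
    n_samples: Optional[int] = None,
) -> ForceSeries:
    """Vertical ground-reaction force with a double-bump stance profile.

    Each event starts a stance phase of ``stance_fraction`` of the cycle
    (the last cycle reuses the median duration).  The force jumps to a
    loading plateau at the contact sample — so the first upward 15 N
    crossing coincides with the true contact — peaks twice (weight
    acceptance and push-off) and returns to zero at toe-off.
    With ``stance_fraction=0`` the output is identically zero.
    """
    times = np.asarray(event_times, dtype=np.int64).ravel()
    if times.size == 0:
        raise ValueError("need at least one event")
    if np.any(np.diff(times) <= 0):
        raise ValueError("event times must be strictly increasing")
    if not 0.0 <= stance_fraction < 1.0:
        raise ValueError("stance_fraction must lie in [0, 1)")
    diffs = np.diff(times)
    fallback = float(np.median(diffs)) if diffs.size else fs  # lone event: 1 s
    cycle_lens = np.concatenate([diffs, [fallback]])
    if n_samples is None:
        n_samples = int(times[-1] + cycle_lens[-1])
    force = np.zeros(n_samples)
    for onset, cyc in zip(times, cycle_lens):
        stance = int(round(stance_fraction * cyc))
        if stance == 0:
            continue
        if onset + stance > onset + cyc:
            raise ValueError("overlapping stance phases")
        end = min(onset + stance, n_samples)
        u = (np.arange(onset, end) - onset) / stance
        bump = np.exp(-(((u - 0.25) / 0.14) ** 2)) + 0.9 * np.exp(
            -(((u - 0.75) / 0.14) ** 2)
        )
        force[onset:end] = peak_newtons * (0.25 + 0.6 * bump)
    return ForceSeries(force, fs)


def generate_ic_mixture(
    config: SynthConfig,
) -> Tuple[Recording, EventSeries, "ICSet", GroundTruth]:
    """Simulate a recording with an exactly known linear decomposition.

    The source (component) activations are built directly: component 0
    is the gait-locked artifact train, the next components are the
    configured neural oscillations, and the rest are 1/f noise sources.
    The mixing matrix uses the artifact-channel indicator for the
    artifact column, smooth Gaussian scalp maps for the neural columns
    and random maps for the noise columns, so that ground truth about
    which component is what is available by construction.
    """
    from .ic_screening import ICSet  # deferred: avoids a module cycle

    cfg = config
    rng = np.random.default_rng(cfg.seed)
    event_times, durations, n_samples = _cycle_events(cfg, rng)
    positions = sensor_layout(cfg.n_channels)
    k = cfg.n_channels

    activations = cfg.background_std_uv * _one_over_f_noise(
        rng, (k, n_samples), cfg.fs, cfg.noise_exponent
    )
    mixing = rng.normal(0.0, 1.0 / np.sqrt(k), size=(cfg.n_channels, k))

    waveform = _artifact_trace(
        rng, event_times, n_samples, cfg.fs, cfg.artifact_jitter_ms
    )
    sd = waveform.std() or 1.0
    activations[0] = waveform / sd
    art_idx = cfg.resolved_artifact_channels()
    art_map = np.zeros(cfg.n_channels)
    art_map[art_idx] = cfg.artifact_amp_uv * sd * rng.uniform(0.7, 1.3, art_idx.size)
    mixing[:, 0] = art_map

    t = np.arange(n_samples) / cfg.fs
    neural_idx = []
    for j, (freq, amp, (cx, cy, width)) in enumerate(cfg.neural_sources, start=1):
        phase = rng.uniform(0, 2 * np.pi)
        activations[j] = np.sin(2 * np.pi * freq * t + phase) + 0.1 * activations[j]
        mixing[:, j] = amp * _gaussian_map(positions, (cx, cy), width)
        neural_idx.append(j)

    data = mixing @ activations
    recording = Recording(
        data=data,
        fs=cfg.fs,
        labels=[f"E{i + 1:03d}" for i in range(cfg.n_channels)],
        positions=positions,
        condition="walk",
    )
    events = EventSeries(event_times, ["RHS"] * event_times.size)
    ic_set = ICSet(
        activations=activations,
        mixing=mixing,
        unmixing=np.linalg.inv(mixing),
        fs=cfg.fs,
    )
    truth = GroundTruth(
        artifact_channel_indices=art_idx,
        event_times_samples=event_times,
        artifact_waveform=cfg.artifact_amp_uv * waveform,
        artifact_gains=art_map[art_idx],
        cycle_durations_s=durations,
        artifact_ic_indices=np.array([0]),
        neural_ic_indices=np.asarray(neural_idx, dtype=int),
    )
    return recording, events, ic_set, truth
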