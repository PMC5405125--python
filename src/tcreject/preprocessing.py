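"""Filtering and conventional bad-channel rejection preceding TCR.

The template-correlation step assumes the recording has already been
high-pass filtered (1 Hz, zero-phase FIR), cleaned of line noise, and
stripped of channels that fail conventional criteria: peak-to-peak
range outside 30–3,000 μV, extreme kurtosis, poor correlation with
neighbouring sensors, or a standard deviation far above the rest of the
montage ("method 1" here).
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
from scipy import signal as sps
from scipy import stats
from scipy.spatial import cKDTree

from .io_events import Recording
from .tcr_core import ChannelDecision, find_breaking_point

__all__ = [
    "highpass",
    "notch_line_noise",
    "reject_channels_method1",
    "design_highpass",
]


def design_highpass(
    fs: float, cutoff: float = 1.0, transition_bw: float = 0.2
) -> np.ndarray:
    """Linear-phase FIR high-pass taps (Hamming window design).

    The tap count follows the Hamming transition-width rule
    ``3.3 * fs / transition_bw`` (odd), giving ~0.2 Hz transition
    bandwidth around the cutoff by default.
    """
    numtaps = int(np.ceil(3.3 * fs / transition_bw))
    numtaps += 1 - numtaps % 2  # force odd for a type-I (zero-phase) filter
    return sps.firwin(numtaps, cutoff, window="hamming", pass_zero=False, fs=fs)


def highpass(
    recording: Recording, cutoff: float = 1.0, transition_bw: float = 0.2
) -> Recording:
    """Zero-phase FIR high-pass filter; removes DC and sub-cutoff drift.

    The symmetric FIR kernel is applied with centred ('same') alignment,
    so the overall response has exactly zero phase.  Raises if the
    recording is shorter than the filter.
    """
    taps = design_highpass(recording.fs, cutoff, transition_bw)
    if recording.n_samples < taps.size:
        raise ValueError(
            f"recording of {recording.n_samples} samples is shorter than the "
            f"{taps.size}-tap high-pass filter"
        )
    filtered = sps.oaconvolve(recording.data, taps[None, :], mode="same", axes=1)
    return recording.copy_with(filtered)


def notch_line_noise(
    recording: Recording, line_freq: float, quality: float = 30.0
) -> Recording:
    """Zero-phase IIR notch at the line frequency and its harmonics.

    One second-order notch per harmonic below Nyquist, applied with
    ``filtfilt`` (zero phase, squared magnitude response, so the
    attenuation at each null is effectively unbounded while the
    response 5 Hz away stays within 1 dB).
    """
    nyq = recording.fs / 2.0
    if line_freq >= nyq:
        raise ValueError(f"line frequency {line_freq} Hz is at or above Nyquist")
    if line_freq <= 0:
        raise ValueError("line frequency must be positive")
    data = recording.data
    harmonic = line_freq
    while harmonic < nyq:
        b, a = sps.iirnotch(harmonic, quality, fs=recording.fs)
        data = sps.filtfilt(b, a, data, axis=1)
        harmonic += line_freq
    return recording.copy_with(data)


def reject_channels_method1(
    recording: Recording,
    positions: Optional[np.ndarray] = None,
    low_uv: float = 30.0,
    high_uv: float = 3000.0,
    kurtosis_z: float = 5.0,
    neighbor_r: float = 0.4,
    neighbor_frac: float = 0.01,
    n_neighbors: int = 8,
    window_s: float = 1.0,
    robust: bool = False,
    std_outlier_z: float = 5.0,
) -> ChannelDecision:
    """Conventional per-channel rejection ("method 1").

    Criteria, each contributing a reason code:

    * ``LOW_RANGE`` / ``HIGH_RANGE`` — whole-recording peak-to-peak
      magnitude below ``low_uv`` or above ``high_uv``;
    * ``KURTOSIS`` — per-channel kurtosis more than ``kurtosis_z``
      standard deviations above the across-channel mean (median/MAD
      when ``robust``);
    * ``NEIGHBOR_CORR`` — in more than ``neighbor_frac`` of 1 s
      non-overlapping windows, the best correlation with the
      ``n_neighbors`` nearest sensors stays below ``neighbor_r``
      (skipped with a warning when no positions are available);
    * ``STD_OUTLIER`` — standard deviation above the knee of the sorted
      across-channel standard-deviation curve *and* a robust
      (median/MAD) z-score above ``std_outlier_z``; the second clause
      makes the automated stand-in for visual inspection conservative
      on homogeneous montages.
    """
    data = recording.data
    n_ch = recording.n_channels
    if n_ch < 8:
        raise ValueError("method-1 statistics require at least 8 channels")
    if positions is None:
        positions = recording.positions

    reasons = [set() for _ in range(n_ch)]
    evidence: dict = {}

    ptp = data.max(axis=1) - data.min(axis=1)
    evidence["ptp_uv"] = ptp
    for i in np.flatnonzero(ptp < low_uv):
        reasons[i].add("LOW_RANGE")
    for i in np.flatnonzero(ptp > high_uv):
        reasons[i].add("HIGH_RANGE")

    kurt = stats.kurtosis(data, axis=1, fisher=True, bias=True)
    if robust:
        center = np.median(kurt)
        scale = 1.4826 * np.median(np.abs(kurt - center))
    else:
        center, scale = kurt.mean(), kurt.std()
    kz = (kurt - center) / scale if scale > 0 else np.zeros(n_ch)
    evidence["kurtosis"] = kurt
    evidence["kurtosis_z"] = kz
    for i in np.flatnonzero(kz > kurtosis_z):
        reasons[i].add("KURTOSIS")

    if positions is None:
        warnings.warn(
            "no sensor positions: neighbour-correlation criterion disabled",
            stacklevel=2,
        )
        evidence["neighbor_low_frac"] = np.full(n_ch, np.nan)
    else:
        low_frac = _neighbor_low_correlation_fraction(
            data, recording.fs, positions, n_neighbors, neighbor_r, window_s
        )
        evidence["neighbor_low_frac"] = low_frac
        # relative gate: a channel must stand out from the montage, not
        # merely share a montage-wide correlation level (otherwise any
        # weakly volume-conducted montage is flagged wholesale)
        outlier = _robust_outlier(low_frac, std_outlier_z)
        for i in np.flatnonzero((low_frac > neighbor_frac) & outlier):
            reasons[i].add("NEIGHBOR_CORR")

    sd = data.std(axis=1)
    order = np.argsort(sd, kind="stable")
    knee = find_breaking_point(sd[order])
    evidence["std_uv"] = sd
    evidence["std_knee_uv"] = knee.value if knee.found else None
    if knee.found:
        outlier = _robust_outlier(sd, std_outlier_z)
        for i in np.flatnonzero((sd > knee.value) & outlier):
            reasons[i].add("STD_OUTLIER")

    flags = np.array([bool(r) for r in reasons])
    return ChannelDecision(list(recording.labels), flags, reasons, evidence)


def _robust_outlier(values: np.ndarray, z: float) -> np.ndarray:
    """True where a value lies more than ``z`` robust (median/MAD)
    standard deviations above the across-channel median.  With zero MAD
    any value strictly above the median counts."""
    med = np.median(values)
    mad = 1.4826 * np.median(np.abs(values - med))
    if mad > 0:
        return (values - med) / mad > z
    return values > med


def _neighbor_low_correlation_fraction(
    data: np.ndarray,
    fs: float,
    positions: np.ndarray,
    n_neighbors: int,
    r_threshold: float,
    window_s: float,
) -> np.ndarray:
    """Fraction of 1 s windows in which each channel's best correlation
    with its nearest neighbours falls below ``r_threshold``."""
    n_ch, n = data.shape
    k = min(n_neighbors, n_ch - 1)
    tree = cKDTree(positions[:, :2])
    _, nbrs = tree.query(positions[:, :2], k=k + 1)
    nbrs = nbrs[:, 1:]  # drop self
    win = max(2, int(round(window_s * fs)))
    n_win = n // win
    if n_win == 0:
        raise ValueError("recording shorter than one correlation window")
    low = np.zeros(n_ch, dtype=int)
    for w in range(n_win):
        seg = data[:, w * win : (w + 1) * win]
        seg = seg - seg.mean(axis=1, keepdims=True)
        norm = np.sqrt((seg**2).sum(axis=1))
        norm[norm == 0] = 1.0
        seg = seg / norm[:, None]
        corr = seg @ seg.T
        best = np.take_along_axis(corr, nbrs, axis=1).max(axis=1)
        low += best < r_threshold
    return low / n_win
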