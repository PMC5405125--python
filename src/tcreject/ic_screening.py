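"""Template-correlation screening of independent components.

The channel-level template correlation transfers directly to the rows
of a linear decomposition's activation matrix: a component whose
activation repeats the same pattern in most gait cycles is gait-locked.
Because component units are arbitrary, the amplitude (breaking-point)
gate is dropped; instead a gait-locked component is kept when it shows
positive evidence of neural content — a spectral peak in the alpha,
beta or gamma band above the aperiodic (1/f) background, or a smooth,
dipole-like scalp map.  Everything else that is gait-locked is removed
by subtracting its back-projection from the channel data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .io_events import EventSeries, Recording
from .tcr_core import (
    TcrParams,
    compute_template,
    epoch_and_warp,
    epoch_template_correlations,
    events_to_smoothed_positions,
    fraction_correlated,
    smooth_moving_average,
)

__all__ = [
    "ICSet",
    "ICDecision",
    "SpectralPeakEvidence",
    "NEURAL_BANDS",
    "tcr_score_components",
    "detect_spectral_peak",
    "scalp_map_smoothness",
    "select_components",
    "remove_components_and_backproject",
]

#: frequency bands whose peaks count as evidence of neural content
NEURAL_BANDS: Dict[str, Tuple[float, float]] = {
    "alpha": (9.0, 13.0),
    "beta": (14.0, 30.0),
    "gamma": (31.0, 80.0),
}

#: default smoothness cutoff separating smooth (dipole-like) scalp maps
#: from scattered ones — the 10th percentile of the smoothness of
#: synthetic Gaussian neural maps over ring layouts (≈0.54; scattered,
#: shuffled or single-sensor maps score ≈0, see docs/methods.md)
DEFAULT_SMOOTHNESS_CUTOFF = 0.55


@dataclass
class ICSet:
    """A linear decomposition of a recording.

    ``activations`` is ``(n_components, n_samples)`` (arbitrary units),
    ``mixing`` is ``(n_channels, n_components)`` with scalp maps as
    columns, and ``unmixing`` its (pseudo-)inverse; when omitted the
    pseudo-inverse of the mixing matrix is used.
    """

    activations: np.ndarray
    mixing: np.ndarray
    unmixing: Optional[np.ndarray] = None
    fs: float = 0.0

    def __post_init__(self) -> None:
        self.activations = np.atleast_2d(np.asarray(self.activations, dtype=float))
        self.mixing = np.atleast_2d(np.asarray(self.mixing, dtype=float))
        if self.mixing.shape[1] != self.activations.shape[0]:
            raise ValueError(
                "mixing matrix columns must match the number of components"
            )
        if self.mixing.shape[1] > self.mixing.shape[0]:
            raise ValueError("component count cannot exceed channel count")
        if self.unmixing is None:
            self.unmixing = np.linalg.pinv(self.mixing)
        else:
            self.unmixing = np.atleast_2d(np.asarray(self.unmixing, dtype=float))
            ident = self.unmixing @ self.mixing
            if not np.allclose(ident, np.eye(self.n_components), atol=1e-6):
                raise ValueError(
                    "unmixing @ mixing is not the identity on the component space"
                )

    @property
    def n_components(self) -> int:
        return self.activations.shape[0]

    @property
    def n_channels(self) -> int:
        return self.mixing.shape[0]

    def scalp_map(self, component: int) -> np.ndarray:
        return self.mixing[:, component]

    def psd(self, nperseg_s: float = 0.512, nfft_s: float = 1.024):
        """Per-component Welch power spectral density (same windowing
        convention as the channel band power)."""
        if self.fs <= 0:
            raise ValueError("ICSet.fs must be set to compute spectra")
        nperseg = int(round(nperseg_s * self.fs))
        nfft = int(round(nfft_s * self.fs))
        freqs, pxx = sps.welch(
            self.activations,
            fs=self.fs,
            window="hamming",
            nperseg=nperseg,
            noverlap=nperseg // 2,
            nfft=nfft,
            axis=1,
        )
        return freqs, pxx


def tcr_score_components(
    ic_set: ICSet,
    events: EventSeries,
    params: Optional[TcrParams] = None,
    event_label: Optional[str] = None,
) -> np.ndarray:
    """Fraction of gait epochs correlated with each component's template.

    Identical to the channel computation (smooth, epoch, warp, template,
    Pearson r, fraction above threshold) applied to activation rows; no
    amplitude step, since component units are not comparable.
    """
    params = params or TcrParams()
    if event_label is not None:
        events = events.with_label(event_label)
    if len(events) < 2:
        raise ValueError("need at least 2 epoching events")
    if events.times[-1] > ic_set.activations.shape[1]:
        raise ValueError("activations do not cover all event epochs")
    smoothed = smooth_moving_average(
        ic_set.activations, ic_set.fs, params.smooth_window_ms, params.smooth_step_ms
    )
    pos = events_to_smoothed_positions(events.times, smoothed)
    es = epoch_and_warp(smoothed.values, pos, params.warp_points)
    template = compute_template(es)
    corr = epoch_template_correlations(es, template)
    return fraction_correlated(corr, params.corr_threshold)


@dataclass
class SpectralPeakEvidence:
    """Outcome of the neural-peak screen for one component."""

    neural: bool
    band: Optional[str]
    peak_freq_hz: Optional[float]
    peak_db: Optional[float]
    all_peaks: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "neural": self.neural,
            "band": self.band,
            "peak_freq_hz": self.peak_freq_hz,
            "peak_db": self.peak_db,
            "all_peaks": self.all_peaks,
        }


def detect_spectral_peak(
    freqs: np.ndarray,
    psd: np.ndarray,
    bands: Dict[str, Tuple[float, float]] = NEURAL_BANDS,
    min_peak_db: float = 3.0,
    fit_range_hz: Tuple[float, float] = (1.5, 80.0),
    ripple_factor: float = 3.0,
) -> SpectralPeakEvidence:
    """Find spectral peaks rising above the aperiodic 1/f background.

    A straight line is fitted to log-power vs log-frequency over
    ``fit_range_hz`` (two passes, down-weighting peak bins in the
    second) and peaks of the residual at least ``min_peak_db`` above the
    fit are located.  Only peaks whose centre falls in the alpha, beta
    or gamma band count as neural evidence; delta/theta peaks are
    recorded but do not qualify.

    A qualifying peak must also rise ``ripple_factor`` robust standard
    deviations above the residual's overall ripple level: stride-locked
    artifact spectra are jagged (a harmonic comb with interference
    ripples of several dB throughout the band), and no single ripple of
    such a spectrum is evidence of an oscillatory neural source.
    """
    freqs = np.asarray(freqs, dtype=float).ravel()
    psd = np.asarray(psd, dtype=float).ravel()
    if freqs.size != psd.size:
        raise ValueError("freqs and psd must have the same length")
    df = np.median(np.diff(freqs))
    if df > 1.0:
        raise ValueError(f"PSD resolution {df:.2f} Hz is coarser than 1 Hz")
    mask = (freqs >= fit_range_hz[0]) & (freqs <= fit_range_hz[1]) & (psd > 0)
    if mask.sum() < 10:
        raise ValueError("too few PSD bins inside the background fit range")
    lf = np.log10(freqs[mask])
    lp = np.log10(psd[mask])
    coef = np.polyfit(lf, lp, 1)
    resid = lp - np.polyval(coef, lf)
    keep = resid < resid.std()  # second pass without the strongest peaks
    if keep.sum() >= 10:
        coef = np.polyfit(lf[keep], lp[keep], 1)
        resid = lp - np.polyval(coef, lf)
    resid_db = 10.0 * resid
    ripple = 1.4826 * np.median(np.abs(resid_db - np.median(resid_db)))
    qualify_db = max(min_peak_db, ripple_factor * ripple)
    idx, props = sps.find_peaks(resid_db, height=min_peak_db)
    all_peaks = []
    best: Optional[Tuple[str, float, float]] = None
    for i, height in zip(idx, props["peak_heights"]):
        f0 = float(freqs[mask][i])
        band = next(
            (name for name, (lo, hi) in bands.items() if lo <= f0 <= hi), None
        )
        all_peaks.append({"freq_hz": f0, "db_above_background": float(height), "band": band})
        if band is not None and height >= qualify_db and (best is None or height > best[2]):
            best = (band, f0, float(height))
    if best is None:
        return SpectralPeakEvidence(False, None, None, None, all_peaks)
    return SpectralPeakEvidence(True, best[0], best[1], best[2], all_peaks)


def scalp_map_smoothness(
    scalp_map: np.ndarray, positions: np.ndarray, n_neighbors: int = 6
) -> float:
    """Spatial smoothness of a scalp map, in [0, 1].

    The mean absolute difference between neighbouring sensors is
    normalized by the mean absolute difference over all sensor pairs (a
    spatial-contiguity ratio): a map varying slowly over the layout
    scores near 1, while a map whose neighbours differ as much as random
    sensor pairs — a scattered or single-sensor map — scores near 0.
    """
    from scipy.spatial import cKDTree

    m = np.asarray(scalp_map, dtype=float).ravel()
    positions = np.asarray(positions, dtype=float)
    if positions.shape[0] != m.size:
        raise ValueError("one position per map value is required")
    n = m.size
    k = min(n_neighbors, n - 1)
    if k < 1:
        return 1.0
    tree = cKDTree(positions[:, :2])
    _, nbrs = tree.query(positions[:, :2], k=k + 1)
    nbrs = nbrs[:, 1:]
    neighbor_diff = np.abs(m[:, None] - m[nbrs]).mean()
    allpair_diff = np.abs(m[:, None] - m[None, :]).sum() / (n * (n - 1))
    if allpair_diff == 0:
        return 1.0
    return float(np.clip(1.0 - neighbor_diff / allpair_diff, 0.0, 1.0))


@dataclass
class ICDecision:
    """Per-component rejection flags with evidence for audit."""

    flags: np.ndarray
    fractions: np.ndarray
    spectral: Sequence[SpectralPeakEvidence]
    smoothness: np.ndarray
    fraction_threshold: float
    smoothness_cutoff: float
    override: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.override:
            self.override = [None] * self.flags.size
        for i, ov in enumerate(self.override):
            if ov is not None:
                self.flags[i] = bool(ov)

    @property
    def flagged_indices(self) -> np.ndarray:
        return np.flatnonzero(self.flags)

    def to_dict(self) -> dict:
        return {
            "n_components": int(self.flags.size),
            "n_flagged": int(self.flags.sum()),
            "fraction_threshold": self.fraction_threshold,
            "smoothness_cutoff": self.smoothness_cutoff,
            "components": [
                {
                    "index": int(i),
                    "flagged": bool(self.flags[i]),
                    "fraction": float(self.fractions[i]),
                    "spectral": self.spectral[i].to_dict(),
                    "smoothness": float(self.smoothness[i]),
                    "override": self.override[i],
                }
                for i in range(self.flags.size)
            ],
        }


def select_components(
    fractions: np.ndarray,
    spectral_evidence: Sequence[SpectralPeakEvidence],
    smoothness: np.ndarray,
    params: Optional[TcrParams] = None,
    smoothness_cutoff: float = DEFAULT_SMOOTHNESS_CUTOFF,
    override: Optional[list] = None,
) -> ICDecision:
    """Flag gait-locked components lacking neural evidence.

    A component is flagged when its epoch fraction exceeds the fraction
    threshold and neither neural criterion holds (no qualifying
    alpha/beta/gamma peak and a scalp map below the smoothness cutoff).
    Components with a qualifying spectral peak are always retained,
    whatever their fraction.  ``override`` entries (True/False) force
    the decision per component, for manual review.
    """
    params = params or TcrParams()
    fractions = np.asarray(fractions, dtype=float)
    smoothness = np.asarray(smoothness, dtype=float)
    if not (fractions.size == len(spectral_evidence) == smoothness.size):
        raise ValueError("inputs must be aligned by component")
    neural = np.array(
        [ev.neural or s >= smoothness_cutoff for ev, s in zip(spectral_evidence, smoothness)]
    )
    flags = (fractions > params.fraction_threshold) & ~neural
    return ICDecision(
        flags=flags,
        fractions=fractions,
        spectral=list(spectral_evidence),
        smoothness=smoothness,
        fraction_threshold=params.fraction_threshold,
        smoothness_cutoff=smoothness_cutoff,
        override=list(override) if override else [],
    )


def remove_components_and_backproject(
    recording: Recording, ic_set: ICSet, decision: ICDecision
) -> Recording:
    """Subtract the flagged components' channel-space contribution.

    The unflagged component subspace is untouched: with no flags the
    output equals the input to floating-point precision.
    """
    if ic_set.n_channels != recording.n_channels:
        raise ValueError("decomposition does not match the recording's channels")
    if decision.flags.size != ic_set.n_components:
        raise ValueError("decision does not match the number of components")
    flagged = decision.flagged_indices
    if flagged.size == 0:
        return recording.copy_with(recording.data.copy())
    contribution = ic_set.mixing[:, flagged] @ ic_set.activations[flagged]
    return recording.copy_with(recording.data - contribution)
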