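"""Template correlation rejection (TCR) of gait-locked EEG channels.

The method rests on one assumption: during steady cyclic movement the
mechanical disturbance of the electrodes repeats in every movement
cycle, so a channel dominated by motion artifact shows nearly the same
amplitude pattern in every gait-cycle epoch.  Neural activity, by
contrast, is not phase-locked to the stride with high amplitude.

The pipeline, per channel:

1. smooth the continuous signal with a 100 ms moving average advanced
   in 50 ms steps (one output value per step);
2. cut the smoothed trace into gait cycles (heel strike to next heel
   strike of the same foot) and linearly time-warp each cycle to 1,000
   points;
3. average the warped epochs into a template and correlate every epoch
   with it (Pearson r);
4. compare against a chance level obtained from surrogate, randomly
   timed events: a channel is a rejection candidate when more than 75%
   of its epochs correlate with the template at r > 0.4;
5. gate candidates by amplitude: compute each channel's amplitude range
   (mean of per-10%-window max−min, averaged over epochs), sort the
   ranges over channels, locate the knee ("breaking point") of the
   sorted curve, and require the candidate to lie above it.

A channel meeting both criteria in either walking condition is removed
from both conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .io_events import EventSeries, Recording

__all__ = [
    "TcrParams",
    "SmoothedSeries",
    "EpochSet",
    "SurrogateEnsemble",
    "BreakingPoint",
    "ThresholdEstimate",
    "ConditionResult",
    "ChannelDecision",
    "smooth_moving_average",
    "events_to_smoothed_positions",
    "epoch_and_warp",
    "compute_template",
    "epoch_template_correlations",
    "fraction_correlated",
    "generate_surrogate_events",
    "estimate_correlation_threshold",
    "amplitude_range",
    "find_breaking_point",
    "analyze_condition",
    "surrogate_condition_fractions",
    "select_channels_tcr",
]


@dataclass
class TcrParams:
    """Tunable parameters of the rejection rule.

    corr_threshold
        Minimum per-epoch Pearson correlation with the template for an
        epoch to count as "correlated" (default 0.4, a rounded-up
        chance level; see :func:`estimate_correlation_threshold`).
    fraction_threshold
        Minimum fraction of correlated epochs for a channel to become a
        rejection candidate (default 0.75, i.e. 3 of every 4 cycles).
    smooth_window_ms, smooth_step_ms
        Moving-average window and step (100/50 ms).
    warp_points
        Common epoch length after time-warping (1,000).
    range_window_fraction
        Sub-window width for the amplitude range as a fraction of the
        warped epoch (0.1 → ten windows per epoch).
    n_surrogate_sets, surrogate_sectors, surrogate_fraction
        Surrogate-event ensemble: number of random event sets (10),
        recording sectors for stratification (5) and number of events
        per set as a fraction of the cycle count (0.5).
    """

    corr_threshold: float = 0.4
    fraction_threshold: float = 0.75
    smooth_window_ms: float = 100.0
    smooth_step_ms: float = 50.0
    warp_points: int = 1000
    range_window_fraction: float = 0.1
    n_surrogate_sets: int = 10
    surrogate_sectors: int = 5
    surrogate_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.corr_threshold < 1.0:
            raise ValueError("corr_threshold must lie in (0, 1)")
        if not 0.0 < self.fraction_threshold < 1.0:
            raise ValueError("fraction_threshold must lie in (0, 1)")
        if self.warp_points < 100:
            raise ValueError("warp_points must be at least 100")
        if self.smooth_step_ms > self.smooth_window_ms:
            raise ValueError("smoothing step must not exceed the window")
        n_win = round(1.0 / self.range_window_fraction)
        if self.warp_points % n_win:
            raise ValueError(
                "warp_points must be divisible by the number of range windows"
            )


@dataclass
class SmoothedSeries:
    """Decimated moving-average series.

    ``values[..., k]`` is the mean of the raw samples in the window
    starting at ``k * step_samples``; ``positions[k]`` is the window
    centre expressed in raw-sample coordinates.
    """

    values: np.ndarray
    positions: np.ndarray
    fs: float
    window_samples: int
    step_samples: int


def smooth_moving_average(
    signal: np.ndarray,
    fs: float,
    window_ms: float = 100.0,
    step_ms: float = 50.0,
) -> SmoothedSeries:
    """Moving average over ``window_ms`` windows advanced by ``step_ms``.

    Output length is ``floor((n - window) / step) + 1``; value ``k`` is
    the mean of samples ``[k*step, k*step + window)``.
    """
    x = np.asarray(signal, dtype=float)
    window = max(1, int(round(window_ms / 1000.0 * fs)))
    step = max(1, int(round(step_ms / 1000.0 * fs)))
    n = x.shape[-1]
    if n < window:
        raise ValueError(
            f"signal of {n} samples is shorter than one {window}-sample window"
        )
    n_out = (n - window) // step + 1
    csum = np.cumsum(x, axis=-1, dtype=float)
    csum = np.concatenate([np.zeros(x.shape[:-1] + (1,)), csum], axis=-1)
    starts = np.arange(n_out) * step
    values = (csum[..., starts + window] - csum[..., starts]) / window
    positions = starts + (window - 1) / 2.0
    return SmoothedSeries(values, positions, fs, window, step)


def events_to_smoothed_positions(
    event_samples: np.ndarray, smoothed: SmoothedSeries
) -> np.ndarray:
    """Map raw-sample event times onto (fractional) smoothed indices."""
    t = np.asarray(event_samples, dtype=float)
    pos = (t - (smoothed.window_samples - 1) / 2.0) / smoothed.step_samples
    n = smoothed.values.shape[-1]
    return np.clip(pos, 0.0, n - 1.0)


@dataclass
class EpochSet:
    """Per-channel epochs time-warped to a common length.

    ``epochs`` has shape ``(n_channels, n_epochs, warp_points)``.
    ``durations`` holds the original segment lengths (series samples);
    ``skipped`` lists the indices of degenerate cycles that were dropped.
    """

    epochs: np.ndarray
    durations: np.ndarray
    events: Optional[np.ndarray] = None
    skipped: list = field(default_factory=list)

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[1]

    @property
    def warp_points(self) -> int:
        return self.epochs.shape[2]


def epoch_and_warp(
    series: np.ndarray,
    events: np.ndarray,
    warp_points: int = 1000,
    duration: Optional[float] = None,
    min_points: float = 4.0,
) -> EpochSet:
    """Cut a series at event positions and warp each segment to
    ``warp_points`` samples by linear interpolation.

    With ``duration=None`` segments run between consecutive events
    (half-open: ``[e_i, e_{i+1})``); otherwise each event starts a
    segment of ``duration`` series samples, and segments running past
    the end of the series are dropped.  Segments shorter than
    ``min_points`` are skipped with a warning.  A segment whose length
    already equals ``warp_points`` is returned unchanged.
    """
    x = np.atleast_2d(np.asarray(series, dtype=float))
    ev = np.asarray(events, dtype=float).ravel()
    n = x.shape[-1]
    if duration is None:
        if ev.size < 2:
            raise ValueError("need at least 2 events to form epochs")
        starts, ends = ev[:-1], ev[1:]
    else:
        if ev.size < 1:
            raise ValueError("need at least 1 event to form epochs")
        starts = ev
        ends = ev + float(duration)
        keep = ends <= n  # truncated trailing epochs are dropped
        starts, ends = starts[keep], ends[keep]
    lengths = ends - starts
    epochs, durations, skipped = [], [], []
    u = np.linspace(0.0, 1.0, warp_points)
    for i, (s, e, length) in enumerate(zip(starts, ends, lengths)):
        if length < min_points:
            skipped.append(i)
            continue
        # sample positions covering [s, e) inclusively of its last sample
        xs = s + (length - 1.0) * u
        i0 = np.clip(np.floor(xs).astype(np.intp), 0, n - 2)
        w = xs - i0
        epochs.append(x[:, i0] * (1.0 - w) + x[:, i0 + 1] * w)
        durations.append(length)
    if skipped:
        warnings.warn(
            f"skipped {len(skipped)} degenerate cycle(s) shorter than "
            f"{min_points} points",
            stacklevel=2,
        )
    if not epochs:
        raise ValueError("no valid epochs remain after skipping degenerate cycles")
    return EpochSet(
        epochs=np.stack(epochs, axis=1),
        durations=np.asarray(durations, dtype=float),
        events=ev,
        skipped=skipped,
    )


def compute_template(epoch_set: EpochSet) -> np.ndarray:
    """Across-epoch average waveform, per channel (the gait template)."""
    if epoch_set.n_epochs < 1:
        raise ValueError("epoch set is empty")
    return epoch_set.epochs.mean(axis=1)


def epoch_template_correlations(
    epoch_set: EpochSet, template: np.ndarray
) -> np.ndarray:
    """Pearson correlation of every epoch with its channel template.

    Returns an ``(n_epochs, n_channels)`` table.  A zero-variance epoch
    or template yields 0 (counts as below any positive threshold).
    """
    template = np.atleast_2d(np.asarray(template, dtype=float))
    ep = epoch_set.epochs
    if template.shape != (ep.shape[0], ep.shape[2]):
        raise ValueError(
            f"template shape {template.shape} does not match epochs "
            f"({ep.shape[0]} channels x {ep.shape[2]} points)"
        )
    ec = ep - ep.mean(axis=2, keepdims=True)
    tc = template - template.mean(axis=1, keepdims=True)
    num = np.einsum("cep,cp->ce", ec, tc)
    den = np.sqrt(np.einsum("cep,cep->ce", ec, ec) * np.einsum("cp,cp->c", tc, tc)[:, None])
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return np.clip(r.T, -1.0, 1.0)  # (epochs, channels)


def fraction_correlated(corr_table: np.ndarray, threshold: float = 0.4) -> np.ndarray:
    """Per-channel fraction of epochs with r strictly above ``threshold``.

    The comparison is signed: anticorrelated epochs never count.
    """
    corr_table = np.atleast_2d(np.asarray(corr_table, dtype=float))
    if corr_table.size == 0:
        raise ValueError("empty correlation table")
    return (corr_table > threshold).mean(axis=0)


@dataclass
class SurrogateEnsemble:
    """Random (surrogate) event sets used to build the chance-level
    correlation distribution."""

    event_lists: list
    seeds: list
    sectors: int
    fraction: float


def generate_surrogate_events(
    recording_len: int,
    fs: float,
    n_cycles: int,
    n_sets: int = 10,
    sectors: int = 5,
    fraction: float = 0.5,
    seed: int = 0,
    epoch_samples: Optional[float] = None,
) -> SurrogateEnsemble:
    """Randomly timed pseudo-events stratified over recording sectors.

    Each of the ``n_sets`` sets holds ``round(fraction * n_cycles)``
    onsets, split as evenly as possible over ``sectors`` equal-duration
    sectors (per-sector counts differ by at most one) and uniform
    within each sector.  Using only half as many events as real cycles
    keeps randomly placed epochs unlikely to overlap.
    """
    n_events = int(round(fraction * n_cycles))
    if n_events < 1:
        raise ValueError("surrogate fraction yields zero events")
    if epoch_samples is not None and n_events * epoch_samples > recording_len:
        raise ValueError(
            "infeasible surrogate density: expected total epoch length "
            f"({n_events} x {epoch_samples:.0f} samples) exceeds the recording"
        )
    base, extra = divmod(n_events, sectors)
    counts = [base + (1 if s < extra else 0) for s in range(sectors)]
    edges = np.linspace(0, recording_len, sectors + 1)
    event_lists, seeds = [], []
    root = np.random.SeedSequence(seed)
    for k, child in enumerate(root.spawn(n_sets)):
        rng = np.random.default_rng(child)
        times = np.concatenate(
            [
                rng.integers(int(edges[s]), max(int(edges[s]) + 1, int(edges[s + 1])), size=counts[s])
                for s in range(sectors)
            ]
        )
        times = np.sort(times)
        # enforce strict monotonicity for downstream EventSeries use
        for i in range(1, times.size):
            if times[i] <= times[i - 1]:
                times[i] = times[i - 1] + 1
        event_lists.append(times.astype(np.int64))
        seeds.append(k)
    return SurrogateEnsemble(event_lists, seeds, sectors, fraction)


@dataclass
class ThresholdEstimate:
    """Data-driven correlation threshold.

    ``value`` is the intersection point of the experimental and
    surrogate correlation densities, or ``None`` when the two
    distributions are indistinguishable ("no separation"); ``used``
    falls back to the fixed default in that case.
    """

    value: Optional[float]
    default: float = 0.4

    @property
    def separated(self) -> bool:
        return self.value is not None

    @property
    def used(self) -> float:
        return self.default if self.value is None else self.value


def _kde_on_grid(sample: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Gaussian KDE with Silverman bandwidth, reflected at the grid ends."""
    n = sample.size
    std = sample.std()
    q75, q25 = np.percentile(sample, [75, 25])
    spread = min(std, (q75 - q25) / 1.34) if q75 > q25 else std
    if spread <= 0:
        spread = max(std, 1e-3)
    bw = 0.9 * spread * n ** (-0.2)
    dx = grid[1] - grid[0]
    edges = np.concatenate([grid - dx / 2, [grid[-1] + dx / 2]])
    counts, _ = np.histogram(np.clip(sample, grid[0], grid[-1]), bins=edges)
    dens = counts / (n * dx)
    return gaussian_filter1d(dens, sigma=max(bw / dx, 1e-9), mode="reflect")


def estimate_correlation_threshold(
    experimental_corrs: np.ndarray,
    surrogate_corrs: np.ndarray,
    default: float = 0.4,
    grid_size: int = 2001,
    min_separation_mass: float = 0.01,
) -> ThresholdEstimate:
    """Intersection of the experimental and surrogate correlation
    distributions.

    Kernel-density estimates of both samples are evaluated on [−1, 1];
    the threshold is the rightmost point between the surrogate mode and
    the experimental mode where the rising experimental density crosses
    above the falling surrogate density — the level above which
    experimental correlations exceed chance.  When the experimental
    mode does not lie to the right of the surrogate mode, or no
    crossing exists, the estimate is "no separation" and callers fall
    back to the fixed default.
    """
    exp = np.asarray(experimental_corrs, dtype=float).ravel()
    sur = np.asarray(surrogate_corrs, dtype=float).ravel()
    if exp.size < 100 or sur.size < 100:
        raise ValueError("need at least 100 correlation values per sample")
    grid = np.linspace(-1.0, 1.0, grid_size)
    dx = grid[1] - grid[0]
    fe = _kde_on_grid(exp, grid)
    fsur = _kde_on_grid(sur, grid)
    ms = int(np.argmax(fsur))
    d = fe - fsur
    # upward crossings right of the surrogate mode, where the experimental
    # density rises above the falling surrogate density
    ups = [i for i in range(ms + 1, grid_size) if d[i - 1] < 0.0 <= d[i]]
    for i in reversed(ups):
        # require genuine separation: a non-trivial excess of experimental
        # probability mass beyond the crossing (guards against KDE noise
        # when the two distributions are indistinguishable)
        tail_mass = np.clip(d[i:], 0.0, None).sum() * dx
        if tail_mass < min_separation_mass:
            continue
        frac = -d[i - 1] / (d[i] - d[i - 1])
        return ThresholdEstimate(
            float(grid[i - 1] + frac * (grid[i] - grid[i - 1])), default
        )
    return ThresholdEstimate(None, default)


def amplitude_range(epoch_set: EpochSet, window_fraction: float = 0.1) -> np.ndarray:
    """Per-channel amplitude range (ARNG), μV.

    Each warped epoch is split into ``1 / window_fraction`` equal
    windows; the per-window max−min values are averaged over windows and
    then over epochs.  Sub-windowing keeps single short spikes from
    dominating the statistic: a spike confined to one of ten windows
    contributes only a tenth of its excursion.
    """
    n_win = int(round(1.0 / window_fraction))
    p = epoch_set.warp_points
    if p % n_win:
        raise ValueError(
            f"warp length {p} is not divisible into {n_win} range windows"
        )
    shaped = epoch_set.epochs.reshape(
        epoch_set.n_channels, epoch_set.n_epochs, n_win, p // n_win
    )
    win_range = shaped.max(axis=3) - shaped.min(axis=3)
    return win_range.mean(axis=(1, 2))


@dataclass
class BreakingPoint:
    """Knee of a sorted ascending curve; ``index is None`` means the
    curve is a straight line ("no knee")."""

    index: Optional[int]
    value: Optional[float]

    @property
    def found(self) -> bool:
        return self.index is not None


def find_breaking_point(
    values_sorted_ascending: np.ndarray, tol: float = 1e-9
) -> BreakingPoint:
    """Knee point of an ascending curve.

    The knee maximizes the perpendicular distance below the chord that
    joins the first and last points (for a fixed chord this is
    equivalent to maximizing the vertical deviation, so the result is
    invariant to rescaling either axis).  Ties break toward the smaller
    index.  A curve that is straight to within ``tol`` (relative to its
    range) has no knee.
    """
    y = np.asarray(values_sorted_ascending, dtype=float).ravel()
    if y.size < 5:
        raise ValueError("need at least 5 values to locate a breaking point")
    if np.any(np.diff(y) < 0):
        raise ValueError("values must be sorted ascending")
    x = np.arange(y.size, dtype=float)
    chord = y[0] + (y[-1] - y[0]) * x / (y.size - 1)
    dev = chord - y  # positive below the chord
    span = y[-1] - y[0]
    scale = span if span > 0 else 1.0
    if dev.max() <= tol * scale:
        return BreakingPoint(None, None)
    idx = int(np.argmax(dev))  # argmax takes the first (smallest) index on ties
    return BreakingPoint(idx, float(y[idx]))


# ---------------------------------------------------------------------------
# condition-level pipeline
# ---------------------------------------------------------------------------


@dataclass
class ConditionResult:
    """All per-channel TCR evidence for one walking condition."""

    condition: str
    fractions: np.ndarray
    arng: np.ndarray
    breaking: BreakingPoint
    corr_table: np.ndarray
    template: np.ndarray
    n_epochs: int
    labels: list
    params: TcrParams
    threshold_estimate: Optional[ThresholdEstimate] = None

    @property
    def above_breaking(self) -> np.ndarray:
        if not self.breaking.found:
            return np.zeros(self.arng.size, dtype=bool)
        return self.arng > self.breaking.value


def _epochs_for_events(
    recording: Recording,
    event_samples: np.ndarray,
    params: TcrParams,
    duration_samples: Optional[float] = None,
) -> EpochSet:
    smoothed = smooth_moving_average(
        recording.data, recording.fs, params.smooth_window_ms, params.smooth_step_ms
    )
    pos = events_to_smoothed_positions(event_samples, smoothed)
    dur = (
        None
        if duration_samples is None
        else duration_samples / smoothed.step_samples
    )
    return epoch_and_warp(smoothed.values, pos, params.warp_points, duration=dur)


def analyze_condition(
    recording: Recording,
    events: EventSeries,
    params: TcrParams = None,
    event_label: Optional[str] = None,
) -> ConditionResult:
    """Run TCR parts 1–3 on one recording/event pair.

    ``event_label`` restricts epoching to one event type (e.g. ``"RHS"``
    so that epochs span right heel strike to next right heel strike);
    by default all events in the series are used as cycle boundaries.
    """
    params = params or TcrParams()
    if event_label is not None:
        events = events.with_label(event_label)
    if len(events) < 2:
        raise ValueError("need at least 2 epoching events")
    es = _epochs_for_events(recording, events.times, params)
    template = compute_template(es)
    corr = epoch_template_correlations(es, template)
    fractions = fraction_correlated(corr, params.corr_threshold)
    arng = amplitude_range(es, params.range_window_fraction)
    breaking = find_breaking_point(np.sort(arng))
    return ConditionResult(
        condition=recording.condition,
        fractions=fractions,
        arng=arng,
        breaking=breaking,
        corr_table=corr,
        template=template,
        n_epochs=es.n_epochs,
        labels=list(recording.labels),
        params=params,
    )


def surrogate_condition_fractions(
    recording: Recording,
    events: EventSeries,
    params: TcrParams = None,
    seed: int = 0,
    event_label: Optional[str] = None,
):
    """TCR part 1 applied to surrogate (random-event) epochs.

    Builds the surrogate ensemble, epochs the smoothed data at each
    random onset for one mean-cycle duration, computes per-set
    epoch-template correlations, and returns ``(fractions, corrs)``
    where ``fractions`` is ``(n_sets, n_channels)`` (fraction of epochs
    with r above the correlation threshold) and ``corrs`` is the pooled
    correlation sample.
    """
    params = params or TcrParams()
    if event_label is not None:
        events = events.with_label(event_label)
    n_cycles = len(events) - 1
    mean_cycle = float(np.mean(np.diff(events.times)))
    ensemble = generate_surrogate_events(
        recording.n_samples,
        recording.fs,
        n_cycles,
        n_sets=params.n_surrogate_sets,
        sectors=params.surrogate_sectors,
        fraction=params.surrogate_fraction,
        seed=seed,
        epoch_samples=mean_cycle,
    )
    fractions, pooled = [], []
    for times in ensemble.event_lists:
        es = _epochs_for_events(recording, times, params, duration_samples=mean_cycle)
        template = compute_template(es)
        corr = epoch_template_correlations(es, template)
        fractions.append(fraction_correlated(corr, params.corr_threshold))
        pooled.append(corr.ravel())
    return np.vstack(fractions), np.concatenate(pooled)


@dataclass
class ChannelDecision:
    """Per-channel rejection flags with machine-readable evidence."""

    labels: list
    flags: np.ndarray
    reasons: list
    evidence: dict

    @property
    def flagged_indices(self) -> np.ndarray:
        return np.flatnonzero(self.flags)

    @property
    def flagged_labels(self) -> list:
        return [self.labels[i] for i in self.flagged_indices]

    def to_dict(self) -> dict:
        ev_keys = list(self.evidence)
        return {
            "n_channels": len(self.labels),
            "n_flagged": int(self.flags.sum()),
            "channels": [
                {
                    "label": self.labels[i],
                    "index": int(i),
                    "flagged": bool(self.flags[i]),
                    "reasons": sorted(self.reasons[i]),
                    "evidence": {
                        k: _scalarize(self.evidence[k], i) for k in ev_keys
                    },
                }
                for i in range(len(self.labels))
            ],
        }


def _scalarize(value, i):
    """Evidence entry for channel ``i``: arrays index per channel, plain
    scalars broadcast, lists index per channel."""
    if isinstance(value, (bool, int, float, str)) or value is None:
        return value
    if isinstance(value, list):
        return value[i]
    arr = np.asarray(value)
    if arr.ndim == 0:
        return arr.item()
    out = arr[i]
    return out.item() if out.ndim == 0 else out.tolist()


def select_channels_tcr(
    result_a: ConditionResult,
    result_b: Optional[ConditionResult] = None,
    params: TcrParams = None,
) -> ChannelDecision:
    """Combine per-condition TCR evidence into rejection flags.

    A channel is flagged when, in at least one condition, its fraction
    of template-correlated epochs exceeds the fraction threshold AND its
    amplitude range lies above that condition's breaking point.  A
    channel flagged in one condition is removed from both (union rule).
    Single-condition use is allowed but warned about.
    """
    params = params or result_a.params
    results = [result_a] + ([result_b] if result_b is not None else [])
    if result_b is None:
        warnings.warn(
            "select_channels_tcr called with a single condition; the "
            "cross-condition union rule has no effect",
            stacklevel=2,
        )
    n = result_a.fractions.size
    for res in results[1:]:
        if res.fractions.size != n or res.labels != result_a.labels:
            raise ValueError("conditions were computed on different channel sets")
    flags = np.zeros(n, dtype=bool)
    met_in = [[] for _ in range(n)]
    for res in results:
        cond_flag = (res.fractions > params.fraction_threshold) & res.above_breaking
        for i in np.flatnonzero(cond_flag):
            met_in[i].append(res.condition or "condition")
        flags |= cond_flag
    evidence = {
        "fraction": np.stack([r.fractions for r in results], axis=1),
        "arng_uv": np.stack([r.arng for r in results], axis=1),
        "breaking_point_uv": np.tile(
            np.array(
                [r.breaking.value if r.breaking.found else np.nan for r in results]
            ),
            (n, 1),
        ),
        "met_in": met_in,
        "fraction_threshold": params.fraction_threshold,
        "corr_threshold": params.corr_threshold,
    }
    reasons = [{"TCR"} if flags[i] else set() for i in range(n)]
    return ChannelDecision(list(result_a.labels), flags, reasons, evidence)
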