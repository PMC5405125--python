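# Methods

## The problem

Scalp EEG recorded during walking is contaminated by motion of the
electrodes and cables. Because the head accelerates in every step, this
contamination is not random: on an affected channel, nearly the same
amplitude transient appears in nearly every gait cycle, time-locked to
heel strike. Conventional bad-channel criteria (range, variance,
kurtosis, neighbour correlation) are blind to this *repetitiveness* — a
moderately sized but perfectly stride-locked artifact passes all of
them and then leaks into every downstream analysis that is itself
locked to the gait cycle.

Template correlation rejection (TCR) targets exactly this signature.
Neural activity can modulate with the gait cycle, but it does not
reproduce the same high-amplitude waveform in three out of every four
strides; a mechanical disturbance does.

## The channel-level procedure

For each channel, on a smoothed copy of the recording:

1. **Smoothing.** Moving average with 100 ms windows advanced in 50 ms
   steps, emitting one value per step. The decimated series (rather
   than a same-rate smoothed series) is deliberate: the correlation
   statistic should compare coarse amplitude envelopes, not
   sample-level noise, and a ~1.2 s gait cycle then contains ~24
   effective values.
2. **Epoching and warping.** The smoothed trace is cut at successive
   heel strikes of one foot (half-open segments, 0-based sample
   coordinates) and every cycle is linearly resampled to 1,000 points,
   removing stride-duration variability.
3. **Template and correlations.** The per-channel template is the
   plain across-epoch mean of the warped epochs. Each epoch is
   correlated with the template (Pearson r), giving an epochs ×
   channels table. Zero-variance epochs get r = 0, which counts as
   below any positive threshold, keeping the fraction statistic total.
   The epoch under test is *not* left out of the template; the
   resulting bias is O(1/n_epochs) and irrelevant at tens of cycles.
4. **Fraction of correlated epochs.** A channel is a candidate when
   more than 75% of its epochs (3 of every 4) exceed r = 0.4. The
   comparison is signed — anticorrelated epochs never count, because
   a mechanical artifact repeats with the same polarity.
5. **Amplitude gate.** The amplitude range (ARNG) of a channel is the
   per-epoch mean of ten per-window (10% of the epoch) max−min values,
   averaged over epochs; sub-windowing keeps one short spike from
   dominating (a spike confined to one window contributes a tenth of
   its excursion). Channel ARNGs are sorted ascending and the
   *breaking point* is the knee of that curve: the point of maximal
   perpendicular distance below the chord joining the first and last
   points (equivalently, maximal vertical deviation — the argmax is
   the same for any axis scaling; ties break toward the smaller index;
   a curve straight to within 1e-9 of its range has no knee, and
   without a knee no channel passes the amplitude gate). Candidates
   must lie strictly above the breaking-point value.
6. **Cross-condition union.** A channel flagged (fraction *and*
   amplitude criteria) in either walking condition is removed from
   both. The flag requires the full conjunction in at least one
   condition; removal is the union.

### Chance-level calibration (surrogate events)

The r > 0.4 / 75% thresholds are justified by a surrogate analysis:
10 event sets of randomly timed onsets, each holding 50% as many
events as there are real cycles (fewer events make randomly placed
epochs unlikely to overlap), stratified as evenly as possible over 5
equal-duration recording sectors and uniform within each sector. Each
surrogate onset starts an epoch of one mean cycle duration; epochs
running past the end of the recording are dropped. The same smoothing
/ warping / template / correlation machinery is applied to these
epochs. On the synthetic recordings the mean fraction of surrogate
epochs with r > 0.4 is ≈17% — random epoching stays under 20%, so a
channel at 75% is far outside chance.

The package can also estimate the threshold from the data: kernel
density estimates (Silverman bandwidth, histogram-binned on [−1, 1],
Gaussian-smoothed with reflection at the boundaries) of the
experimental and surrogate correlation samples are intersected. The
estimate is the rightmost point right of the surrogate mode where the
rising experimental density crosses above the falling surrogate
density, accepted only when at least 1% of experimental probability
mass exceeds the surrogate beyond the crossing; otherwise the result
is "no separation" and the fixed default 0.4 is used. The
between-the-modes formulation fails whenever clean channels dominate
the pooled sample (both modes then coincide near zero), which is why
the crossing is searched to the right of the surrogate mode instead.
On two equal-variance Gaussians the estimator returns the analytic
midpoint of the means. Note that the estimated intersection depends on
the *shape* of the contaminated lobe: with broadly distributed
artifact correlations (moderate artifact amplitude) it falls around
0.3–0.5, while extremely strong synthetic artifacts (a narrow lobe at
r ≈ 0.95) push the crossing to ≈0.6. The fixed 0.4 default is used
for the rejection rule in either case.

## Independent components

The same parts 1–2 apply unchanged to the rows of a linear
decomposition's activation matrix (the decomposition itself — e.g.
Infomax or FastICA — is an input, not something this package runs).
The amplitude gate is dropped because component units are arbitrary.
A gait-locked component (fraction > 75%) is *retained* when it shows
positive evidence of neural content:

- **Spectral peak.** The component PSD (Welch, same 512 ms window /
  1,024 ms zero-pad convention as the band power) is fitted with a
  log-log straight line over 1.5–80 Hz (two passes, the second
  ignoring bins more than one SD above the first fit). A peak
  qualifies when its centre lies in the alpha (9–13), beta (14–30) or
  gamma (31–80 Hz) band and it rises at least 3 dB — *and* at least 3
  robust SDs of the residual ripple — above the fit. The ripple gate
  matters: a stride-locked transient has a harmonic-comb spectrum
  whose interference ripples (the "jagged" profile produced by two
  transients ~250 ms apart) reach 5–12 dB throughout the band; on the
  fixtures the artifact component's residual ripple is ≈5 dB MAD
  versus ≈0.35 dB for genuine oscillations, so single comb ripples
  never qualify while true alpha/beta peaks always do. Delta/theta
  peaks are recorded but never count as neural evidence.
- **Scalp-map smoothness.** Smoothness is one minus the ratio of the
  mean absolute difference between nearest-neighbour sensors (k = 6)
  to the mean absolute difference over all sensor pairs, clipped to
  [0, 1] — a spatial-contiguity ratio. A map varying slowly across the
  layout scores near 1; a scattered or single-sensor map scores near
  0. (A pair-count-normalized mean gradient would score a sparse map
  as "smooth" because almost all of its neighbour pairs are 0–0.)
  The default cutoff 0.55 is the 10th percentile of the smoothness of
  synthetic Gaussian neural maps across ring layouts of 64–256
  sensors; synthetic artifact and shuffled maps score ≈0. A manual
  override field per component allows review to force either decision.

Flagged components are removed by back-projection: the mixing-matrix
columns of the flagged set times their activations are subtracted from
the channel data, leaving the retained subspace untouched to
floating-point precision.

## Preprocessing

- **High-pass**: zero-phase linear-phase FIR (Hamming design), 1 Hz
  cutoff, 0.2 Hz transition band — ≈8,400 taps at 512 Hz — applied
  with centred overlap-add convolution. Passband flat within ±0.5 dB
  above 1.2 Hz.
- **Line noise**: zero-phase IIR notch (Q = 30, `filtfilt`) at the
  line frequency and all harmonics below Nyquist. This replaces
  sliding-window sinusoidal regression tools; for the synthetic and
  validation use here a deep static notch is sufficient.
- **Conventional rejection ("method 1")**, applied before TCR:
  peak-to-peak range outside 30–3,000 μV; kurtosis more than 5 SDs
  above the across-channel mean (median/MAD optional); best
  correlation with the 8 nearest sensors below 0.4 in more than 1% of
  1 s non-overlapping windows; and standard deviation above the knee
  of the sorted across-channel SD curve. The last two criteria
  additionally require the channel to be a robust outlier (median/MAD
  z > 5) across the montage. Without that gate the criteria are
  degenerate: a montage of mutually weakly correlated channels is
  flagged wholesale by the absolute correlation rule, and a knee
  always splits even a homogeneous montage in two. The SD knee with
  outlier gate is an automated stand-in for what is usually done by
  visual inspection of the sorted SD curve.
- **Gait events**: initial contact at the sample where the vertical
  ground-reaction force first reaches 15 N, toe-off where it drops
  below. Any crossing within 100 ms of the last accepted event is
  ignored (a minimum phase duration). Debouncing only same-direction
  crossings is not enough: chatter produces close *opposite*-direction
  crossings which would derail the contact/toe-off alternation.
  Alternation is enforced starting from the first contact.

## Band power diagnostics

Absolute band power uses Welch averaging with 512 ms segments
zero-padded to 1,024 ms at 50% overlap, integrated over delta 1–4,
theta 5–8, alpha 9–13, beta 14–30 and gamma 31–80 Hz (inclusive
edges, one-sided totals in μV²). The default taper is a Slepian
(DPSS, NW = 1.2) window rather than Hamming: with 0.5 s segments the
main lobe is ≈2 Hz wide, and the Slepian's maximal spectral
concentration is what keeps a narrow line's energy inside a 3–4 Hz
band (with Hamming, ~5.5% of a 10 Hz line leaks out of alpha; with
DPSS 1.2 it is ~2.4%, and white-noise band powers are proportional to
bandwidth within 2% after seed-averaging). Any scipy window name can
be passed instead.

The gait-locked amplitude map converts one channel to a centred 50 ms
sliding RMS and stacks event-locked segments, one row per cycle, with
the across-epoch mean trace as the summary. On artifact channels the
mean trace shows the post-contact transient at many baseline SDs;
with shuffled events it does not.

## The synthetic-data generator

Validating an artifact-rejection method on real walking EEG is
circular — there is no ground truth for which channel is artifact.
The generator therefore constructs recordings where the truth is known:

- **Background**: per-channel Gaussian noise spectrally shaped to
  PSD ∝ 1/f^β (β = 1 by default), normalized to 10 μV SD — an
  EEG-like broadband floor on every channel.
- **Neural sources**: 10 Hz (4 μV) and 25 Hz (2 μV) sinusoids with
  random phase, projected through 2-D Gaussian spatial maps over a
  concentric-ring sensor layout on the unit disc (the layout is
  generated internally; no published 256-electrode geometry is
  assumed).
- **Gait cycles**: durations drawn from Normal(1.2 s, 0.1 s), clipped
  to ±60% of the mean; one contact event per cycle.
- **Artifact**: two Gaussian transients per cycle — 50 ms latency,
  20 ms width, full amplitude (heel-strike impact) and 300 ms
  latency, 50 ms width, 0.6× amplitude (mid-stance) — with per-cycle
  timing jitter (10 ms SD) and fixed per-channel gains in 0.7–1.3,
  added only on the configured artifact channels (10 evenly spaced by
  default). The default amplitude, 120 μV, makes the artifact
  channels' smoothed amplitude range ≈4× that of clean channels —
  the "unambiguously contaminated" regime the recovery validation
  assumes (≥3× background ARNG). The true waveform shape of walking
  artifacts is not known; only their stride-locked repetitiveness is
  emulated, which is the one property TCR uses.
- **Ground-reaction force**: a double-bump stance profile (weight
  acceptance and push-off) occupying 60% of each cycle, rising
  through 15 N exactly at the true contact sample.
- **IC mixtures**: a variant builds the recording as an explicit
  mixing of known sources (component 0 = artifact train, next
  components = the neural oscillations, rest = 1/f noise) so the
  decomposition, and hence the component-level ground truth, is exact.

Everything is a pure function of the integer seed (bit-identical
reruns).

What the generator does **not** emulate: volume conduction from a
head model (spatial maps are ad hoc Gaussians), eye/muscle artifacts,
non-stationary artifact morphology, electrode pops, or correlated
background noise between channels. Consequently, passing the
validation shows that the statistics behave as designed under the
stated model — stride-locked transients are detected, non-locked
oscillations are spared — not that real-data rejection counts will
match any particular study.

## Validation scales and numerical choices

The validation suite runs the full two-condition pipeline at 128
channels / 45 cycles / 256 Hz over 20 seeds (sensitivity ≥ 0.9 with
false positives ≤ 5% at the default artifact amplitude; zero flags in
≥ 95% of artifact-free runs), and the chance-level calibration at 32
channels / 500 cycles (channel count does not affect the per-channel
fraction statistic, cycle count does). The full-scale calibration
(256 channels, 500 cycles, 512 Hz, 10 surrogate sets of 250 events)
is what `scripts/acceptance.py` recomputes; it lands at ≈17%.

Other numerical conventions: sample indices are 0-based and intervals
half-open; warping uses linear interpolation with endpoints preserved
(a segment already 1,000 points long is returned unchanged); epochs
shorter than 4 smoothed points are skipped with a warning; Pearson
correlations are computed via centred dot products and match a direct
`np.corrcoef` to 1e-12; surrogate per-sector counts differ by at most
one, and times are made strictly increasing after sorting.

## Known limitations

- The breaking point needs enough channels to be meaningful; below
  ~64 channels the sorted-ARNG curve is short and the knee unstable.
- With all channels contaminated equally there is no knee to find and
  the amplitude gate passes nothing (by design, the method flags
  channels that stand out).
- The smoothness proxy depends on sensor positions; without positions
  component retention rests on spectral peaks alone.
- The surrogate chance level inherits the autocorrelation of the
  background; heavily oversmoothed or strongly low-frequency data
  raise it (the 1 Hz high-pass the pipeline assumes keeps it under
  20%).
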