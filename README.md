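# tcreject — template correlation rejection for walking EEG

`tcreject` identifies and removes EEG channels and independent
components that carry **motion-locked artifacts** recorded during
cyclic movement such as treadmill walking. It is aimed at mobile
brain/body-imaging pipelines: high-density EEG plus ground-reaction
forces (or precomputed gait-event tables), where stride-locked
electrode motion contaminates a subset of channels in a way that
range/kurtosis/correlation criteria do not catch.

## The method

During steady walking the head accelerates in every step, so an
affected channel repeats nearly the same amplitude transient in nearly
every gait cycle. TCR (template correlation rejection) quantifies that
repetitiveness. Per channel, on a smoothed copy of the data
(100 ms moving average, 50 ms steps):

1. cut the signal into gait cycles (heel strike → next heel strike of
   the same foot, detected as 15 N crossings of the vertical
   ground-reaction force) and time-warp every cycle to 1,000 points;
2. average the warped epochs into a template `AV_GAIT` and compute the
   Pearson correlation `r` of each epoch with it;
3. flag the channel as a candidate when the fraction of epochs with
   `r > 0.4` exceeds 75% — randomly timed surrogate epochs stay below a
   20% fraction, so 3-of-4 cycles cannot be chance;
4. require the channel's amplitude range `ARNG` (mean of per-10%-window
   max−min values, averaged over epochs) to lie above the *breaking
   point* — the knee of the ascending sorted-`ARNG` curve across
   channels;
5. a channel flagged in either walking condition (e.g. eyes-open /
   blindfolded) is removed from both.

For independent components the same correlation statistic is applied to
the activation rows (no amplitude gate — component units are
arbitrary); a gait-locked component is kept only if it shows evidence
of neural content (an alpha/beta/gamma spectral peak above the 1/f
background, or a smooth dipole-like scalp map), and removed components
are subtracted by mixing-matrix back-projection.

Because no public walking-EEG dataset comes with artifact ground truth,
the package ships a first-class synthetic-data module
(`tcreject.synthetic_data`): 1/f background, oscillatory neural sources
with smooth scalp maps, stride-duration variability, a heel-strike-
locked artifact waveform on known channels, and a ground-reaction force
whose 15 N crossings mark the true contacts. All validation runs
against that ground truth. See `docs/methods.md` for the model and its
limits.

## Worked example

Simulate two walking conditions (64 channels, 60 gait cycles, 512 Hz;
10 channels carry the injected artifact), detect gait events from the
force trace, and run the channel-level method:

```sh
$ tcr simulate --out walk_eo --channels 64 --cycles 60 --fs 512 --seed 1
wrote 64-channel recording (73.7 s), 61 events, 10 artifact channels
$ tcr simulate --out walk_bf --channels 64 --cycles 60 --fs 512 --seed 2
wrote 64-channel recording (74.5 s), 61 events, 10 artifact channels
$ tcr detect-events --grf walk_eo_grf.tsv --fs 512 --threshold 15 --out events.tsv
61 contacts, 61 toe-offs -> events.tsv
$ tcr channels --in walk_eo.json --in walk_bf.json \
      --events walk_eo_events.tsv --events walk_bf_events.tsv \
      --out decisions.json
flagged 10 channels -> decisions.json
```

The ten flagged channels are exactly the ten that carry the injected
artifact (`E001, E008, …, E064` — the ground truth is in
`walk_eo_truth.json`). Each entry in `decisions.json` carries the
evidence behind the decision, per condition:

```json
{
 "label": "E001",
 "flagged": true,
 "reasons": ["TCR"],
 "evidence": {
  "fraction": [0.983, 1.0],
  "arng_uv": [17.14, 14.92],
  "breaking_point_uv": [5.27, 5.17],
  "fraction_threshold": 0.75,
  "corr_threshold": 0.4
 }
}
```

Read: 98% and 100% of this channel's gait cycles correlate with its
template at `r > 0.4` (threshold 75%), and its amplitude range (17.1
and 14.9 μV) lies above the breaking point of the sorted channel curve
(5.3 and 5.2 μV) in both conditions — so it is removed.

The same library surface is available from Python
(`tcreject.analyze_condition`, `tcreject.select_channels_tcr`,
`tcreject.tcr_score_components`, …), and `tcr components` / `tcr
method1` / `tcr diagnose` cover component screening, conventional
bad-channel rejection and band-power / gait-locked-amplitude
diagnostics.

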