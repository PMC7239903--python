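# ripplering

Analysis pipeline for the coupling of anterior-thalamic head-direction (HD)
and non-HD neurons to hippocampal sharp wave-ripples (SWRs), together with a
fully parameterized synthetic session generator so every stage can be tested
end to end without any recorded data.

## What it does

- **`ripplering.synth`** — synthetic sessions: a latent ring trajectory
  (state-dependent angular diffusion, optional pre-SWR stabilization and
  gain increase), von Mises HD units, non-HD units with refractoriness,
  Hawkes-like burstiness, slow log-rate (OU) timescales, oscillatory
  SWR-coupling kernels and theta-phase modulation; UP/DOWN gain modulation
  during NREM; an LFP with ripple bursts and theta. Deterministic per seed;
  writes plain TSV/JSON session files.
- **`ripplering.events`** — session I/O, SWR detection (Gaussian band-pass
  80–300 Hz, squared, 11-sample smoothing, z-scored, 3/7 s.d. thresholds,
  25–350 ms duration filter, 30 ms merging), UP/DOWN detection from
  population firing (10 ms bins, 20 ms smoothing, 20% threshold), normalized
  DOWN+UP event-rate profiles, and baseline event sampling.
- **`ripplering.tuning`** — HD tuning curves, Rayleigh classification
  (peak > 1 Hz, p < 0.001, kappa > 1), Poisson Bayesian decoding of angle
  (30 ms bins, 50% overlap, 6° angle bins, log-domain), and normalized
  angular-velocity time courses around events.
- **`ripplering.ring`** — population rate matrices (sqrt + Gaussian
  smoothing), joint ISOMAP embedding of wake and event-locked windows in
  batches, polar radius/angular-velocity statistics around SWRs normalized
  against baseline events.
- **`ripplering.coupling`** — event-triggered cross-correlograms (5 ms bins,
  ±500 ms), z-normalization against a 150 ms low-passed expectation under a
  Poisson variance model, SWR energy, Morlet-wavelet theta phases and spike
  phase modulation, jPCA (antisymmetric dynamics fit in closed form) and
  per-unit SWR phases, circular-circular correlation.
- **`ripplering.dynamics`** — per-state auto-correlograms, burst index
  (observed 2–9 ms ISI count over the homogeneous-process expectation),
  exponential decay-time fits, K-means/t-SNE clustering of normalized
  auto-correlogram shapes, within-shank pairwise curve correlations.
- **`ripplering.structure`** — PCA weights of curve matrices, determinant
  total correlation (rho² = 1 − |C|) with global/within-shank shuffle nulls
  and partial-correlation variants, theta-depth vs SWR-energy correlation,
  and HD-vs-non-HD classification from auto-correlograms with a
  shuffle-referenced score (gradient-boosted trees).

## CLI

```sh
ripplering generate --out session/ --seed 1 --n-hd 24 --n-nonhd 24
ripplering detect-swr --manifest session/manifest.json --low 3 --high 7
ripplering detect-updown --manifest session/manifest.json
ripplering ccg --manifest session/manifest.json        # z-CCGs + SWR energy
ripplering jpca --manifest session/manifest.json       # per-unit SWR phases
ripplering dynamics --manifest session/manifest.json   # burst index, taus, clusters
ripplering couple --autocorr A.tsv --ccg B.tsv --shuffle global
```

Session files are plain text: a JSON manifest, spikes TSV
(`unit_id shank_id time_s`), epochs TSV (`label start_s end_s`), events TSV
(`start_s peak_s end_s`), and LFP as int16 binary (with scale metadata) or
TSV.

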