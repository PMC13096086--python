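# freqstate

Frequency-resolved EEG microstate analysis with a synthetic-data generator,
built as a reusable Python package.

The pipeline characterizes multichannel EEG across consciousness states
(wakefulness, LOC, ROC) by:

1. **signal prep** — zero-phase 5th-order Butterworth band-pass filtering
   into six bands (broadband 1–45, delta 1–4, theta 4–8, alpha 8–15,
   beta 15–30, gamma 30–45 Hz), polyphase resampling, common-average
   re-referencing (`freqstate.prep`);
2. **spectra** — sliding-window multitaper PSD (2-s windows, 1.5-s hop,
   time–bandwidth 3, five Slepian tapers), band powers, dB normalization to
   the wakefulness baseline (`freqstate.spectral`);
3. **microstates** — GFP and GFP-peak extraction, polarity-invariant
   modified k-means (assignment by maximal squared spatial correlation,
   eigenvector centroid updates, best of 20 restarts), GFP²-weighted global
   explained variance, a predictive-residual CV criterion, and a k = 2–8
   scan with fixed-k (default 7) or elbow selection
   (`freqstate.microstates`);
4. **templating / back-fitting** — polarity-aligned multi-level map
   averaging (individual → condition → grand), optimal-assignment sorting
   against a canonical A–G template set, back-fitting with midpoint
   interpolation between GFP peaks, truncated-fragment exclusion, and
   per-class duration / occurrence / coverage / IEV (`freqstate.backfit`);
5. **group statistics** — Monte-Carlo Lilliefors normality screening,
   one-way repeated-measures ANOVA, Bonferroni-corrected paired t-tests
   (`freqstate.stats`);
6. **classification** — feature tables (`band.class.param`, 28 / 140 / 168
   columns), hybrid diagonal-NCA + greedy-MRMR feature scoring with min–max
   composite top-10 selection, linear SVM and 100-tree random forest under
   LOOCV or stratified 5-fold with per-fold standardization and (by
   default) nested selection (`freqstate.classify`);
7. **synthetic data** — cohorts with known microstate ground truth:
   semi-Markov state sequences (gamma dwell times, no self-transitions),
   smooth polynomial topographies, rectified band-limited carriers,
   condition effects and between-subject jitter, all reproducible from one
   seed (`freqstate.synthetic`).

Recordings round-trip through a packaged `.npz` + JSON sidecar format or a
minimal EDF writer/reader; models and reports are JSON; tables are tidy CSV.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (structural
constants, brute-force clustering oracle, cohort parameter recovery,
spectral sanity, statistical calibration, classifier contract, metric
identities).

## CLI

Every stage is a subcommand driven by a YAML config:

```sh
freqstate run-all --config cohort.yaml --out out/
freqstate simulate --config cohort.yaml --out out/
freqstate segment --config cohort.yaml --out out/   # re-run one stage
```

Example config:

```yaml
seed: 1
bands: {broadband: [1.0, 45.0], alpha: [8.0, 15.0]}
cohort:
  n_subjects: 4
  conditions: [wake, LOC, ROC]
  n_templates: 7
  n_channels: 16
  duration_s: 30.0
  snr: 5.0
microstate: {fixed_k: 7, restarts: 20}
classification: {model: linear_svm, cv: loocv, top_n: 10}
```

Exit codes: 0 ok, 1 stage failure, 2 config error. A `manifest.json` in the
output directory records per-stage artifacts with SHA-256 checksums, seeds,
and timing; re-running an unchanged config reproduces identical checksums.

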