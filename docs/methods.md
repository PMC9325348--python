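# Methods

## Problem and scope

`ecgbp` estimates systolic and diastolic blood pressure (SBP/DBP, mmHg) from
short windows of ECG alone, and determines the shortest window ("epoch")
duration that preserves peak estimation accuracy. The package covers the
full protocol — epoching, labelling from the pressure waveform, 25
time-domain features, Spearman subset levels, three regressors, seven
metrics, and the minimum-time decision rule — plus a synthetic generator
that makes the whole chain testable against known ground truth.

## Labelling from the pressure waveform

Arterial pressure oscillates once per heartbeat between the diastolic
trough and the systolic peak, so per-epoch labels are taken directly from
the waveform: SBP is the mean of the interior local maxima in the window,
DBP the mean of the interior local minima. The detector applies a 5-sample
moving average (reflect-padded) before the peak search and enforces a
minimum peak separation of 0.33 s, i.e. a 180 bpm ceiling; label values are
read from the raw (unsmoothed) samples at the detected indices. Extrema on
the first or last sample of a window are artifacts of the windowing, not
beats, and are excluded. Windows are 0-based and half-open; the trailing
partial window of a record is discarded. Epochs whose pressure window
yields no usable extrema are dropped together with their ECG window so
features and labels stay paired. Epochs are consecutive and
non-overlapping; a sliding-window variant would change every epoch count
downstream and is deliberately not offered.

## The 25 features

All features are computed on the raw epoch samples. Where the conventional
definitions admit variants, the following are frozen:

- `std` is the sample standard deviation (divisor n−1); `hjorth_activity`
  is its square; `standard_error` is std/√n.
- `kurtosis` and `skewness` divide by (n−1)·Sᵏ — plain, not excess,
  kurtosis.
- Hjorth mobility is √(var(Δx)/var(x)); complexity is
  mobility(Δx)/mobility(x), with variances ddof = 1.
- `curve_length` is the mean absolute first difference; `teager_energy` is
  (1/n)Σᵢ₌₃ⁿ (x²ᵢ₋₁ − xᵢxᵢ₋₂).
- Geometric and harmonic means operate on |x| + 1e−12: a zero-mean ECG has
  negative and near-zero samples on which both are otherwise undefined.
- `iqr` uses linearly interpolated quantiles; `mean_abs_deviation` deviates
  from the mean, not the median.
- Trimmed means remove 12.5 % (`trimmed_mean_25`) or 25 %
  (`trimmed_mean_50`) of the points per tail, with the per-tail count
  rounded half-up.
- `shape_factor` is RMS over mean |x|; `svd_norm` is the Euclidean norm
  (the sole singular value of a 1 × n matrix).
- Ratio statistics (cv, skewness, kurtosis, shape factor, mobility,
  complexity) return 0 on constant input rather than propagating NaN.

The order of the 25 names is frozen in `FEATURE_NAMES` and is the
tie-breaking key in the ranking.

## Selection

Spearman correlation is implemented as the Pearson correlation of mid-ranks
(average ranks on ties), clipped to [−1, 1]; zero rank variance yields 0
with a warning. Ranking is by |r_s|: "most correlated" is read as magnitude
since a strongly negative monotone association is equally informative.
Equal magnitudes break toward the lower frozen feature index. Ranking uses
the training split only, so the held-out split cannot influence selection
(the leakage-guard test permutes test labels and asserts a bit-identical
ranking).

Levels take the top 5 %, 10 %, …, 50 %, then 100 % of the features, with
counts rounded half-up (2.5 → 3, 7.5 → 8, 12.5 → 13); for 25 features the
ladder is exactly {1, 3, 4, 5, 6, 8, 9, 10, 11, 13, 25}. Levels are nested
prefixes of the ranking.

## Models

- **FT** — one `DecisionTreeRegressor`, `min_samples_leaf=4` (the "fine"
  preset).
- **EBT** — `BaggingRegressor` of 30 trees, `min_samples_leaf=8`; the
  ensemble prediction is exactly the mean of the member predictions.
- **GPR** — `GaussianProcessRegressor` with a constant × Matérn(ν = ½)
  kernel — the exponential / Ornstein–Uhlenbeck covariance — plus a fitted
  white-noise term; hyperparameters by marginal-likelihood maximization
  with 3 restarts. Inputs are standardized with training statistics
  (unstandardized exponential-kernel GPs on raw feature scales diverge
  easily); targets are internally centred. Exact GP fitting is O(n³), so
  above `gpr_max_train` rows (default 1000) the GP is fitted on a
  deterministic random subset of the training data — the standard
  subset-of-data approximation used by the common toolboxes for large
  tabular fits. A `noise_level` override pins the noise variance instead of
  fitting it (used by the interpolation tests).

No cross-validation or tuning is performed inside the grid: each cell is a
single fit with frozen defaults, reproducible from the seed.

## Metrics

With e = t − y: MAPE = mean|e/t|·100 (a percentage, reported as such even
where pressure tables habitually caption it mmHg), MAD = mean|e|,
SE = √(Σe²/(n−2)) (undefined at n = 2, returned as +inf), MSE = mean e²,
RMSE = √MSE, R = Pearson(t, y), and R² defined as the *square of R* — not
the coefficient of determination; the two coincide only for an unbiased
linear fit, and the squared-R convention is what the benchmark tables this
pipeline mirrors use (printed pairs like R = 0.97, R² = 0.94 match 0.97²).
Bland–Altman agreement reports mean(d) and mean(d) ± 1.96·SD(d) (sample SD)
for d = t − y.

## Grid, split and the minimum-time rule

Per duration: pool the usable epochs of all subjects, split 80/20 (train
count = round-half-up(0.8 n); random permutation by seed, with sequential
and leave-one-subject-out alternatives — pooled random splitting lets
subject identity leak between train and test, so the holdout mode exists
for stricter evaluation), rank on train, and score all 11 × 3 = 33 cells on
the held-out split, separately for SBP and DBP. Durations pooling fewer
than 50 usable epochs are skipped with a warning.

Best model per duration: lowest test MAPE, ties to higher R, remaining ties
to GPR > EBT > FT. The minimum time is the smallest duration whose best row
attains the maximum R over durations and a MAPE within `delta_mape` of the
minimum, jointly for both targets; `delta_mape` defaults to 0.1 — an
improvement of that order (e.g. 0.07) is treated as insignificant. If no
duration qualifies jointly the rule falls back to the lowest summed MAPE
rank (smallest duration on ties).

## Synthetic generator

The generator emulates what the pipeline needs from a real recording — a
beat-periodic ECG-like signal whose morphology co-varies with a
synchronized pressure-like oscillation — not clinical realism.

Beats occur at intervals jittered by `hr_jitter_frac` (default 3 %) around
the configured heart rate (default 60 bpm at 64 Hz). Per-beat latents
drive the physiology: a slow amplitude process and the standardized rate
deviation, plus per-target slow drift and white residuals. All latents are
empirically standardized and sequentially orthogonalized in-sample
(Gram–Schmidt): slow processes are heavily autocorrelated, so two
independent draws can show large spurious sample correlation over a finite
recording; orthogonalization makes the coupling weights exact variance
fractions and the configured label SDs exact per record. Per-beat pressures
are then linear in the latents with SD-fraction weights from the `Coupling`
config (defaults 0.6 amplitude, 0.2 rate; the residual splits 80/20 between
slow drift and white noise), means 120/80 mmHg and SDs 10/7 mmHg; DBP is
clipped to at least 5 mmHg below SBP so the ordering invariant always
holds.

The ECG is a train of Gaussian R-spikes (FWHM 40 ms) with height
1 + 0.25·z_amp — only statistical features are consumed downstream, so
morphological realism (P/T waves, arrhythmias, motion artifacts) is out of
scope. The pressure waveform follows a quarter-phase-shifted raised cosine
from trough to peak within each beat, so every beat contributes exactly one
*interior* maximum and minimum (a trough-phased cosine would park one
extremum on the window boundary, where the detector rightly ignores it);
a noiseless 4 s window at 60 bpm therefore shows exactly 4 maxima at the
systolic value and 4 minima at the diastolic value. White noise of SD
`noise_sd` (default 0.02) is added to both signals. Subject k of a cohort
uses seed `config.seed + k`; identical configurations are bit-identical.

What passing tests on this generator do *not* show: robustness to real ECG
morphology and artifacts, to sensor drift, to inter-subject physiological
diversity, or to the much weaker ECG↔BP coupling of real recordings — the
generator's coupled conditions are a best case by construction.

## Problem sizes and numerical choices

The recovery acceptance test runs a 5-subject × 30-minute cohort at a
single 16 s grid duration — enough epochs (~560) for stable metrics while
keeping the 22 GP fits affordable; smaller cohorts exercise the grid across
multiple durations. The independence test (coupling = 0) uses a 4 s drift
timescale matching the epoch length: with slow drift the effective number
of independent epochs would be far below the nominal 500 and the null
spread of max |r_s| across 25 features correspondingly wider — an
autocorrelation effect, not a coupling one. Feature-formula agreement with
the independent literal oracle is asserted to 1e−10 relative; GP
interpolation at pinned noise to 1e−3 absolute.

## Known limitations

- The per-subject 125-column wide layout is exported for compatibility, but
  the pipeline trains on pooled epochs over the 25 feature columns; the two
  framings are not equivalent and the pooled one is canonical here.
- Published benchmark rows bundled in `ecgbp.reference` are inputs for the
  decision rule only; the underlying recordings are unavailable, so their
  per-cell metric values are not reproducible by this package and no
  attempt is made.
- MAPE is scale-dependent on the label mean; comparing SBP and DBP MAPEs
  across studies with different cohorts is not meaningful.
- The GP subset-of-data cap trades accuracy for tractability above 1000
  training rows; results at large n depend mildly on the subset seed.
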