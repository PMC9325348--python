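# ecgbp

**How many seconds of ECG are enough to estimate blood pressure?**

`ecgbp` is a pipeline for answering that question with paired ECG and
continuous arterial-pressure recordings. Cuffless blood-pressure estimation
maps features of a cardiovascular waveform to systolic (SBP) and diastolic
(DBP) pressure; for wearable and embedded use the open design choice is the
*epoch duration* — how long a window of signal the estimator needs before it
can produce a reading. `ecgbp` evaluates the whole grid of epoch durations ×
feature subsets × regression models and applies an explicit rule for the
shortest duration that preserves peak accuracy.

It is written for biomedical-signal researchers and students who want a
tested, reproducible reference implementation of this protocol, including a
synthetic-data generator with known per-beat ground truth so every stage can
be validated without access to clinical recordings.

## The method

1. **Epoching and labelling.** Paired same-rate ECG and BP waveforms
   (default 64 Hz) are cut into consecutive non-overlapping epochs of
   2, 4, …, 20 s. Within each BP epoch the interior local maxima and minima
   are detected (5-sample smoothing, 0.33 s minimum peak separation); the
   label is SBP = mean of the maxima, DBP = mean of the minima — one beat
   contributes one systolic peak and one diastolic trough.
2. **Features.** Each ECG epoch yields 25 time-domain statistics: moments
   (mean, s, skewness, kurtosis, 10th central moment), robust summaries
   (median, IQR, 25 %/50 % trimmed means, mean absolute deviation), energy
   measures (average energy, RMS, curve length ⟨|Δx|⟩, Teager energy
   ⟨x²ᵢ₋₁ − xᵢxᵢ₋₂⟩), Hjorth activity/mobility/complexity, and shape
   descriptors (CV, shape factor, Euclidean norm, extrema).
3. **Selection.** Features are ranked by |r_s|, the Spearman correlation
   with the target on the *training split only*, and taken in 11 nested
   levels: the top 5 %, 10 %, …, 50 % and 100 % of the 25 features — subset
   sizes 1, 3, 4, 5, 6, 8, 9, 10, 11, 13, 25 (percentages rounded half-up).
4. **Models and metrics.** Three regressors per cell — a fine decision tree
   (leaf size 4), 30 bagged trees (leaf size 8), and a Gaussian process with
   an exponential (Matérn ν = ½) kernel — evaluated on a held-out 20 % split
   with seven measures: MAPE, MAD, SE (divisor n−2), MSE, RMSE, Pearson R
   and R². Bland–Altman limits of agreement are exported for the best cell.
5. **Minimum-time rule.** For each duration take its best model (lowest
   MAPE; ties to higher R, then GPR > EBT > FT). The selected duration is
   the smallest one whose best row attains the maximum R over durations
   *and* a MAPE within `delta_mape` (default 0.1) of the minimum — jointly
   for SBP and DBP.

## Worked example

```python
import ecgbp

coupling = ecgbp.Coupling(amp_to_sbp=0.9, rate_to_sbp=0.3,
                          amp_to_dbp=0.9, rate_to_dbp=0.3)
cfg = ecgbp.SimConfig(duration_s=600, coupling=coupling, hr_jitter_frac=0.05,
                      noise_sd=0.005, seed=7)
cohort = ecgbp.generate_cohort(3, cfg)
grid = ecgbp.run_grid(cohort, ecgbp.GridConfig(durations_s=[4.0, 8.0, 16.0],
                                               split=ecgbp.SplitSpec(seed=7), seed=7))
best = grid.best_per_duration("SBP")
print(best[["duration_s", "level", "fn", "algorithm", "MAPE", "RMSE", "R"]]
      .round(3).to_string(index=False))
print("selected minimum duration:", ecgbp.select_min_time(grid, delta_mape=0.1), "s")
```

prints

```
 duration_s  level  fn algorithm  MAPE  RMSE     R
        4.0     10  13       GPR 2.139 3.155 0.935
        8.0     10  13       GPR 2.066 3.123 0.927
       16.0     11  25       GPR 1.925 2.757 0.962
selected minimum duration: 16.0 s
```

Three synthetic subjects (10 min each) whose per-beat pressures are strongly
coupled to the ECG spike amplitude and rate. At every duration the grid of
33 (level × model) cells is scored on the held-out split; the best SBP cell
uses the GPR with 13–25 features, MAPE falls from 2.14 % at 4 s to 1.93 % at
16 s, and correlation R peaks at 16 s — so the joint rule selects 16 s as the
shortest duration with peak performance on this run.

The same workflow is available from the shell:

```bash
ecgbp generate --config cfg.yaml --out data/
ecgbp run-grid --data data/ --config cfg.yaml --out run/
ecgbp select-time --grid run/grid.json --delta 0.1
ecgbp report --grid run/grid.json --out report/
```

## Layout

| module | contents |
| --- | --- |
| `ecgbp.synthetic` | paired ECG/BP generator with per-beat ground truth |
| `ecgbp.epoching` | records, windowing, extrema detection, labels, CSV I/O |
| `ecgbp.features` | the 25 statistics and the feature table |
| `ecgbp.selection` | Spearman ranking and the 11 subset levels |
| `ecgbp.regression` | FT / EBT / GPR training and prediction |
| `ecgbp.metrics` | the seven measures and Bland–Altman agreement |
| `ecgbp.pipeline` | grid orchestration, splitting, minimum-time rule, reports |
| `ecgbp.cli` | `ecgbp` command-line entry point |

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
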