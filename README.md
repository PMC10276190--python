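# eegslope

Wide-band EEG aperiodic (1/f) slope analysis: artifact rejection,
trial-averaged single-taper PSD estimation, aperiodic + periodic spectral
model fitting, sliding-window slope profiling over 4–1000 Hz, and
nonparametric group statistics — together with a synthetic-EEG cohort
generator that provides ground truth for every stage.

## What it does

The power spectrum is modeled in log10-power space as an aperiodic power
law plus Gaussian peaks:

```
log10 P(f) = b − χ·log10 f + Σₙ aₙ exp(−(f − μₙ)² / 2σₙ²)
```

where χ (the exponent or "slope") is positive when power falls with
frequency. The toolkit estimates χ either by the iterative
parameterization (`fit_spectral_model`) or a direct log–log line fit
(`fit_loglog_line`), over fixed bands (LFR 64–140 Hz, HFR 230–430 Hz) or a
sliding grid of 100 Hz windows stepped by 20 Hz with centres 40–960 Hz.
Windows whose endpoints hit a ±4 Hz band around 50 Hz harmonics are
skipped, interior line-noise bins are excluded from fits, and exponents
below 0.01 are recorded as missing.

Modules (under `src/eegslope/`):

| module          | contents |
|-----------------|----------|
| `simulate`      | synthetic cohorts: power-law + peaks + line noise + EMG hump spectra, age-dependent exponents, injectable artifacts |
| `recordings`    | `Recording`/`EpochSet` containers, 10-10 electrode groups, bipolar re-referencing (112-pair table), epoching, EDF + internal-layout IO |
| `preprocess`    | the ordered artifact-rejection pipeline: fixation breaks, impedance > 25 kΩ, 6-SD outlier repeats, 30 %/10 % electrode and common-bad rules, 56–84 Hz slope screen, RMS bounds (1.25/2.5–35 µV), block validation |
| `spectral`      | single-Slepian-taper trial-averaged PSD, dB and linear power-change measures, log-domain group pooling |
| `aperiodic`     | model and line fits, window grid, slope profiles, alpha-peak and knee extraction (`τ = 1/2πf_knee`) |
| `groupstats`    | bootstrap SEM of the median (10 000 iterations), exact/asymptotic Wilcoxon rank-sum, Kruskal–Wallis, ≥3-bin cluster correction, Benjamini–Hochberg FDR, slope-vs-age OLS, case–control matching (gender + age ±1 yr), R² subsample matching |
| `analysis`      | per-subject orchestration: clean → PSD → pool → slopes |

## CLI

```bash
eegslope simulate --out cohort/ --seed 1 --condition eyes_open
eegslope preprocess cohort/S000.dat out/
eegslope psd cohort/S000.dat psd.csv --group high_priority
eegslope slopes cohort/S000.dat slopes.csv --band sliding
eegslope regress cohort/ --band HFR
eegslope convert cohort/S000.dat rec --to edf
```

Recordings are stored either as EDF (16-bit, 0.1 µV/bit) or as an internal
layout (little-endian float32 matrix + JSON sidecar with fs, labels,
impedances, trial onsets and subject metadata).

## Notes

- The generator's age effects (low-range exponent −0.010/yr, high-range
  +0.017/yr, alpha slowing) are configurable inputs; downstream statistics
  are validated by recovering them.
- The 6-SD outlier rule uses a robust (median/pooled-MAD) deviation
  statistic; a plain pointwise mean/SD z is bounded by √(n_repeats−1) and
  cannot detect a lone spike at small repeat counts.
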