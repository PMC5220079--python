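# spectraqc

Exploratory quality control and regression screening for high-resolution
canopy spectral reflectance data, built for plant-breeding trials measured
with full-range field spectroradiometers (350–2500 nm at 1 nm).

## The problem

A breeding campaign scans hundreds of plots, each as *k* replicate sample
spectra, producing matrices of thousands of wavelengths × thousands of rows
that are hopeless to clean by eye in a spreadsheet. Three families of
measurement problems dominate:

* **atmospheric-absorption noise** — water vapour and CO₂ corrupt bands
  near 1350–1400, 1800–1950 and 2350–2500 nm, more widely under humid
  conditions;
* **within-scan inconsistencies** — a replicate sample that drifted onto
  soil, sky or a neighbouring plot because the fibre moved;
* **calibration drift** — a skipped white-reference calibration leaves a
  contiguous block of plots with systematically distorted reflectance.

After cleaning, the exploratory questions are which individual wavelengths
and which spectral reflectance indices (SRIs — arithmetic band
combinations such as NDVI, PRI or WI) track a measured trait, and which
wavelengths carry redundant (collinear) information.

## What the package computes

**Noise filter.** Per wavelength segment (up to ten, each with its own
criteria), the relative change between neighbouring wavelengths
d(λᵢ) = |R(λᵢ) − R(λᵢ₋₁)| / |R(λᵢ₋₁)| × 100 is compared against a maximum
percentage; positions where d exceeds it for *N* or more consecutive
wavelengths are noise. *Group* mode deletes the envelope of flagged
wavelengths pooled over all samples uniformly; *individual* mode cuts each
sample to its own envelope. Negative reflectances can be deleted globally.

**Scan QC.** Per scan and wavelength, the coefficient of variation over
the k replicate samples, CV = s/x̄ × 100 (sample s, n−1). A scan is
flagged when CV exceeds the threshold at any wavelength; individual
samples can then be deleted, leaving empty rows so the block structure
never shifts.

**Outlier loop.** Indices are computed on scan-averaged spectra;
(index, trait) scatter tables are flagged by value range and whole plots
removed — the programmatic form of circling a suspicious data cloud.

**Collinearity pruning.** Wavelengths ranked by simple-linear R² against
the trait; greedily retain the best and discard every remaining wavelength
whose pairwise r² with it reaches the cutoff, with a full audit trail.

**Screening.** Six regression models of trait on predictor — y = p₁x + p₂,
y = p₁x² + p₂x + p₃, the Weibull density form p₁p₂x^(p₂−1)e^(−p₁x^p₂),
y = p₁e^(p₂x), y = p₁ + p₂x^(p₃), y = p₁ln x + p₂ — fitted per wavelength
or per index, reported with SSE, DFE, R², adjusted R² and RMSE, filtered
by a statistic cutoff. The SRI full report shows the best model (highest
adjusted R²) first, then every tested model, over a curated registry of
47 literature indices that users can extend from a plain-text file.

**Synthetic trials.** A seeded generator produces vegetation-like spectra
(red edge, NIR plateau, water-absorption dips) with injectable noise
bands, replicate jitter and calibration-drift blocks, plus a truth log —
every claim in the test suite is checked against injected ground truth.

## Worked example

```python
from spectraqc import (
    TrialSimConfig, simulate_trial, NoiseSegment, apply_noise_filter,
    ScanQCConfig, flag_scans, average_scans, scatter_table, flag_by_range,
    remove_plots, screen_sris,
)

config = TrialSimConfig(
    n_plots=100, seed=1,
    noise_bands=((1800, 1950, 0.5),),   # humid-day absorption noise
    drift_block=(21, 40, 0.4),          # 20 plots after a skipped calibration
    sigma=0.1,
)
dataset, responses, truth = simulate_trial(config)

filtered = apply_noise_filter(
    dataset, [NoiseSegment(350, 2500, max_pct_change=20, n_size=5, mode="group")]
)
print("noise envelope deleted:",
      filtered.report.deleted_from_nm.min(), "-",
      filtered.report.deleted_to_nm.max(), "nm")

qc = flag_scans(filtered.dataset, ScanQCConfig(max_cv_pct=0.5))
print("scans without problems:", len(qc.ok), " with problems:", len(qc.problems))

table = scatter_table(average_scans(filtered.dataset), responses, "NDVI", "Yield")
outliers = flag_by_range(table, "index", "lt", 0.66)   # between the two clouds
print(f"plots flagged by NDVI < 0.66: {outliers[0]}..{outliers[-1]} ({len(outliers)} plots)")
cleaned = remove_plots(filtered.dataset, outliers)

report = screen_sris(average_scans(cleaned), responses,
                     ("poly1", "poly2", "exponential"), adj_r2_cutoff=0.25)
top = report.table.sort_values("best_adjR2", ascending=False).head(3)
print(top[["sri", "best_model", "best_adjR2", "best_RMSE"]].to_string(index=False))
```

prints

```
noise envelope deleted: 1800.0 - 1951.0 nm
scans without problems: 96  with problems: 4
plots flagged by NDVI < 0.66: 21..40 (20 plots)
  sri  best_model  best_adjR2  best_RMSE
MCARI       poly2    0.810310   0.102387
TCARI exponential    0.809277   0.102666
PSSRb       poly2    0.809210   0.102684
```

The group filter localizes the injected 1800–1950 nm noise band to within
1 nm; the replicate-CV check flags 4 of 100 scans at the 0.5 % threshold;
NDVI range flagging recovers exactly the 20 drift-block plots; and after
cleaning, the index screening ranks chlorophyll/greenness indices on top —
as expected for a trait generated from true NDVI.

The same loop is available from the shell via a persisted session whose
step log replays deterministically:

```bash
spectraqc simulate --out-prefix trial --seed 1 --noise-band 1800:1950:0.5 --drift 21:40:0.4
spectraqc init --session work --spectra trial_spectra.csv \
    --responses trial_responses.csv --samples-per-plot 3
spectraqc noise --session work --segment 350:2500:20:5:group
spectraqc scanqc --session work --max-cv 0.5
spectraqc outlier-flag --session work --index NDVI --variable Yield --lt 0.66
spectraqc outlier-remove --session work --plots 21-40
spectraqc sriscan --session work --models poly1,poly2,exponential --adj-r2 0.25
spectraqc replay --session work     # verifies byte-identical reproduction
```

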