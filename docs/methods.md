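# Methods

This note documents the models and procedures implemented in `spectraqc`,
the parameter choices that matter, the design decisions taken where the
procedure was genuinely open, and the limits of what the synthetic-data
tests demonstrate.

## Data model

A `SpectralDataset` is a rows × wavelengths reflectance matrix with three
structural guarantees: wavelengths strictly increasing (files with
shuffled columns are rejected, never silently sorted — reordering hides
format bugs); every row has exactly one cell per wavelength; and the row
count is a multiple of the samples-per-scan count *k*, so consecutive
k-row blocks are scans (plots). A cell is a finite real or missing
(blank on disk, NaN in memory). Two invariants hold across every
operation in the package: filters only ever turn values into missing,
never invent or alter them, and the k-row block structure is preserved —
deleting samples or whole plots leaves empty rows in place, so plot
indices never shift mid-analysis.

Scan averaging is the missing-aware arithmetic mean over the k samples
per wavelength (missing when all k are missing). All index evaluation and
screening operates on these averages; per-sample screening is
deliberately out of scope, which also forces the cleaning steps to come
first.

Exports mirror the input layout. Floats are written with `repr`, so a
load→export→load cycle is a fixed point (byte-identical re-export) — the
property the CLI's replay check relies on. The "exclude empty" export
drops a wavelength column only when it is missing in *every* exported
row; dropping on any-missing would destroy the per-sample results of the
individual noise filter.

## Noise filter

For a sample spectrum r and wavelength index i, the neighbour change is

    d_i = |r_i − r_{i−1}| / |r_{i−1}| × 100 .

The previous (lower) wavelength serves as denominator, matching a
left-to-right scan of the signature. If |r_{i−1}| < 1e−12 the change is
defined as +∞ (a jump from zero is maximal relative change) unless r_i is
also ~0, in which case 0. Within a user segment, positions with
d_i > max% are *pct* flags; maximal streaks of at least N consecutive pct
flags are *run* flags. Missing cells break streaks and are never flagged.
Run flags mark the changed positions themselves, not their left anchors —
a conservative choice whose effect vanishes under envelope deletion.

Deletion is by inclusive envelope: group mode pools run flags over all
samples per segment and blanks [min, max] in every sample; individual
mode blanks each sample's own [first, last] run flags. Individual mode
uses one envelope per segment rather than per streak, mirroring
group-mode geometry; with realistic absorption noise the distinction is
minor because flags are dense inside the corrupted band. Segment bounds
are inclusive in nm on the native grid; at most ten segments, pairwise
non-overlapping. Negative-value deletion is an independent global pass
applied after segment deletion. The whole filter is idempotent.

## Scan QC

Per scan and wavelength, CV = (sample standard deviation / mean) × 100
over non-missing replicates, with the n−1 standard deviation (replicate
statistics at k = 3–4). CV is undefined below two values; a non-positive
mean with ≥ 2 values is treated as exceeding any threshold, since CV is
meaningless there and non-positive mean reflectance is itself a symptom.
A scan is a problem when CV exceeds the threshold at any wavelength with
defined CV. All-missing scans are not problems (no evidence) but are
reported separately as empty. Sample deletion blanks rows in place.

## Collinearity pruning

Wavelengths are ranked by simple-linear R² against the response
(descending, ties to the lower wavelength); the procedure repeatedly
retains the top-ranked remaining wavelength and discards every remaining
wavelength whose squared Pearson correlation with it reaches the cutoff.
Greedy best-first pruning was chosen because it directly operationalizes
"keep the wavelengths that best explain the trait", is deterministic, and
is auditable — the audit trail records each discarded wavelength, its
absorber and their pairwise r². Correlations use pairwise-complete
observations; wavelengths with fewer than three complete pairs against
the response, or zero variance, are excluded up front and reported. The
first retained wavelength is always the single best linear predictor.
An artificial-neural-network strategy is declared as an extension hook
(`method="ann"`) and deliberately not implemented: no architecture,
stopping rule or collinearity criterion is defined for it here.

## Regression models

Six single-predictor forms (m = parameter count):

| model | formula | m | solver |
|---|---|---|---|
| poly1 | y = p₁x + p₂ | 2 | exact linear LS |
| poly2 | y = p₁x² + p₂x + p₃ | 3 | exact linear LS |
| weibull | y = p₁p₂x^(p₂−1)e^(−p₁x^p₂) | 2 | damped nonlinear LS |
| exponential | y = p₁e^(p₂x) | 2 | damped nonlinear LS |
| power | y = p₁ + p₂x^(p₃) | 3 | damped nonlinear LS |
| logarithmic | y = p₁ln x + p₂ | 2 | exact linear LS (on ln x) |

The Weibull form is the two-parameter density shape with no amplitude on
y, implemented exactly as written; it can only fit responses on the
density's scale.

Nonlinear fits use Levenberg–Marquardt-style damped least squares
(`scipy.optimize.least_squares`, ftol/xtol/gtol 1e−12, ≤ 500·m residual
evaluations) from deterministic data-driven seeds: exponential from a
log-linear regression of ln|y| on x when y is one-signed, else (ȳ, 0);
power from the log-log slope of (y − min y + ε) against x with the linear
pair (p₁, p₂) solved exactly given the exponent, plus a p₃ = 1 fallback
seed; Weibull from a shape grid {0.5, 1, 2, 5} with the rate seeded as
mean(x)^(−shape). The best of the refined candidates by SSE is kept, and
a fit is never reported with SSE above the best seed's (falling back to
the seed, unconverged, if the optimizer moved uphill). Seeding is
derivative-free and deterministic, so repeated runs are bit-identical.

Statistics: SSE, DFE = n − m, R² = 1 − SSE/SST,
adjR² = 1 − (1−R²)(n−1)/(n−m), RMSE = √(SSE/DFE). The same R² definition
is kept for nonlinear models and may be negative; reports preserve it. A
constant response (SST = 0) gives R² = 0 with a degenerate flag and is
excluded from screening reports. Pairs with a missing member are dropped
listwise per fit; ln/power/Weibull require x > 0 (domain error
otherwise). No confidence intervals or p-values are computed.

## Index registry and evaluation

An index definition is an arithmetic expression (+ − × ÷ and power, plus
numeric constants) over band tokens R⟨nm⟩, compiled through a whitelisted
AST — no other syntax evaluates. The built-in registry carries 47
citation-tagged literature indices (NDVI, SR, PRI, WI, NDWI, SAVI, OSAVI,
MSR, RDVI, SIPI, TVI, MCARI, TCARI, CRI, ARI, MTCI, red-edge and pigment
families, …) plus template constructors for normalized-difference and
simple-ratio forms; user files extend it with one
`name; citation; expression` entry per line. Indices whose published
definitions require logarithms or band interpolation (e.g. NDNI, REP)
are outside the expression grammar and intentionally absent. Where band
choices conflict across the literature, the bands of the cited original
are used.

Bands match the nearest grid wavelength within a tolerance (default 3 nm,
exact-distance ties to the lower wavelength). An unmatched band, a
missing cell or a zero division yields a missing index value — never an
exception — so deletion upstream propagates cleanly into the reports.

## Synthetic trials

The generator emulates the data regime the package targets: 100 plots ×
3 samples on the 350–2500 nm 1-nm grid by default, with per-plot
greenness ~ U(0.4, 0.95) and water status ~ U(0.2, 0.8). The spectrum is
a smooth composition of a visible baseline (higher for senescent
material), a 550 nm green bump, a logistic red edge at 715 nm rising to a
NIR plateau 0.25 + 0.30·greenness, a gentle SWIR decline, and Gaussian
water-absorption dips at 1190/1450/1940 nm deepened by water status,
plus a tiny smooth low-frequency per-plot wiggle. True NDVI is strictly
increasing in greenness; all values stay inside (0, 1); neighbouring-
wavelength changes stay far below any realistic filter cutoff (< 10 %),
so clean spectra never trip the noise rule.

Artifacts are multiplicative by design, so the neighbour-percentage
criterion is scale-free across the spectrum:

* noise bands — i.i.d. per-cell factors uniform in 1 ± amplitude inside
  the band (default amplitude 0.5 where used in tests, the regime of
  strong absorption noise);
* replicate jitter — one scalar factor per sample,
  sd = within-scan CV % (default 0.3 %, a steady-handed operator;
  the 0.5 % QC threshold then flags a realistic few percent of scans);
* calibration drift — a contiguous plot block whose reflectance above
  700 nm is multiplied by a gain (0.4 in tests). The gain is spectrally
  selective on purpose: a flat gain would cancel in every ratio-based
  index, and the phenomenon being emulated — a stale white reference
  under a moving sun — is wavelength-dependent in reality.

The response is y = β₀ + β₁·NDVI_true + N(0, σ) with defaults
β₀ = 2, β₁ = 8, σ = 0.3 (a yield-like trait in t/ha spanning ≈ 2–10).
NDVI_true comes from the *pre-artifact* spectrum, so cleaning can be
shown to recover, never manufacture, the trait signal. One integer seed
fixes every draw; exports are byte-identical across runs.

What passing tests do **not** show about real data: the generator has no
radiative-transfer realism (no PROSPECT/SAIL), no correlated noise
between neighbouring wavelengths, no sensor-junction steps, no
non-multiplicative stray-light effects, and its two latent factors make
the spectra far more mutually correlated than a real trial — collinearity
pruning retains correspondingly few wavelengths. The tests validate the
*logic* of the filters against known injected artifacts, not instrument
physics.

## Sessions and replay

CLI state is a directory: original CSV, current CSV, optional responses,
and an ordered JSON step log. Only dataset-mutating steps (noise
filtering, sample deletion, plot removal) are replayed; report-only steps
are logged with `mutates: false`. Running a step from the original data
resets the log to that single step. The replay contract — re-applying the
log to the original reproduces the current export byte-identically —
holds because every analysis step is deterministic and exports are
`repr`-exact.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full 350–2500 nm 1-nm
grid with 100-plot trials (300 sample rows), the package's own default
study condition; the noise-oracle and collinearity-oracle checks use
1,000 and 100 random small instances respectively. Linear fits agree
with the normal equations to 1e−9 relative; nonlinear convergence is
relative-SSE-change driven at 1e−12; the zero-denominator guard in the
noise rule is 1e−12; band-match tolerance defaults to 3 nm (the original
instruments resample to a 1 nm grid where exact matching is typical).

## Known limitations

* The Weibull model, as printed, has no response amplitude and rarely
  fits trait data; it is included for completeness and excluded from
  reports when unconverged, like any other model.
* Individual-mode noise deletion cuts one envelope per segment, not per
  streak; users wanting per-streak granularity should define narrower
  segments.
* Collinearity pruning is a greedy heuristic: it guarantees the audit
  properties (retained pairs below cutoff, every discard justified) but
  not a globally optimal subset.
* Index screening reports correlational fits only; no multiple-testing
  correction is applied across the hundreds of (index, model, trait)
  combinations, by design — this is an exploratory screen, not inference.
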