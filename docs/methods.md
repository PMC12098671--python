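# Methods

## The analytical problem

Aspirin (ASP) and atorvastatin (ATO) are co-formulated for cardiovascular
prevention and both fluoresce natively in ethanol — ASP at 405 nm (excited
at 285 nm), ATO at 364 nm (excited at 300 nm) — but their emission bands
overlap so heavily that neither can be quantified in the other's presence
by conventional fluorimetry. First-derivative synchronous fluorescence
spectrofluorimetry (FDSFS) resolves the overlap without separation: a
synchronous scan with a constant offset Δλ narrows and simplifies the
bands, and the first derivative of that trace has, for each pure analyte,
zero crossings whose position is independent of concentration. Reading
analyte A at interferent B's crossing yields a response that depends only
on A.

## Spectral model

Each fluorophore is a separable product of Gaussian excitation and
emission bands:

    I(λ_ex, λ_em) = c · B · exp(−(λ_ex−μ_x)²/2σ_x²) · exp(−(λ_em−μ_m)²/2σ_m²)

with concentration `c` (µg/mL) and brightness `B` (AFU per µg/mL at the
band maxima). Mixtures are strictly additive; a flat, small, non-fluorescent
excipient background (2 AFU by default) models the formulation matrix.
Inner-filter and quenching effects are not modelled — concentrations are
assumed to stay inside the validated linear ranges (ATO 0.4–6, ASP
1–10 µg/mL), where the response is linear by construction.

Under this model the synchronous trace of a single fluorophore,
S(λ) = I(λ−Δλ, λ), is itself Gaussian with peak at the precision-weighted
mean

    λ* = [ (μ_x+Δλ)/σ_x² + μ_m/σ_m² ] / [ 1/σ_x² + 1/σ_m² ],

which serves as the closed-form oracle for the slicing geometry throughout
the test suite (agreement demanded to 0.5 nm over randomised band
parameters).

## Default constants and how they were fixed

The band **positions** are the analytes' published excitation/emission
maxima. The literature does not give band widths, relative brightness, or
instrument noise, so these are package constants fixed once by the grid
search in `scripts/tune_defaults.py` (kept in the repository; the frozen
values live in `fluorophores.py` and `simulate.py`):

| constant | value | selection target |
| --- | --- | --- |
| ASP widths (σ_x, σ_m) | 20, 21 nm | ASP's Δλ=80 derivative crossing at 384 nm |
| ATO widths (σ_x, σ_m) | 38.73, 10 nm | ATO's crossing at 365 nm (σ_x = √15·σ_m pins it) and scan argmax at 80 nm |
| brightness ASP / ATO | 100 / 150 AFU·mL/µg | comparable channel amplitudes |
| noise | additive SD 0.15 AFU, proportional CV 0.35% | triplicate quantification %RSD inside 0.3–2.0% (median ≈ 0.7%) |

These tuned defaults are a stand-in for the real spectra, not a claim
about them. The noise level deserves a note: a triplicate's sample RSD is
a χ²₂-distributed statistic with a long upper tail, so the underlying
per-determination CV is centred near 0.7% to keep the n = 3 statistic
reliably below the 2% repeatability limit across seeds.

Default scan grids are excitation 220–500 nm and emission 250–600 nm at
1 nm — wide enough to cover both bands and every offset in the 20–120 nm
scan. Grids are declared, not inferred; instrument exports with
non-uniform axes are resampled linearly on read, with a warning.

## Pipeline

1. **Synchronous extraction** — the diagonal EEM slice at constant Δλ,
   reported on the emission axis (λ_em = λ_ex + Δλ; emission indexing makes
   the 364/405 nm landmarks natural). Off-grid excitation values are
   bilinearly interpolated; at least 20 points of overlap are required.
2. **Derivative** — Savitzky–Golay first derivative, polynomial order 2,
   15-point window by default, scaled to AFU/nm; edges keep full length
   through the filter's polynomial edge fit but are excluded from
   crossing searches. The "data interval of N points" of spectrometer
   software is ambiguous between a smoothing window and a differentiation
   gap; both interpretations are implemented (`derivative_mode:
   savgol | difference`), Savitzky–Golay being the default.
3. **Wavelength selection** — for analyte A, the wavelength minimising the
   worst-case |¹D| of interferent B across a ≥3-concentration panel,
   restricted to wavelengths where A's own |¹D| is at least 30% of its
   maximum (the sensitivity floor), then refined to B's interpolated zero
   crossing when one lies within a grid step. The floor default is 30%
   rather than something looser because, on noiseless Gaussian tails, a
   weak floor admits far-tail wavelengths where the interferent is
   numerically dead but the analyte signal is nearly useless; 30% keeps
   the selection at the crossing with strong analyte sensitivity. The
   sub-grid refinement matters quantitatively: reading half a grid step
   off the crossing leaks interferent signal worth several percent of a
   low-concentration analyte's response.
4. **Calibration** — OLS of signed ¹D amplitude on concentration
   (`SyncDerivCalibration.fit()` → `CalibrationResults`). Amplitudes are
   calibrated signed; negative-slope channels (ATO at 384 nm sits on the
   falling flank) are legal. σ for LOD/LOQ is the SD of intercepts from
   k ≥ 2 replicate curves (k = 3 by default), matching the
   "SD of the y-intercepts of regression lines" convention; with fewer
   replicates it is reported unavailable rather than silently zero.
5. **Quantification** — C = (¹D − intercept)/slope; predictions outside
   the validated range always carry a flag (no silent extrapolation).

## Validation battery

* Percent recovery 100·found/added, acceptance band 98.0–102.0%; %RSD =
  100·SD/mean with sample (n−1) SD throughout — this convention exactly
  reproduces the published standard-addition summary rows (99.35 ± 1.097,
  100.79 ± 1.036). Report rounding is half-up to 2 decimals; internal
  values are never rounded.
* LOD = 3.3σ/|S|, LOQ = 10σ/|S|; the 10/3.3 ratio is an identity and the
  report renderer warns if a report ever violates it.
* Accuracy: 3 × 3 recovery study at 80/100/120% of the assay
  concentrations (ATO 1, ASP 2 µg/mL). Precision: triplicates at three
  levels (ATO 1/2/3, ASP 2/4/6 µg/mL) for repeatability; three re-seeded
  "days" pooled for intermediate precision (day effects are modelled only
  as a per-day seed offset).
* Method comparison: pooled-variance two-sample t (reported unsigned) and
  F = larger/smaller variance, with critical values computed from the t
  and F distributions at 95% confidence, not hard-coded (the classical
  2.306 at df = 8 and 6.388 at (4,4) serve as pinned checks).
* Robustness re-quantifies a fixed mid-range mixture (ASP 6 + ATO
  2 µg/mL) under {−δ, 0, +δ}. The two axes are treated differently, and
  deliberately so: a Δλ change is an instrument setting that applies to
  standards and samples alike, so the procedure (wavelength selection +
  calibration) is re-derived per condition; brightness jitter — the
  in-silico stand-in for small pH/buffer-volume changes, since protonation
  chemistry is not modelled — perturbs the sample only and is read against
  the base calibration. A ±1% brightness jitter therefore propagates
  linearly to exactly 1% RSD, which the tests pin.

## Δλ optimisation

Candidates 20–120 nm are scored as |slope_A| · |slope_B| ·
min(separation, 50 nm), with each slope taken at that candidate's
auto-selected measurement wavelength; ties break toward the smallest
offset, candidates without grid overlap score −∞, and identical analytes
collapse to separation 0 ("unresolvable"). The criterion is a package
choice (the qualitative requirement is only "two well-defined peaks");
with the tuned defaults its argmax is 80 nm.

## Synthetic demo campaign

`run_demo` chains: calibration panels → Δλ scan → zero-crossing
calibration → five-mixture recovery series at the fixed 1:3.75 ATO:ASP
ratio → standard addition on a tablet-like base (base found averaged over
five determinations, each spike over three) → validation report. One
master seed drives everything through fixed per-stage offsets, so reruns
are byte-identical. The method-comparison block compares two
independently seeded simulated assay runs — a synthetic stand-in for a
second (chromatographic) method, whose raw data no simulation can
reproduce — and exercises the t/F machinery rather than making any claim
about a real reference method.

## What the simulation does and does not show

The generator reproduces the statistical structure the analysis relies
on: linear additive responses over the stated ranges, stated band maxima,
heavy spectral overlap, replicate noise at validated-method magnitude, and
a non-fluorescent excipient background. It does not reproduce real band
shapes (true spectra are asymmetric), pH-dependent ASP hydrolysis,
surfactant or solvent effects, inner-filter effects, or instrument drift.
Passing tests therefore demonstrate that the pipeline's arithmetic and
geometry are correct and self-consistent under the model's assumptions —
not that the tuned constants describe the real drugs' spectra.

## Numerical choices and degenerate inputs

* Zero crossings are located by sign change plus linear interpolation;
  flanking-amplitude suppression (`min_flank`) guards against noise
  wiggles; edge-fitted points never produce crossings.
* Wavelength-selection ties break toward the strongest analyte signal;
  scan-score ties toward the smallest Δλ.
* All-zero interferent panels degrade the selection rule to the
  floor-constrained argmax of analyte |¹D|; an all-zero analyte reference
  raises "channels unresolvable".
* Calibration requires ≥ 3 distinct levels; zero slope makes inversion a
  hard error; blank samples predict 0 µg/mL with a below-range flag.
* Every stochastic quantity derives from explicit integer seeds
  (child seeds spawned via `SeedSequence`, kept below 2³¹); noiseless
  paths are exactly deterministic.

## Problem sizes

Default panels are 6 levels × 3 replicates per analyte on a 281 × 351
EEM grid; the offset scan evaluates 11 candidates on 3-level noiseless
panels; the full demo campaign runs in a few seconds on one CPU. These
sizes were chosen to be comfortably instrument-realistic while keeping a
full validation cycle interactive.
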