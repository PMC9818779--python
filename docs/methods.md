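# Methods

This note documents the models, conventions and design choices behind
`cocoanir`, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Data model

Spectra are stored and processed as absorbance, log(1/R). Instruments that
export reflectance are converted at ingest (`load_spectra(...,
reflectance=True)`), since all band interpretation in this domain is done
in absorption terms. Wavelength grids are matched with an absolute
tolerance of 1e-6 nm and CSV output uses 17 significant digits, so dataset
and model round trips are lossless to well below 1e-12.

Reference values may be missing per constituent. A sample lacking a
laboratory value for one trait is excluded only from that trait's
calibration, which is why the retained N varies by constituent in grid
reports.

Range restriction (`restrict_range`) works by exact column selection —
never interpolation — and therefore requires the target grid to be a
subset of the source grid with a step that is an integer multiple of the
source step. Restricting the 3301-point benchtop grid to 900–1680 nm at
2 nm yields exactly the portable 391-point grid, which is how the
"benchtop on the portable range" comparison scenario is produced.

## Preprocessing

Order is fixed: scatter correction first, then derivative. Which order a
given commercial package uses is generally undocumented; fixing
scatter-first keeps the derivative operating on scatter-free signal and is
stated here so results are reproducible.

* **SNV** centers each spectrum and scales it to unit sample SD (n−1
  denominator). It is exactly invariant to per-sample affine scatter
  a·x + b, a > 0.
* **Detrend** removes the least-squares quadratic polynomial in
  wavelength (fitted on a [−1, 1]-scaled axis for conditioning); the
  residual is orthogonal to {1, λ, λ²}. The degree is fixed at 2, the
  standard meaning of detrending after SNV in NIR practice.
* **SNV_DT** is SNV followed by detrend, then re-standardized to unit SD.
  The final rescaling is a deliberate choice: it makes the correction
  idempotent (a second application is a no-op), at the cost of a
  per-sample scalar that a calibration is insensitive to anyway.
* **MSC** regresses each spectrum on a reference spectrum and inverts the
  fitted affine transform. The reference is the mean of the calibration
  spectra (computed before any other processing), frozen in the fitted
  model and reused verbatim for later predictions — predictions must
  never recompute the reference from prediction-set spectra.

**Gap-segment derivatives** follow the 4-digit code `d,g,s1,s2`. The
stencil is a central gap difference, Δ_g(x)[i] = x[i+g] − x[i−g], applied
d times, followed by two centered running means of widths s1 and s2
(width 1 = no smoothing). Even widths use the window [i − s/2,
i + s/2 − 1]. Edges where the stencil is incomplete are truncated rather
than padded, and the retained wavelength sub-grid is reported explicitly;
this keeps wavelength registration symmetric and makes the truncation
testable. Code `0,0,1,1` is the identity.

## Calibration engines

All engines center X column-wise and center y; X is never variance-scaled
globally (NIR absorbance columns share units and comparable scale).

**PLS** is univariate-response NIPALS with per-factor deflation of X and
y. **MPLS** differs in exactly one step: after each factor's deflation,
the residual matrix columns are divided by their per-wavelength residual
SD before the next factor is extracted (the Shenk–Westerhaus
modification, the de-facto meaning of "modified PLS" in NIR calibration
software). Residual columns whose SD falls below 1e-12 are frozen at
scale 1 rather than raised as errors. The accumulated scalings and
deflations are folded back into a raw-coordinate regression vector

    v_a = Π_{j<a} (I − w_j p_jᵀ) D_{j+1}⁻¹ w_a ,   B_k = Σ_{a≤k} q_a v_a

so prediction is always `y_mean + (x − x_mean)·B`. By construction MPLS
with one factor is identical to PLS with one factor (no standardization
precedes the first factor).

**PCR** regresses y on the first k principal-component scores of centered
X via SVD.

Each decomposition yields a full coefficient path B_0..B_k (B_0 = 0, the
mean-only model), making cross-validated factor selection cheap. Two
degenerate situations are distinguished: if y is fully explained before k
factors, the path continues flat (a perfect fit, not an error); if the
covariance is exhausted while y residual remains, requesting more factors
raises an error naming the achievable rank. Loadings are exported
unit-norm with the largest-magnitude element made positive, so serialized
loadings are reproducible.

Factor counts are capped at min(16, n − 6): with ~50 calibration samples,
larger models are overfit regardless of apparent SECV.

## Evaluation

* **Cross-validation**: seeded 5-fold; folds are a seeded permutation
  split into parts differing in size by at most one. The default seed is
  20221220 — arbitrary but fixed, so published runs are bit-reproducible.
* **Factor selection**: the smallest k whose SECV is within 2% of the
  minimum SECV over the path (parsimony rule); ties break toward fewer
  factors and the choice never exceeds the argmin.
* **Metrics**: SEC uses calibration degrees of freedom (N − 1 − k); SECV
  uses (N − 1). R² is 1 − SSE/SST (not a squared correlation), clamped to
  [0, 1]. RPD = SD/SECV; a perfect CV fit (SECV < 1e-12) is guarded with
  ε and flagged rather than reported as infinity.
* **Outlier rule**: samples whose cross-validated residual exceeds 2.5
  residual SDs (T statistic) are removed; at most two elimination passes,
  then the model is re-selected, refit and re-cross-validated on the
  retained set. Culling happens before the final CV (cull-then-final-CV);
  whether the alternative (culling inside each fold) is meant by common
  practice is ambiguous, so the simpler convention is fixed and
  documented. All removed sample ids are retained in the report.
* **Interpretation bands**: R²cv ≥ 0.91 excellent, ≥ 0.82 good, ≥ 0.66
  approximate, else poor; the conventional band definitions leave the
  gaps 0.81–0.82 and 0.90–0.91 unassigned, which resolve downward here,
  while 0.91 itself is excellent (matching how the thresholds are applied
  in the literature this package follows). RPD > 2.5 adequate, < 1.5
  unsatisfactory, otherwise intermediate.
* **iPLS**: the grid is split into 30 contiguous equal intervals
  (remainder points joining the last: 391 points → 29 × 13 + 14). Step 1
  cross-validates one model per interval and selects the RMSECV minimum —
  this step is checked against an exhaustive independent loop in the
  tests. Forward continuation greedily adds the interval that most
  reduces RMSECV, stopping when no addition improves it; `steps=1`
  reproduces the single-step variant.
* **Grid search**: 3 scatter modes × 3 derivative codes = 9 cells; each
  cell runs treat → select factors → CV → cull → refit → metrics; the
  winner minimizes SECV.

## Wet-chemistry arithmetic

Only assay arithmetic is implemented, with the standard constants:
protein = 6.25 × Kjeldahl N; FI = A₄₆₀/A₅₃₀ with well-fermented strictly
above 1; TA = M·V·(extract/aliquot)·(100/powder), which is 4·V at the
default geometry (0.05 M NaOH, 25 mL aliquot of a 5 g / 100 mL extract),
with % acetic acid as a secondary unit (60.05 g/mol, 1:1); DM = 100 −
moisture with moisture from loss on drying. The Folin–Ciocalteu dilution
factor is fixed from the assay geometry — 0.1 mL extract brought to 4.6
mL assay volume (3 mL water + 0.5 mL reagent + 1 mL Na₂CO₃), 0.05 g
defatted powder in 10 mL extract — giving TPC (mg GAE/g) = 9.2 × C(mg/L);
this is the single place that inference is made. TPC is expressed per
as-weighed defatted powder (a dry-mass correction of the extract basis
would need data the assay record does not carry).

## Synthetic data generator

The generator emulates a ~56-sample commercial cocoa-bean study.
Constituent tables are drawn from a correlated normal truncated to
realistic bounds, with marginal means/SDs matching typical commercial
beans (fat 44.7 ± 1.9 %, protein 13.9 ± 1.1 %, dry matter 94.5 ± 0.6 %,
TPC 56.4 ± 13.3 mg/g, pH 5.58 ± 0.36, TA 17.2 ± 4.2 mmol/100 g, FI 1.29
± 0.49, ash 2.99 ± 0.30 %, shell 13.3 ± 1.5 %). Default correlations:
fat–TPC −0.3 (phenolics concentrate in the non-fat solids) and TA–pH
−0.6; all other pairs independent.

Spectra are linear Beer–Lambert mixtures of Gaussian bands on a smooth
baseline. Band centers follow standard NIR assignments: lipid C–H
overtones at 1210/1725/1744/2320 nm, water O–H at 1450/1930 nm, protein
N–H at 1500/2057/2130 nm, carboxylic-acid combination bands at
940/1106/1395 nm, phenolics at 1420 nm, with a carbohydrate background
driven by the non-fat-solids remainder (100 − fat − protein − ash −
moisture). Traits without a direct absorber (pH, ash) receive weak
effective proxy bands standing in for the indirect associations real NIR
calibrations exploit. Intensities were chosen once from signal-to-noise
reasoning — multi-band traits (fat, protein, water) several times above
the noise floor, single weak overlapping bands for TPC and FI so those
traits are intrinsically hard — and widths so the simulated spectra show
the smooth broad-band structure of real cocoa spectra. They are tunable
configuration, not claims about true cocoa extinction coefficients.

Ground mode adds only i.i.d. noise (0.002 AU). Whole-bean mode applies
per-sample multiplicative (SD 0.15) and additive (SD 0.05) scatter, a
random wavelength slope (SD 0.02), a broadband shell-interference
component proportional to each sample's shell fraction, and 3× noise
(0.006 AU) — emulating intact-bean spectra where the shell reflects
light before it reaches the nib. All draws come from named
counter-independent streams of one global seed, so adding a constituent
never perturbs the others, and the bundled fixture is bit-reproducible.

What passing tests show — and what they do not: recovery on this
generator demonstrates that the pipeline is correct and that its
qualitative orderings (ground beats whole; multi-band traits beat
single-band traits; scatter correction helps when scatter dominates)
emerge for the right reasons. It does not certify accuracy on real cocoa
spectra, whose scatter physics (particle size, packing, detector
response) is far richer than an affine model plus one broadband
interferent.

A note on scatter-correction efficacy: with ~56 samples a multi-factor
PLS model absorbs most affine scatter by spending factors on it, so
NONE-treatment performance degrades only mildly at that size. The
efficacy property (scatter-corrected cells beating NONE by a wide margin
on scatter-planted data) is therefore demonstrated in a scatter-sensitive
regime of 20 calibration samples, where the factor budget cannot cover
the scatter subspace.

## Problem sizes

Default test and acceptance runs use the bundled 56-sample fixture; the
expensive shared computation is the 9-cell grid search per constituent
per preparation mode on the 3301-point benchtop grid, chosen as the
smallest configuration that exercises the full pipeline at study scale.

## Known limitations

* The affine + broadband scatter model is a first-order emulation; no
  radiative-transfer or particle-size physics.
* iPLS forward continuation uses strict RMSECV improvement as its
  stopping rule, which on noisy data can accept many marginal intervals.
* MPLS is one member of a family of "modified PLS" definitions; only the
  residual-standardization variant is implemented.
* External test-set validation is out of scope; all validation is
  cross-validation.
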