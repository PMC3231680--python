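# Methods

## Retrieval model

The package estimates two biophysical variables from canopy reflectance:

- **Green LAI** (m²/m²) from a normalized difference index,
  `NDI(a, b) = (R_b − R_a)/(R_b + R_a)`, calibrated by regression through
  the origin, `LAI = s·NDI`. The through-origin form is deliberate: bare
  soil produces a near-zero red-edge NDI and zero LAI, so the data anchor
  the origin and an intercept would only absorb soil-background noise. The
  slope estimator is the least-squares solution `s = Σxy/Σx²`; its standard
  error is reported from the residual variance.
- **Leaf chlorophyll Ch** (µg/cm²) and **canopy chlorophyll Ch·LAI**
  (g/m²) from the Normalized Area Over the reflectance Curve,
  `NAOC = 1 − ∫ₐᵇ R dλ / (R(b)·(b−a))` with a = 643 nm, b = 795 nm. Ch uses
  a linear calibration; Ch·LAI uses `A·exp(k·NAOC)`. Canopy chlorophyll is
  the product of leaf chlorophyll and LAI converted at the boundary:
  µg/cm² × (m²/m²) × 0.01 = g/m².

Pearson r is reported beside every fit: between index and response for the
proportional/linear forms, and between index and ln(response) for the
exponential form (which is fitted in the log domain; see below). Since
Pearson r is invariant under affine maps, r(predictions, response) equals
the stored r for the proportional and linear forms.

## Band-pair optimization

`optimize_ndi` computes Pearson r between NDI(a, b) and the target for
*every* ordered pair of candidate bands in the search window and returns
the full antisymmetric correlation surface plus the pair maximizing |r|,
reported in the r > 0 orientation with ties broken toward the smallest a,
then smallest b. Pairs whose NDI has zero variance (or an undefined value
from a zero denominator) are marked undefined and excluded from the
argmax. Plain Pearson r of the index itself is used as the search
criterion — for a through-origin linear calibration the |r|-optimal pair
is the same under either convention, and the surface is returned so users
can apply any other criterion.

Under the built-in simulator the LAI-optimal pair anchors one band in the
chlorophyll absorption (650–690 nm) but prefers a *short*-wavelength
partner (~620–645 nm) over a red-edge partner: a red-edge band adds
chlorophyll sensitivity, which behaves as noise when the target is LAI.
On real crop spectra the optimum is typically an absorption/red-edge pair
such as (674, 712) nm; that pair also scores highly here (r within a few
percent of the optimum), but users should expect the exact argmax to be
data-dependent.

## NAOC numerical scheme

- The reflectance curve is reconstructed by **linear interpolation between
  band-centre nodes lying inside [a, b]**, held constant from the outermost
  node to the integration limits. For the Sentinel-2 set the nodes are B4,
  B5, B6 and B7 (665–783 nm), so constant extension covers 643–665 nm and
  783–795 nm. This is the least-assumption closure of the window; bands
  just outside the limits (B3 at 560, B8 at 842 nm) are intentionally not
  used as nodes.
- R(b) is the reconstructed curve evaluated at b — not a windowed maximum.
- Integration is the composite trapezoid rule on a uniform grid
  (`sample_step`, default 1 nm). The rule is exact for a piecewise-linear
  curve whose nodes lie on the grid; a convergence test (1 nm vs 0.1 nm)
  guards the default.
- Pixels with R(b) ≤ 0 are masked and counted, as are NDI pixels with a
  zero denominator: 0/0 carries no information, so masking is preferred to
  imputing 0.
- The red-edge ablation (`naoc_bandset_variants`) recomputes NAOC with
  nodes {B4, B5, B6, B7} and with {B4, B7} only, under identical limits,
  grid and extrapolation, so the difference isolates the red-edge bands.

## Spectral resampling

Broad bands are synthesised as SRF-weighted means of the source samples
inside the band support — a discrete convex combination, so constants are
preserved exactly and resampling is linear in the input. Two SRF shapes
are available:

- **boxcar** (default): uniform over [centre − width/2, centre + width/2].
  Chosen as the default because official response curves are out of scope
  and the boxcar is exactly testable (a linear ramp resamples to its value
  at the band centre).
- **gaussian**: FWHM equal to the band width, truncated at ±2·FWHM.

A band whose support contains fewer than two source samples raises a
coverage error naming the band; `covered_bands` subsets a sensor to the
bands a given cube can support (a 400–1000 nm cube covers Sentinel-2
B1–B9 but not the SWIR bands).

Reflectance outside [0, 1] is retained — atmospheric correction routinely
produces slight negatives, and clipping would bias the indices — but
counted and logged. Only NaN marks missing data.

## Synthetic scenes

The simulator provides field-structured scenes with exactly known truth:

| parameter | default | meaning |
|---|---|---|
| grid / fields | 40×50 px, 40 fields | rectangular fields, per-field LAI and Ch |
| `lai_range` | (0, 6) m²/m² | span of field LAI draws (uniform) |
| `ch_range` | (10, 60) µg/cm² | span of field chlorophyll draws (uniform) |
| `soil_fraction` | 0.15 | fraction of fields set to bare soil (LAI = 0) |
| `jitter` | ±10 % | within-field pixel variability of LAI and Ch |
| `noise_sd_additive` | 0.005 | i.i.d. Gaussian reflectance noise per band |
| `axis` | 400–1000 nm @ 1 nm | output wavelength grid |

Spectra are built from three closed forms: an exponential-absorption leaf
model `R_leaf = 0.05 + 0.45·exp(−Ch·ε(λ))` with
`ε(λ) = 0.06·G(670, 40) + 0.03·G(500, 30)` (unit-height Gaussians, σ in
nm), a linear soil ramp `0.10 + 0.00025·(λ − 400)` clipped to [0, 0.45],
and gap-fraction mixing `R = f·R_leaf + (1−f)·R_soil` with
`f = 1 − exp(−0.5·LAI)`. All draws flow from one seed in a fixed order
(field LAI, field Ch, soil selection, LAI jitter, Ch jitter, noise), so
scenes are bit-reproducible.

**What the simulator does and does not emulate.** It produces the
qualitative structure the pipeline needs — a chlorophyll absorption at
670 nm, a Ch- and LAI-driven red edge, an NIR plateau, field-block truth —
but it is not a radiative-transfer model: no multiple scattering, BRDF,
atmosphere, or band-correlated noise. Two consequences matter for
interpreting tests:

1. Because every spectrum is an affine function of the cover fraction
   `f = 1 − exp(−0.5·LAI)`, *every* NDI is a saturating (Möbius) function
   of LAI. A through-origin linear LAI calibration over the full 0–6 range
   therefore carries an irreducible lack-of-fit here (held-out RMSE ≈ 1
   LAI unit at the default noise), noticeably worse than what the same
   method achieves on real crop data, where increased NIR scattering with
   LAI keeps the red-edge NDI more linear. Passing pipeline tests show
   correctness of the computation, not field-level accuracy.
2. NAOC increases strictly with LAI at fixed Ch and with Ch at fixed
   LAI > 0, and tracks Ch·LAI strongly (rank correlation ≳ 0.93 on
   noiseless scenes) — but not perfectly, because the soil background
   makes NAOC a two-variable function. Sparse, chlorophyll-dense canopies
   (high Ch, LAI ≈ 0.5, "kiwi-like") depress NAOC despite maximal leaf
   chlorophyll, which is exactly why the canopy-level product Ch·LAI, not
   leaf Ch, is the right regressand for the exponential calibration.

## Fitting choices

- The exponential calibration is fitted by **OLS on ln y** rather than
  nonlinear least squares: closed-form, deterministic, and adequate for a
  single-curve calibration. This weights relative (multiplicative) errors,
  which matches the lognormal-style scatter of canopy chlorophyll; a
  nonlinear refit would weight absolute errors instead.
- Validation reports RMSE, bias and Pearson r (r only when n ≥ 3), with an
  optional per-class breakdown keyed on the truth table's `class_label`.
  Points are compared pixel-wise by default; aggregate your truth table
  beforehand if plot-level means are wanted.
- Map-vs-map agreement uses jointly unmasked pixels only and returns the
  paired values for scatter plotting.

## Known limitations

- No saturation handling above LAI 6; the proportional LAI calibration is
  only meaningful where the index remains unsaturated.
- NAOC on very coarse band sets depends on the constant-extrapolation
  closure at the window edges; with only two nodes (the B4+B7 ablation)
  the "curve" is a chord and the index is biased low over convex red
  edges — that bias is the phenomenon the ablation experiment measures.
- The ENVI reader supports float BSQ/BIL with a `wavelength` header field;
  it is not a general ENVI implementation.
- Presets apply published coefficients verbatim; they are appropriate for
  sensors and conditions matching their original calibration and are
  exposed mainly so map production and unit handling can be tested without
  refitting.
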