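# Methods

This note records the scientific and numerical choices behind `stromap`:
what each stage computes, the parameters that matter, what the synthetic
phantoms do and do not emulate, and the limits of what passing tests show.

## Elastic pressure model

Total tissue pressure (TTP, mmHg) is decomposed into interstitial fluid
pressure (IFP) and a solid stress stored by stromal elements. Hyaluronan
(HA) exerts a constant swelling stress `SS_swell` (electromechanical
repulsion plus osmotic imbibition); collagen elastically confines it. With
collagen and HA as springs in series under that load, the transmitted
stress is `SS_swell/(1 + [HA]/[C])`, giving

    TTP = SS_swell / (1 + [HA]/[C]) + IFP .

`[HA]` and `[C]` are ROI area fractions; only their ratio enters, so the
units (percent vs proportion) cancel and the implementation works on the
ratio internally. The form is algebraically identical to the saturating
curve `SS_swell·[C]/([C]+[HA])` — a property test asserts this over random
inputs. Zero collagen leaves the ratio undefined and is rejected;
generator code that must handle a collagen-free ROI uses the analytic
ratio→∞ limit (TTP = IFP).

**Fitting.** `SS_swell` is the only free parameter; IFP is held at the
mean of the measured IFP values (one IFP probe per tumor is the expected
design; a per-tumor IFP can be supplied instead by fitting per tumor).
The fit maximizes the coefficient of determination R² of predicted vs
observed TTP by bounded scalar search on [0, 1000] mmHg with an absolute
tolerance of 0.01 mmHg, recording the search trace. R² is quadratic-like
and unimodal in `SS_swell` (the model is linear in it), so a bracketed
1-D search is exact in practice; if the optimum lands at the upper bound
the bracket is doubled (up to 8 times) before reporting. Noiseless
synthetic data are recovered exactly (R² = 1); at n = 24 observations and
10 mmHg Gaussian reading noise, the median recovery error over 100
replicates is below 10 mmHg.

**TTP maps.** A calibrated linear TTP-vs-collagen regression is applied
per tile on a grid of ~100 µm tiles. A tile's collagen fraction is the
percent of its *tumor* pixels that are collagen (tumor-restricted
denominator, consistent with ROI handling at tumor edges); tiles with
under 50% tumor coverage are flagged undefined (NaN). The map is a model
projection, not a measurement: it inherits all uncertainty of the
regression it is fed.

## Stain segmentation

- Masson's Trichrome (collagen, blue): HSV gate with hue ∈ [0.6, 0.7],
  saturation ∈ [0.7, 1], value ∈ [`v_min`, 1], inclusive endpoints, hue
  normalized to [0, 1). The value gate's printed upper bound is 1; a
  strict `V = 1` would select almost nothing in real scans, so the lower
  bound is exposed as `v_min` (default 0, i.e. value effectively
  unconstrained). Achromatic pixels get hue 0 and fail the saturation
  gate.
- HABP-1 (hyaluronan, brown): red dominance, `R > 2G` and `R > 2B`
  (strict), after white-background subtraction (all three channels above
  220 by default).
- Lectin (patent vessels): single-channel intensity strictly above a
  user threshold.

These are the original study's rules, deliberately simple; no color
deconvolution or stain normalization is attempted. Segmenters are checked
for exact agreement against a per-pixel brute-force oracle on random
images, and for ≥ 99.9% round-trip agreement on rendered phantoms.

## Registration

Serial sections are aligned by a conformal similarity transform (uniform
scale, rotation, translation — reflections excluded) estimated in least
squares from 5–8 manually matched control points via the closed-form
Umeyama solution (scikit-image backend). Estimation is exact on noiseless
data from ≥ 2 non-coincident pairs and equivariant under joint rotation of
both point sets. Masks are warped with nearest-neighbour interpolation so
binarity — and hence downstream area fractions — is preserved; a warp +
inverse-warp round trip retains ≥ 98% of pixels (resampling loss only).

## ROI quantification

A probe site's ROI is a square window of side 0.5/1/1.5/2 mm (1–4× the
0.47 mm sensor diameter), rounded to an odd pixel count so it centers on
the site pixel, clipped at image bounds (a warning is logged when > 10%
is clipped). The introducer-needle track is excluded as a disk of 640 µm
diameter by default (nominal 23-gauge outer diameter; configurable). Note
that at the smallest (0.5 mm) ROI this default excludes almost the whole
window, leaving only its corners — the 1 mm ROI, where the exclusion
removes about a third of the window, is the default reporting size. Area
fractions are percentages of analyzable pixels (window minus track,
optionally restricted to the tumor outline); verteporfin uptake is the
arithmetic mean intensity over the same support. All four ROI sizes are
reported by default since no single size is canonical.

## Texture metrics

Entropy and uniformity need a distribution of local collagen fractions V.
The estimator tiles the ROI into non-overlapping square sub-windows
(default 32 px ≈ 64 µm; partial tiles dropped; at least 16 complete tiles
required), computes V per tile, and histograms V into 64 equal bins on
[0, 1] (the top bin closed). Entropy is reported in bits with the
0·log 0 = 0 convention. Both tile size and bin count are configurable and
recorded in output metadata; absolute entropy values depend on them, so
only comparisons at fixed settings are meaningful.

The box-counting fractal dimension uses box sides e = 2, 4, 8, … up to a
quarter of the window side, counting boxes containing ≥ 1 collagen pixel
on a grid anchored at the window origin; incomplete edge boxes are
dropped so every count has full-box support (including partial edge boxes
demonstrably flattens the slope). D is the least-squares slope of log N
vs log(1/e); the fit R² is reported so scaling quality can be judged.
Oracles: filled square → 2.00, one-pixel line → 1.00, depth-4 Sierpinski
carpet at its native 81-px grid → 1.892 (analytic log 8 / log 3 = 1.8928),
all within ±0.05. A depth-4 carpet *upsampled* to a larger grid is
deliberately not used as an oracle: below the upsampled cell scale the
set is locally space-filling and the measured slope inflates toward 2 —
a generic pre-asymptotic artifact of box counting on fat sets.

## Statistics

OLS regressions report slope, intercept, R², and the two-sided t-test
p-value for the slope under the no-correlation null (scipy backend,
verified against explicit normal equations to 1e-10; null p-values are
uniform by KS test). Power-law fits regress ln y on ln x — natural
logarithms throughout — with the exponent as slope and prefactor
exp(intercept); non-positive inputs are rejected with the offending
indices listed. Group comparisons use Welch's unequal-variance t-test
with Satterthwaite degrees of freedom, two-sided (the analyses here never
pre-specify a direction); its type-I error at α = 0.05 is calibrated to
[0.04, 0.06] over 10⁴ null simulations. The collagenase analysis reports
per-tumor percent TTP change 100·(post − pre)/pre and compares
treated/untreated verteporfin residuals against a fit calibrated on the
untreated group (positive residual = uptake above the untreated trend).
Regressions can pool per-site values or collapse to per-tumor means;
tumor means are the default convention.

## Synthetic phantoms

The generator produces co-registered multi-stain sections with ground
truth, emulating the *statistical structure* the analysis assumes — not
photorealistic histology (no nuclei, no H&E channel, no staining
artifacts, no section deformation).

**Geometry and fields.** The tumor is a harmonically perturbed ellipse
filling ~90% of the frame. The collagen density field is a Gaussian
random field with isotropic power-law spectrum S(k) ∝ k^−β, with
β = 3.5 − 1.5·complexity: rougher spectra (higher complexity) add
fine-scale perforation at all scales, which raises both the entropy and
the measured box-counting dimension of the thresholded mask monotonically
in expectation — a single-scale smoothed-noise field does *not* have this
property (its finer speckle saturates the large boxes and D falls). The
threshold is found by bisection so the mask's tumor-interior area
fraction hits the configured target within 2 percentage points. HA pools
are disks (default radius 75 µm, ±30% jitter) placed uniformly inside the
tumor at a count matching the HA target fraction; with probability
`encapsulation` a pool is ringed by a 40 µm collagen annulus. Collagen
and HA masks are disjoint (pools carve collagen out). Many small pools —
rather than few large ones — keep the ROI-scale HA fraction close to its
target everywhere, which is what makes site-level TTP essentially
uncorrelated with HA area alone while strongly correlated with collagen,
the structure the real data exhibit.

**Pressure-coupled channels.** A per-pixel modelled TTP field is computed
from ~250 µm local averages of the masks via the elastic model (local
collagen floored at 1% to keep the ratio defined). Patent vessels are
small ellipses (~15 µm) whose placement is accepted with probability
exp(−(TTP − IFP)/60 mmHg) — high-pressure regions are vessel-poor.
Verteporfin intensity is I₀·exp(−TTP/τ) with I₀ = 100, τ = 40 mmHg plus
mild Gaussian noise — a monotone inverse relation chosen without
asserting the (unknown) real functional form. Per-site records apply the
model to the ROI-local ground-truth fractions and add Gaussian reading
noise (default 5 mmHg); IFP is recorded at the first site only (single
IFP probe per tumor).

**Rendering.** MT and HABP channels are rendered from 64-color palettes
per tissue class chosen strictly inside (collagen: hue 0.62–0.68,
saturation 0.75–0.95, value 1) or outside (pale pink tissue, white
background) the segmentation gates, with margins that survive uint8
quantization — so segmentation recovers the truth masks exactly, and
area-fraction round trips hold to well under 0.5 percentage points.
Fluorescence channels render as bright foreground over a dim noise floor
that a mid-range threshold separates cleanly.

**Defaults as study conditions.** 2048×2048 px at 2 µm/px (≈ 4 mm
section — the real tumors were 5–15 mm; the scan resolution at "10×" is
unstated, so 2 µm/px is a configurable choice); 3 TTP sites per tumor,
one with IFP, ≥ 2 mm apart (the study spaced sites ~4 mm on larger
tumors); collagen target 30%, HA target 12%, complexity 0.5,
encapsulation 0.5; model parameters SS_swell = 170 mmHg, IFP = 10.9 mmHg
(the fitted values reported for the original data) with 5 mmHg noise.
All randomness flows from one seed; identical seeds reproduce phantoms
byte-for-byte after encoding.

**What passing tests show — and not.** Round trips prove the pipeline's
bookkeeping (geometry, counting, units) is exact, and recovery tests
prove the fitting machinery inverts the generative model under realistic
noise. They cannot validate the biological model itself, segmentation
robustness to real staining variability, registration of genuinely
deformed serial sections, or absolute texture values on real scans.

## Cohort experiments

The acceptance suite simulates a 20-tumor cohort whose collagen targets
span 10–45% (the across-tumor range of desmoplastic xenografts) at fixed
HA target, then checks the qualitative structure of site-level readouts:
TTP rises with collagen fraction (r ≈ +0.8), is weakly related to HA area
alone (|r| ≈ 0.3), and falls with patent-vessel fraction and verteporfin
uptake. Sizes were chosen so the full suite runs in a couple of minutes.

## Known limitations

- Registration assumes supplied control points; no automatic feature
  detection.
- The needle-track exclusion uses a nominal disk, not the actual track
  geometry; at the 0.5 mm ROI it dominates the window.
- The viscoelastic (time-dependent) behavior of tissue is out of scope;
  only the final algebraic form of the elastic model is used.
- Phantom pressure "measurements" are the model plus noise by
  construction, so model-fit R² on phantoms is optimistic relative to
  real data.
- Box-counting D on finite binary masks is pre-asymptotic; values are
  comparable only at fixed window and box-size scheme.
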