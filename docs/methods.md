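# Methods

## The measurement problem

Chronic myocardial scar can be imaged without contrast agents by exploiting
the rotating-frame relaxation time T1ρ: under a spin-lock pulse of duration
TSL, magnetization decays as `S(TSL) = S0·exp(−TSL/T1ρ)`, and fibrotic scar
relaxes roughly twice as slowly (≈92 ms) as healthy myocardium (≈47 ms) at
3 T. This package quantifies scar from multi-TSL magnitude image stacks:
relaxation-time maps, infarct size as a fraction of the endocardial
perimeter, transmurality on a chord grid, mass, and contrast-to-noise,
together with the agreement statistics used to compare measurement methods.
Because no raw in-vivo data are available, all validation runs on a digital
LV phantom whose ground truth is known analytically.

## Phantom model

Each of `n_slices` identical short-axis slices contains a circular blood
pool (radius = endocardial radius, default 20 mm), an annular myocardium
(epicardial radius 30 mm), and background air, on a 192×192 grid at 0.64 mm
with 2.6 mm slices — a high-resolution 3 T cardiac protocol. The infarct is
a sector of the wall: an angular arc (default 21.1% of 360°) with a
per-angular-bin transmural depth profile in [0, 1] measured from the
endocardium, so partial-thickness (non-transmural) border arcs are a first-
class configuration. Optional non-uniform bin edges let arc boundaries be
placed exactly (used to align them with chord-wedge boundaries).

Partial volume is modeled by rasterizing the geometry on a grid supersampled
in-plane by `supersample_factor` (default 4; 8 for volumetric accounting)
and block-averaging to per-voxel tissue fractions; voxel signal is the
fraction-weighted sum of the tissue decays. Supersampling is in-plane only:
the geometry is a prism, constant through each slice, so through-plane
supersampling would change nothing. The majority tissue gives a crisp label
volume; contours are closed counterclockwise polygons (360 vertices) at
pixel-center coordinates. All `true_*` quantities (volumes, perimeter
fraction, non-transmural share) are closed-form functions of the
configuration, never read back from the raster — voxel-count volumes
converge to them as the supersampling factor grows (within 1% at factor 8).

Tissue constants: T1ρ 91.7 ms (infarct) and 47.2 ms (remote myocardium) are
the reported chronic-infarct swine values this package is benchmarked
against. Blood (150 ms) and background are **placeholders** chosen only to
reproduce the qualitative brightness ranking blood > infarct > myocardium on
T1ρ-weighted images; no literature values at 3 T were adopted. The signal
model is pure mono-exponential rotating-frame decay at a single spin-lock
amplitude (500 Hz, metadata only): no T1/T2 recovery terms, no dispersion
with ν₁, no Bloch-level spin-lock artifacts, no motion or coil sensitivity.

Noise is Rician by default — the magnitude of the signal perturbed in two
independent Gaussian receiver channels of SD σ (default σ = S0/50, i.e.
SNR 50) — with a clipped-Gaussian alternative retained for analytic tests.
In air the model reduces to a Rayleigh distribution with mean σ√(π/2),
which is how σ is re-estimated from the background at analysis time.
A simulated "reference modality" image (scar bright, myocardium nulled,
blood intermediate) stands in for the contrast-enhanced comparison arm in
agreement analyses; it is synthetic plumbing, not a contrast-agent model.

## T1ρ fitting

The primary estimator is bounded nonlinear least squares in linear signal
space on `(S0, R = 1/T1ρ)`, initialized from the closed-form log-linear
regression. Magnitude noise is heteroscedastic and biased in log space, so
log-space regression is kept only as initializer and as an independent
oracle (the two agree to 1e-6 relative on noiseless decays, which the test
suite enforces). T1ρ is constrained to [1, 1000] ms; a pixel whose fit
lands on a bound, whose signal never decays, or is nowhere positive is
marked invalid with a reason — never clamped into validity. R² is
1 − SS_res/SS_tot on the fitted points.

Two implementations share this model: `fit_monoexp_pixel` (scipy
trust-region least squares, the reference path) and the vectorized
Levenberg-damped Gauss–Newton used by `fit_map`, which fits the ~10⁵ pixels
of a full stack in well under a second; the suite cross-checks them to
1e-6 relative. At SNR 50 with the 5-point TSL schedule the region-mean bias
is below 1% (Rician floor effects dominate; at lower SNR the bias grows).

## Chord segmentation

Each slice's myocardium is partitioned into 20 circumferential wedges (18°)
and 5 radial sections about the cardiac centroid. Decisions where the
procedure is underdetermined:

- the centroid is the **epicardial polygon's area centroid** (shoelace);
- transmural depth is measured along the centroid ray between the polar-
  interpolated endocardial and epicardial radii; section = floor(5·d)+1,
  with d clamped into [0, 1) (clamps are tallied, not silent) — section 1
  is subendocardial, so "mid-myocardium" is literally sections 2–4;
- wedge 1 starts at a configurable reference angle (default 0° = +x,
  counterclockwise); no anatomical anchor is imposed.

Sector tables report per-sector mean signal normalized to the table
maximum, plus the mid-myocardial per-wedge profile.

## Infarct metrics

Where operators traced scar manually, this package substitutes an explicit,
logged rule so results are reproducible: infarct ⇔ value > remote mean +
k·SD (default k = 5) on the T1ρ map, with FWHM and fixed-threshold
alternatives; the remote reference region is the myocardial arc opposite
the infarct (width 60° by default), standing in for an operator's remote
ROI.

**Size** is the infarct-adjacent fraction of the endocardial perimeter:
a contour segment is infarct-adjacent when the majority of classified
pixels in the innermost radial section within its angular span (widened to
≥ 3° so sub-pixel segments see a few pixels) are infarct; lengths are
summed over all slices before the ratio is taken.

**Transmurality** works per (slice, wedge): a radial section is infarcted
at ≥ 50% classified pixels; a wedge is infarct-containing if any section is
and transmural if all five are. The perimeter ratio uses endocardial arc
length of transmural vs infarct-containing wedges. The non-transmural
infarct volume fraction counts classified voxels within infarct-containing
wedges only: isolated above-threshold voxels in otherwise clean wedges are
almost always blood partial-volume at the endocardial border (blood's long
T1ρ mimics scar) and counting them as "non-transmural scar" inflated the
fraction by 3–4 points even noiselessly. This accounting keeps the
wedge-based definition self-consistent.

**Mass** is voxel count × voxel volume × 1.06 g/mL (fractional,
partial-volume-weighted counts allowed); infarct + remote mass equals LV
mass exactly. **CNR** is (mean infarct − mean remote)/σ, measured on the
longest-TSL image with σ estimated from the air background by the Rayleigh-
mean relation.

## Agreement

Bland–Altman uses sample (n−1) SD and fixed 1.96 limits; correlation is
OLS with r² the squared Pearson coefficient; the two-way ANOVA is a
balanced fixed-effects decomposition (statsmodels OLS/anova_lm behind the
package surface, verified in tests against an explicit textbook
sum-of-squares oracle), with interaction only when cells are replicated and
an error on unbalanced layouts. Significance is reported at 5% with no
multiplicity correction. Cohorts draw each synthetic subject's infarct arc
fraction within 15–30% so correlations are estimated over a realistic
between-animal spread.

## Recovery studies and problem sizes

`scripts/acceptance.py` (and `tests/test_acceptance.py`) rebuild each
headline value from scratch:

- **T1ρ recovery**: noiseless 192×192×20 phantom; pure-tissue region means
  recover 91.7/47.2 ms to < 0.1 ms. Region means use pure voxels because
  boundary voxels decay bi-exponentially by construction — they probe
  partial volume, not the fitter.
- **Size recovery**: 10 seeded SNR-50 phantoms with a 21.1% true arc,
  full pipeline; 10 slices (the perimeter fraction is slice-count
  invariant).
- **CNR**: σ solved so the theoretical 48 ms contrast equals 2.7; 10 seeded
  images, σ re-estimated from background. The estimator is slightly
  conservative (≈2.64) because magnitude noise inflates the remote mean
  more than the infarct mean at the remote tissue's working SNR of ≈4 —
  an honest property of magnitude-image CNR, documented rather than
  corrected.
- **Mass**: arc extent solved so the analytic infarct volume equals
  10.9 g / 1.06 g·mL⁻¹; mass recomputed from the supersample-8 raster.
- **Transmurality**: a 90° transmural arc (five whole wedges) plus a
  40%-depth border arc whose width is solved analytically to hold exactly
  6% of infarct volume, arc edges aligned to wedge boundaries so the chord
  calls are not confounded by straddling wedges; 10 seeded SNR-50 runs.

## What passing on the phantom does and does not show

The phantom validates the estimators, the geometry code, and the
propagation of noise through the pipeline under known ground truth. It does
not contain motion, B0/B1 inhomogeneity, spin-lock banding artifacts,
through-plane geometry change, trabeculation, or operator variability in
contour tracing — so recovery here bounds algorithmic error only, not
in-vivo accuracy. Known limitations worth keeping in mind: classification
near the blood pool is fundamentally ambiguous in T1ρ alone (blood and scar
both relax slowly); transmurality at 18° wedge granularity quantizes border
arcs; and the mono-exponential model ignores multi-compartment decay in
mixed voxels, which biases fitted T1ρ at tissue boundaries.
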