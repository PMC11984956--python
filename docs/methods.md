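# Methods

This note records the models, conventions, parameter choices and known
limitations behind `dapquant`'s pipelines, in the order a dataset would
flow through them.

## Synthetic data model

All validation runs on synthetic inputs with exact ground truth; the
generators are first-class, tested code.

**Point-spread function.** Wide-field/SIM-scale blur is modelled as an
isotropic 2D Gaussian parameterised by FWHM (σ = FWHM / 2√(2 ln 2)).
Puncta are rendered by exact per-pixel integration of the Gaussian (erf
differences over pixel edges), so injected amplitude equals integrated
rendered mass up to the ±6σ stamp-window truncation (< 10⁻⁶ relative).
There is no engineered-PSF optics model and no EM-gain/camera noise model:
read noise is plain additive Gaussian. Defaults: 100 nm pixels, 250 nm
FWHM and 6 ADU read noise for centrosome fields (63×/NA 1.4-scale
acquisition); 40 nm pixels and 120 nm FWHM for ring images (SIM-scale).
A noise-free default would be degenerate for background estimation, so
the field default is noisy.

**Centrosome fields.** Centrosomes are Gaussian puncta with per-channel
integrated amplitudes (default: uniform in 2×10⁴–2×10⁵ ADU, a 10× dynamic
range); an optional pericentriolar "haze" fraction redistributes part of
the amplitude into a 3σ-wider Gaussian. Positions are uniform with a
margin so no structure touches the image border.

**Ninefold rings.** Nine blade puncta are spaced 40° apart on a circle of
the configured peak-to-peak radius (defaults mirror the outer
appendage-ring scale, 513.4 nm diameter), optionally tipped about the
image x axis by `tilt_deg` (blade y coordinates scale by cos tilt before
projection — side views are generated by tilting the truth coordinates,
never by a 3D render). Blade phase defaults to 0° and is configurable.

**Two-channel SMLM scenes.** The scene contains (a) a reference ring
(FOP-like) in both channels — radius 150 nm (ring diameter ≈ 300 nm,
typical for FOP at the centriole), 12,000 localizations per channel by
default, radial jitter σ 15 nm, axial σ 30 nm; (b) a vesicle-scale
anisotropic Gaussian cloud in the reference channel with 1/e² widths
defaulting to 230 × 170 × 190 nm (σ = width/4) and 2,000 localizations;
(c) a partner cloud in the second channel offset by a configurable 3D
vector (default magnitude 89 nm split evenly over axes) with 500
localizations; (d) fiducial beads localized in every frame. Localization
noise jitters each emitter by N(0, CRLB) laterally and N(0, 1.5·CRLB)
axially, with CRLB drawn per localization (mean 10 nm, SD 3 nm, floored
at 2 nm) — so measured cluster widths include localization broadening,
exactly as experimental widths do. Fiducials are localized to 1 nm per
frame: bright photostable beads reach sub-nm per-frame precision, and the
two-channel registration error budget (two drift traces referenced at
frame 0) requires it. Stage drift is a per-axis cubic polynomial, zero at
frame 0, scaled to a configurable amplitude — smooth and
spline-recoverable, like slow mechanical drift. The second channel is
observed through a planar affine (+ z shift) followed by a residual 3D
shift; drift is applied before the channel mapping (both channels image
the same drifting stage). Spurious localizations, when enabled, are
uniform over a 1.5×-inflated bounding box with CRLB below the quality
threshold, so only the density filter can catch them.

What the scenes do *not* emulate: blinking/re-activation statistics,
z-dependent aberrations (the affine is depth-independent), background
auto-fluorescence localizations, and multi-emitter fitting artefacts.
Passing tests therefore demonstrate correctness of the post-processing
arithmetic, not robustness to every experimental pathology.

**Nested datasets.** value = grand mean + condition effect + replicate
shift (N(0, replicate_sd), shared within replicate) + cell noise
(N(0, cell_sd)). Defaults (3 replicates, 30 cells, replicate SD 5, cell
SD 15 on a grand mean of 100) give the replicate-dominated error
structure that motivates nested testing.

## Intensity pipeline

1. **Rolling-ball background** — Sternberg's rolling ball: grayscale
   opening with a spherical-cap structuring element (height
   √(r²−d²) over a disk footprint), radius 5 px by default; the top-hat
   (image − opening) is clipped at 0. The opening is anti-extensive, so a
   constant offset anywhere below the headroom is removed exactly. Note
   an isolated 1-px spike keeps its height only up to the cap's
   center-to-neighbour sag (r − √(r²−1)); a flat kernel would keep it
   exactly.
2. **Thresholding** — the original recipe sets a manual per-image
   threshold; reproducibility requires a rule, so three recorded
   strategies are provided: absolute value, sigma-clipped background mean
   + k·SD (default k = 5), and percentile. Sigma clipping (3σ, ≤5
   iterations) keeps sparse bright structures from inflating the
   background statistics.
3. **Mask combination** — the reference and POI masks are united
   (max-projection of the two-mask stack), dilated with a disk(1) element
   until the connected-component count is stable for one iteration (cap:
   10), then eroded the same number of times (configurable override). If
   the cap is hit while counts still fall, the result is flagged
   unmerged.
4. **Particle analysis** — per component: area, centroid, circularity
   4π·area/perimeter² with the Crofton perimeter estimator, capped at 1
   (small rasterized disks can exceed 1 under any discrete perimeter);
   border-touching components are discarded (biased shape metrics);
   size and circularity windows are assay-tuned. Defaults: puncta
   4–400 px², circularity 0.3–1.0; ciliary variant 15–5000 px²,
   circularity 0–0.75. The ciliary gate was calibrated on synthetic
   filaments: short (1.5 µm) cilia at the default PSF reach circularity
   ≈ 0.6, while round puncta sit near 0.9.
5. **Outlier flagging** — ROUT (below) on the POI integrated intensities
   at Q = 1%. Flags are recorded; nothing is deleted.

Integrated intensity under a thresholded mask underestimates total
Gaussian mass (tails are cut); the pipeline is validated for *rank*
recovery (Spearman ≥ 0.9 against injected amplitudes), which is what
fold-change comparisons between conditions need.

## Ring diameters and the molecular ruler

The ring center is the intensity-weighted centroid after subtracting the
20th-percentile background. Full line profiles through the center are
sampled at 0.25 px steps by cubic-spline interpolation at four angles
(0/45/90/135° — equally spaced to minimize orientation bias); on each
side the dominant interior maximum is refined with a three-point
parabola; the per-angle diameter is the peak-to-peak distance, and the
measurement is their four-angle mean. Angles with fewer than two valid
peaks are dropped; fewer than two valid angles is a failure.

Two physical biases are inherent to a peak-to-peak readout of a blurred
blade ring and are *not* corrected, because the experimental measurement
carries them too: (1) curvature bias — blurring a ring of radius r with a
Gaussian of width σ pulls the radial peak inward by ≈ σ²/r per side;
(2) blade-geometry bias — a fixed-angle profile crosses the annulus
between discrete blades, where the peak radius is foreshortened by
cos(δ) for angular offset δ to the nearest blade. At the default
geometry both biases together stay inside half a pixel, the validation
tolerance. No tilt deprojection is attempted; averaging four angles is
the (also experimental) mitigation.

The molecular ruler is linear: helical residues contribute the α-helical
rise (0.15 nm/residue), disordered residues their contour length
(0.4 nm/residue, the fully-extended bound — hence "maximal" extension),
and each IgG layer 8 nm. No persistence-length physics; the model is an
upper-bound arithmetic, not a polymer simulation.

## SMLM post-processing

**Drift.** The fiducial is tracked frame-by-frame (nearest localization
within 250 nm of the running position; error if coverage < 80% or a gap
exceeds 50 frames). Per-axis smoothing uses a cubic smoothing spline in
the csaps convention — objective p·Σ(y−f)² + (1−p)·∫f″², p = 10⁻⁶ —
mapped onto `scipy.interpolate.make_smoothing_spline` via λ = (1−p)/p.
On a frame-index abscissa this gives an equivalent smoothing window of
λ^¼ ≈ 32 frames. The trace is zero-referenced to its frame-0 value; that
constant is a coordinate-origin convention (it shifts a whole channel
uniformly and is absorbed by registration), but it carries the spline's
boundary noise, which is why drift accuracy is asserted on the trace
shape.

**Quality filter.** Keep localizations with lateral CRLB ≤ 20 nm and
mean 3D distance to the 8 nearest neighbours ≤ 100 nm. The CRLB filter
removes *imprecise* localizations (the high-CRLB tail). The neighbour
threshold is ≈ 5× the typical intra-structure nearest-neighbour distance
of the default scenes; on planted-outlier scenes it removes ≥ 95% of
uniform spurious points while losing < 1% of structure localizations.
Outliers that land inside a dense structure are indistinguishable from
signal by any density criterion and are retained.

**Registration.** A planar affine is estimated from bead correspondences
by linear least squares (≥ 3 non-collinear beads; collinearity detected
via the singular values of the centered bead cloud). Fine-tuning: both
channels are histogrammed into 10 nm voxels on a shared grid, their 3D
cross-correlation is computed by FFT, and the peak is refined per axis
with a least-squares quadratic over a ±5-voxel window — the ring×ring
correlation peak is broad (~15 voxels), so a 3-point parabola would be
count-noise limited while the windowed quadratic reaches the ≈1 nm
level. The moving channel is shifted and the procedure iterated until
the incremental shift is below 2 nm on every axis (cap 20 iterations);
a peak within 5 voxels of the histogram border is an error. Registration
is a planar affine plus a 3D translation; no z-dependent affine.

**Clusters.** "Manual isolation" is replaced by explicit, recorded
axis-aligned box ROIs. Per-axis histograms (10 nm bins over ±5 sample
SD) are fitted with a single Gaussian by least squares with √N Poisson
weights (the correct weighting for count histograms; it also halves the
σ-estimator scatter); a non-convergent fit falls back to sample moments
with a flag. 1/e² width = 4σ; cluster COM = fitted means. The vesicle
candidate rule is inclusive: all three widths ≥ 120 nm. COM offsets fit
one Gaussian per species per axis (not a two-component mixture — the
species are separate tables) and the 3D separation is the Euclidean norm
of the three per-axis differences. Minimum 50 localizations per fit.

## Statistics

- **Welch's t** — scipy, Welch–Satterthwaite df, two-sided. Note the t
  reference differs from the exact permutation null by up to ~0.1 in p
  at n = 5 per group; they agree asymptotically (validated at n = 30).
- **Fisher's exact** — two-sided by the probability-mass convention (sum
  of hypergeometric probabilities ≤ that of the observed table); this is
  also scipy's convention and is cross-checked against exhaustive
  enumeration for every table with total ≤ 30. Alternative two-sided
  definitions (doubling the one-sided tail) give different values.
- **Nested t** — equal-variance Student t on replicate means,
  df = n_repA + n_repB − 2. For balanced designs this equals the
  one-level random-effects comparison; it deliberately discards
  within-replicate df to avoid pseudo-replication. Degenerate case:
  zero pooled variance with equal means → t = 0, p = 1.
- **Nested one-way ANOVA + Dunnett** — one-way ANOVA on replicate means;
  many-to-one contrasts use pooled-variance t statistics, with the
  familywise-adjusted p estimated as P(max|T| ≥ |t_obs|) by Monte-Carlo
  (default 10⁵ draws, mandatory seed) over the correlated null t vector
  (shared control mean, shared χ² variance). The adjusted p is floored
  at the unadjusted p (the adjustment is monotone; the floor only trims
  MC noise). MC standard error at the default draw count is < 0.002.
  Cross-checked against `scipy.stats.dunnett` (multivariate-t
  integration) in the tests.
- **ROUT, single-column adaptation** — the published procedure is defined
  for nonlinear regression; the constant-model specialization used here
  is: robust center = median; robust scale RSDR = 68.27th percentile of
  absolute residuals × n/(n−1); test points from the most extreme
  inward, flagging the j-th most extreme when its two-tailed t
  probability (df = n−1) is below Q·(n−j+1)/n, stopping at the first
  non-significant point. On clean normal data the mean flagged fraction
  stays below 2Q. Constant data with distinct values: the off-median
  values are flagged directly (zero scale).

## Scoring rules

Cilium length is the longest geodesic path through the component's
skeleton (8-connected, √2 diagonal steps), found by double Dijkstra
sweep — exact for tree-shaped skeletons. A cell is ciliated when its
candidate is ARL13B-positive, centrosome-associated and strictly longer
than 1 µm. Punctum-to-centriole colocalization uses an explicit radius
(default 500 nm — sub-diffraction proximity at 63×) standing in for
by-eye colocalization; the CP110 count per cell is 2 when CP110
colocalizes with both FOP dots, 1 when it colocalizes only with the
CEP164-negative (daughter) FOP dot, else 0; cells with > 2 FOP dots are
skipped with a logged reason. How centrosome association of a cilium is
judged experimentally is not standardized; the distance rule here is an
explicit, recorded stand-in.

## Problem sizes

The validation suite uses desk-scale sizes chosen to keep estimator
standard errors well inside the asserted tolerances: 12–15k ring
localizations per channel for registration (COM standard error ≈ 0.3 nm),
2,000/500-localization clouds for offsets and widths, 10⁴ null
simulations for nested-t calibration, 200 × 1,000 draws for the ROUT
null rate, and 10 seeds for the end-to-end drift + affine + residual
recovery invariant.

## Known limitations

- The ring-diameter readout is validated for top views only; tilted
  rings are measured without deprojection.
- The intensity pipeline does not assign centrosomes to cells (no
  nuclear segmentation) and reports mask-limited integrated intensity,
  validated for rank rather than absolute recovery.
- Channel registration assumes a depth-independent planar affine plus a
  translation; field-dependent or z-dependent distortions are out of
  scope.
- The Dunnett adjustment assumes a balanced-enough design for the
  pooled-variance model on replicate means; no mixed-effects machinery
  is provided.
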