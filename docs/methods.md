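# Methods

This note documents the models, conventions and numerical choices behind
`nflreflect`, and what the synthetic-data tests do and do not establish
about real OCT data.

## Geometry and conventions

En-face maps live on a square grid of pixel centers over a 4.5 × 4.5 mm
scan centered on the optic disc (clinically 400 × 400 A-lines; the
synthetic generator defaults to 200 × 200 and the test suite mostly uses
128–160, a resolution choice — all geometry is expressed in mm, so the
code paths are identical). Coordinates are mm from the disc center, x
rightward, y upward. All eyes are analyzed in right-eye (OD) orientation;
left-eye maps are mirrored horizontally first, which swaps the nasal and
temporal sides and preserves the multiset of pixel values exactly. After
orientation, azimuth 0 is the temporal horizontal and increases
counterclockwise (90° superior). The analytic zone is the annulus between
1.1 and 2.0 mm; the region beyond 2.0 mm is excluded to avoid cropping
artifacts from scan decentration.

dB means `10·log10` (power convention) throughout, since OCT intensity is
a power quantity; `normalize_to_db(..., db_factor=20)` gives the amplitude
convention if wanted.

## The normalized reflectance map

The map is `NFL_summed / PPEC_mean` per pixel, divided by the population
normalization constant — the mean over the *normal training eyes* of each
map's mean linear ratio in the analytic zone — and converted to dB. Eyes
are never self-normalized; the constant is part of the fitted normative
model. Pixels where the PPEC reference falls below 10⁻⁶ × its median are
treated as vessel-like and inpainted. Vessel inpainting seeds masked
pixels with their nearest unmasked value and then runs Jacobi sweeps of
4-neighbor means over the masked set until the largest update is below
10⁻⁶, a continuity-preserving, order-independent diffusion that cannot
invent values outside the surrounding range; unmasked pixels are
bit-identical to the input.

## Azimuthal band-stop filter

Beam tilt produces, at each radius, an additive first-degree angular
harmonic in dB. The filter splits the 0.9–2.2 mm annulus (the analytic
zone plus margin) into 64 concentric rings and, per ring, fits
`a0 + a1·cos θ + b1·sin θ` by least squares at the *exact* azimuths of the
ring's valid pixels, then subtracts `a1·cos θ + b1·sin θ` in place. Because
nothing is resampled, the operation is an orthogonal projection per ring:
a pure bias of any amplitude and phase is annihilated, the azimuthal mean
and all degree ≥ 2 content pass through, and the filter is idempotent and
linear — all to machine precision on fully sampled rings (the grid's
point symmetry makes odd and even harmonics exactly orthogonal over a
ring's pixel set). Rings whose valid pixels span no more than half the
circle are passed through unfiltered with a warning, since the harmonic is
then unidentifiable. A polar-resampling API (`to_polar`, `from_polar`,
`azimuthal_bandstop`) is provided for polar-domain work and inspection;
the map-level filter avoids it to dodge bilinear interpolation residue
(~10⁻⁴ dB) that would otherwise spoil exactness.

The filter's inherent cost: a defect's own first-harmonic content is
removed along with the bias — no degree-1 band-stop can tell them apart.
The wedge-preservation test therefore checks
`filter(wedge + bias) == filter(wedge)` rather than
`filter(wedge + bias) == wedge`.

Degree-1-only removal is the default (`max_degree=1`); higher orders are a
config option but remove progressively more defect signal.

## Superpixel grid

Trajectories follow a one-parameter arcuate model:
`θ(r) = θ₀ − bend·sin(θ₀)·u(r)` with `u` ramping 0→1 across the annulus,
so superior fibers arc temporally toward the raphe, inferior fibers arc
upward, and nasal fibers run radially. For `|bend| < 1` the map
`θ₀ → θ` is a strict contraction inverse (solved by fixed-point
iteration), so trajectories never cross. Default `bend = 0.35` rad
(≈ 20° swing at the outer radius); `bend = 0` gives straight radial
tracks. The angular flux profile defaults to a double-hump von Mises
mixture peaking at the inferotemporal (6:30 clock position) and
superotemporal (11:00) bundles with a secondary superonasal (1:00) peak;
users can supply their own profile or samples. Track boundaries invert
the cumulative flux integral (trapezoid on 8192 points) at 32 equal
quantiles starting from the temporal horizontal; tracks are then cut into
5 radial segments of equal width (0.18 mm). "Evenly divided" is read as
equal radial width, not equal area — a declared convention, as is the
track origin/ordering (track 0 temporal, counterclockwise, segment 0
innermost). Aggregation is the plain mean of valid pixels per superpixel;
empty superpixels at coarse resolutions are a hard error at grid build
and a NaN (excluded downstream) if validity masks empty one later.

## Normative model

Fixed effects are age − 50, axial length − 23.6 mm, their interaction and
gender (male = 1), with a random intercept per superpixel, fit by REML
(`statsmodels MixedLM`). The interaction is fit on the centered product
and converted back to the raw-product parameterization used by the
adjustment; the centered form is required for numerical conditioning
(the raw product is nearly collinear with age). The adjustment

`x_adj = x − β_age(age−50) − β_axl(axl−23.6) − β_int(age·axl − 50·23.6)`

uses age and axial length only — gender is fitted but, following standard
normative practice, not adjusted for. Reference values: age 50 years,
axial length 23.6 mm (a typical emmetropic normal-group mean). After
adjustment, per-superpixel means μ_s and SDs σ_s over the normal cohort
define Gaussian bands with cutoffs at the 5th (μ − 1.6449σ) and 1st
(μ − 2.3263σ) percentiles; μ_s/σ_s are computed on *adjusted* values, the
scale on which eyes are later compared. A superpixel-demeaned OLS fit
(`method="ols"`) gives identical coefficient estimates on balanced data
and is the default inside bootstrap loops for speed; it uses a
pseudoinverse so that bootstrap resamples with a degenerate column (e.g.
single-gender in-bag samples) do not abort a trial.

Cross-validation uses the 0.632+ bootstrap: each trial resamples the
normal eyes with replacement, fits adjustment and cutoffs in-bag, and
evaluates out-of-bag normals plus all glaucoma eyes; per-eye parameters
are averaged over the trials that evaluated the eye (default 200 trials;
an eye never out-of-bag raises an error advising more trials).

## Diagnostic parameters and patterns

Low-reflectance means strictly below the 5% cutoff (ties are not low — a
measure-zero event for continuous data). Focal reflectance loss sums
(value − μ_s) over low superpixels and divides by the total superpixel
count (160), so it is ≤ 0, exactly 0 when nothing is low, insensitive to
values of non-low superpixels, and monotone in added loss.

Pattern classification operates on the 32 × 5 lattice with cyclic wrap in
the track dimension and 4-connectivity (diagonal adjacency is not
contiguity — the conservative reading):

* **diffuse**: all 5 segments low in a cyclic run of more than 8
  consecutive tracks (strictly more than a quadrant);
* **wedge**: a connected component touching both the inner and outer
  segment rings;
* **other grouping**: a component of ≥ 3 superpixels that is not a wedge;
* **isolated**: any low superpixel, none of the above; **none**: empty.

Severity precedence diffuse > wedge > other grouping > isolated > none
resolves coexisting patterns. The quadrant threshold, connectivity and
the choice of the 5% mask are config options with these defaults. The
published pattern categories were human-graded; this module is an explicit
operationalization, so exact per-eye agreement with human grading is not
claimed.

## Statistics

* **Clustered AUC**: Mann–Whitney with ties counted ½ over all
  diseased/non-diseased pairs; variance from cluster-level sums of the
  placement values (the clustered nonparametric ROC estimator), which
  reduces to the DeLong-type structural-components variance for singleton
  clusters. One eye per participant makes clusters singletons here; the
  implementation stays general for two-eye data. AROC comparisons use a
  paired z-test on the clustered variance of the difference.
* **Sensitivity at fixed specificity**: the cutoff is where the Gaussian
  KDE (Silverman bandwidth) of the normal scores leaves 1 − specificity
  in the disease-indicating tail, found by bisection on the smoothed CDF;
  sensitivity is the fraction of disease scores beyond it. The KDE
  smooths the cutoff into the tail, so at n ~ 10⁵ the Gaussian benchmark
  is met within 0.01.
* **McNemar**: exact two-sided binomial on discordant pairs; p = 1 with no
  discordance. **Wilcoxon rank-sum**: exact for small untied samples,
  tie-corrected normal approximation otherwise (scipy).
* **Pooled SD**: √(mean over eyes × superpixels of the within-cell
  between-repeat variance, ddof = 1).
* **Pearson comparison**: paired bootstrap over eyes of r₁ − r₂, two-sided
  bootstrap p. **GMM clustering**: full-covariance, best of 10 seeded EM
  restarts, components relabeled by decreasing mean average-reflectance.
* **Piecewise regression**: independent fits above/below a fixed −6 dB MD
  breakpoint (not estimated); segments with < 3 points are flagged
  unfitted.

All stochastic operations take explicit seeds and are bit-reproducible.

## Synthetic data: what it emulates, and what it does not

A normal eye is an angular template (von Mises double-hump, offset so the
linear annulus mean is exactly 1, hence 0 dB after normalization) plus
three noise layers:

* **intrinsic individual variation**: a smooth field over (radius,
  azimuth), ~10° angular correlation, 0.35 mm radial correlation, split
  into an angular-coherent part and a radially decorrelating part
  (42% of variance) with total per-superpixel SD 1.78 dB. Its first
  angular harmonic is zeroed — at the population level it is
  indistinguishable from incidence bias, which the filter removes anyway;
* **incidence bias**: per-scan `A·cos(θ − φ)` with Rayleigh(1.19 dB)
  amplitude and uniform phase, giving an unfiltered population SD of
  √(1.78² + 1.19²) ≈ 2.14 dB;
* **repeat-scan noise**: 0.57 dB smooth angular noise per scan plus a
  Rayleigh(0.46 dB) bias perturbation, giving an unfiltered pooled repeat
  SD of √(0.57² + 0.46²) ≈ 0.73 dB.

These four SDs are the study conditions the generator is built to
reproduce and are fixed once. White pixel noise (0.3 dB) stands in for
speckle residue and averages out over superpixels. PPEC maps carry a
smooth beam-coupling modulation that cancels in the ratio, vessels are
curvilinear radial shadows (attenuation 0.4), and the disc is a 0.9 mm
mask. Glaucomatous eyes receive a global attenuation (0.5–3.5 dB,
group-dependent) plus a trajectory-aligned wedge or diffuse defect whose
depth grows with simulated VF MD severity and is capped at a 12 dB
reflectance floor — the cap produces the floor effect seen in the
piecewise regression. Ground-truth superpixel masks mark superpixels with
≥ 50% of pixels inside a defect (a scoring convention, not a claim about
biology); the scalar ground truth `defect_burden` is depth × annulus
fraction covered + global loss.

Not emulated: OCT speckle statistics and A-scan physics, layer
segmentation error, peripapillary atrophy (which inflates the normalized
ratio in real data), media-opacity spatial structure, motion artifacts,
and the human grading of defect patterns. Defect depths needed by the
operational pattern rules (≥ cutoff + ~2 population SD before a region
reliably classifies diffuse) are somewhat deeper than the subtlest
clinical defects, and synthetic normals show spurious wedge patterns
somewhat more often than graded clinical normals. Passing tests therefore
establish the correctness and internal consistency of the algorithms
under the stated statistical structure — not clinical accuracy figures,
which depend on a cohort no synthetic generator reproduces.

## Numerical choices

* Inpainting tolerance 10⁻⁶ (max update per sweep), nearest-neighbor
  seeded for fast convergence.
* Filter rings: 64 over 0.9–2.2 mm; rows with ≤ π angular support pass
  through with a warning rather than erroring, so one occluded ring
  cannot kill a map.
* Equal-flux boundaries: trapezoid cumulative on 8192 points, linear
  inversion; per-track flux equal to ≤ 0.1%.
* Trajectory inversion: 60 fixed-point iterations (contraction factor
  ≤ |bend| < 1 guarantees convergence well past double precision).
* KDE cutoff bracket extends 5 data spans plus 10 bandwidths beyond the
  normal-score range before bisection.
* Superpixel vectors use NaN for missing (empty aggregation); metrics
  exclude NaN and error only when everything is missing.
* Seeds: every generator and stochastic statistic takes an explicit seed;
  cohort rendering derives per-eye substreams from (seed, eye index) so
  cohorts are reproducible eye-by-eye.

## Problem sizes

The test suite and acceptance script use 128–160 px grids, cohorts of
35/30/35 eyes (the reference cohort size), 20 eyes × 2 repeats for
repeatability, 50 replicates for coefficient-recovery coverage, 10⁴ draws
for false-positive calibration and 10⁵ for the sensitivity benchmark —
sizes chosen so a full run completes in a couple of minutes on one CPU
while keeping every statistical check well-powered.
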