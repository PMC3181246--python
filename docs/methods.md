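# Methods

`crmquant` quantifies the structure of 3D collagen networks as imaged by
confocal reflection microscopy (CRM), and validates every measurement on a
synthetic fiber-network generator whose geometry is known exactly. This
note records the models, the estimators, the tunable parameters, and the
design decisions taken where the underlying experimental protocol leaves
the choice open.

## The synthetic collagen model

**Geometry.** A collagen gel is modelled as a set of straight cylinders
(fibers) with endpoints and radii in µm inside an axis-aligned box.
Straight cylinders were chosen over curved fibrils because they admit
closed-form ground truth for every downstream quantity (volume fraction,
length, diameter); fibril curvature and branching are out of scope. Fiber
centers are uniform in the box; orientations are uniform on the sphere
unless an alignment strength is applied. Lengths and radii are lognormal
(coefficients of variation 0.35 and 0.15) around configurable means —
defaults 10 µm and 0.4 µm, in the range reported for reconstituted type I
collagen fibrils imaged at 60×. Segments are clipped to the box.

**Density.** `generate_network` adds fibers until the *union* volume
fraction — tracked on an internal 0.2 µm voxel grid, which corrects for
cylinder overlap — reaches the target. The nominal mg/ml concentration is
carried only as a label: all quantitative truth is the geometric fraction,
so no unpublished mg/ml-to-fraction calibration is ever assumed. If the
target cannot be reached within the fiber budget the generator raises; it
never silently undershoots.

**Remodeling.** One step applies, in order: random fiber removal
(independent Bernoulli with the degradation probability), nematic rotation
of survivors toward a preferred axis (linear mixing of each direction with
the axis, renormalised; strength 1 gives exact alignment), and Poisson
deposition of new fibers with the same alignment bias. The expected count
after a step is `n·(1−p_deg) + rate_dep`. For runs that should *converge*
to a target occupancy, `rates_toward_fraction` converts the occupancy gap
into rates using the Boolean-model identity `occ = 1 − exp(−Σv/V)` between
naive summed cylinder volume and union occupancy; a `rate` parameter in
(0, 1] sets the fraction of the gap closed per step.

**Rendering.** The CRM renderer assigns each voxel whose center lies
inside a fiber the base intensity (default 100) scaled by that fiber's
orientation reflectance, combines overlapping fibers by maximum, then
applies a Gaussian PSF and additive Gaussian noise clipped at zero. The
default PSF sigmas (0.15 µm lateral, 0.35 µm axial) correspond to a
1.2 NA water-immersion lens at 488 nm. Reflectance falls as cos²(elevation
out of the transverse plane) and is forced to zero for fibers within the
blind-spot half-angle of the optical axis, reproducing the known CRM
artifact that axis-parallel fibers return no signal and mesh size is
consequently overestimated. The cos-power form is a modelling choice; the
literature gives only the qualitative effect. The default stack geometry is
60×60 µm laterally at 0.23 µm pixels, 30 µm deep at 0.5 µm slices. Voxel
centers sit at `(index + 0.5) × voxel size`; a warning is raised when
fibers are thinner than one voxel (they then render at least one voxel
wide — a documented diameter bias). The cell channel renders spheres
(default radius 8 µm) with the same PSF/noise model.

## Structural metrics

**Binarization** is per-slice thresholding with the method and value
always recorded. A fixed value applied to every image of an experiment is
the default discipline (cross-image consistency); Otsu computed on the
stack's middle slice and frozen is the alternative. In the synthetic
pipeline the fixed threshold is *calibrated*: a phantom network of known
occupancy is rendered with the experiment's imaging settings and the
threshold solved (bisection, 0.01 intensity units) so that the measured
fraction equals the phantom's true voxelised occupancy, then frozen for
all stacks. This removes the blur-induced area bias that any fixed
guess (e.g. half-maximum) retains when fibers are thin relative to the
axial PSF. Residual bias away from the calibration density is about
±0.01–0.02 absolute over occupancies 0.05–0.30.

**Fibril fraction** is foreground voxels over total voxels; per-slice 2D
area fractions are available and their mean equals the 3D value exactly.

**Pore size** is measured from background run lengths along three lines —
horizontal, vertical, and 45° diagonal (supercover, step √2 × pixel
pitch) — through the image center of the stack's center slice. Only
*interior* runs, bounded by collagen on both sides, count as pores; runs
cut by the image border or by an excluded (cell) region are censored and
tallied separately, so the estimator never mistakes a truncated gap for a
pore. Physical length is pixel count × pitch. The per-stack summary is the
mean of the pooled interior runs (the median is also retained); zero
interior runs yield a missing value, never 0. `pore_runs_stack` applies
the same three-line estimator to every slice when a per-stack estimate
needs more sampling power (e.g. resolving the blind-spot inflation, a
~0.1–0.3 µm systematic, against three-line sampling noise). Cell pixels
from the fluorescence channel are excluded from the lines.

**Fiber morphometry** labels 26-connected components of at least
`min_voxels` (default 8, a speck filter) voxels. Per object: the 3D
skeleton is traced; *diameter* is twice the median Euclidean distance
transform (anisotropy-aware) sampled on skeleton voxels; *length* is the
longest geodesic path through the skeleton graph, measured as a polyline
subsampled every 5 skeleton voxels (suppressing stair-step inflation on
oblique fibers) plus one radius per end (3D thinning retracts skeleton
ends by roughly one radius). When thinning deletes an object outright — a
known artifact for symmetric even-width shapes — a principal-axis fallback
estimates length from the extent of the voxel projection and diameter from
the distance-transform maximum. On isolated cylinders (radius 0.3–0.6 µm,
length 8–20 µm, 0.2 µm voxels) ≥95% of cases recover length within ±10%
and diameter within ±25%.

**Region classification** follows the acquisition rule that a volume is
acellular only when no cell lies within 10 µm above, below, or laterally:
a volume is cellular iff any above-threshold cell voxel lies within the
margin (Chebyshev distance in physical units) of the analysed bounds.
Without a fluorescence channel the label is `control`, with a warning.

## Assay quantification

**Zymography.** A lane is thresholded (polarity selectable for film vs
inverted scans; the threshold is user-supplied with an Otsu suggestion
helper, and always recorded), cleared regions are separated by connected
components, and each band's activity is its pixel count divided by the
culture's cell density — so doubling the density exactly halves the
normalized activity. When exactly two major bands exist (area ≥ 25% of the
largest) the upper is labelled MMP-9 (~92 kDa) and the lower MMP-2
(~72 kDa); this is positional, not ladder-calibrated, and any other band
pattern is labelled `other` with positions reported.

**Rheology.** Storage-modulus frequency sweeps are fit by least squares on
log G vs log f; the modulus at 10 Hz is the fitted line evaluated there, so
`G₁₀ = a·10^b` holds to machine precision by construction. The fit is
exact on noiseless power-law input and requires ≥3 strictly positive
points. Only a single modulus series is fit; a loss-modulus series can be
fit by a second independent call.

## Statistics

All metrics are summarised with bootstrap confidence intervals (default
95%, ≥5000 resamples) because pore-run and fiber-size distributions are
strongly non-normal; no parametric tests or p-values are produced.
The bias-corrected and accelerated (BCa) interval is implemented directly:
z₀ from the fraction of bootstrap replicates below the observed statistic
(continuity-corrected `(count+0.5)/(B+1)` when all replicates fall on one
side, logged), acceleration from jackknife skewness, adjusted percentiles
from the standard BCa formula. An all-identical sample returns the
degenerate interval [x, x] with z₀ defined as 0 and a warning. With z₀ and
a forced to zero the interval reduces exactly to the percentile interval
(asserted in tests). BCa bounds that fail to bracket the estimate under
extreme acceleration are logged, never clamped. Empirical coverage for the
mean of N(0,1) samples (n=30) is within [0.93, 0.97].

Comparisons pool raw measurements (pore runs, fiber sizes) across a
condition's stacks by default — the measurement-level bootstrap; a
stack-level cluster bootstrap is available for per-stack metrics, with the
caveat that a handful of stacks per condition makes it coarse. Groups are
compared descriptively by CI overlap flags, mirroring error-bar reading.

## The experiment pipeline

`run_experiment` executes the full design from one config and one master
seed: per condition (concentration × cell line), replicate gels ×
stacks are generated as independent network realizations, evolved day by
day (default imaging days 1/3/5/7, one remodeling step per day), rendered,
classified (cell-seeded conditions image cellular and acellular regions;
rendered cells provide the classifier input and the pore-line exclusion
mask), measured, and assembled into a long-format table (one row per
individual measurement). Seeds are split hierarchically
(`numpy.random.SeedSequence`) into per-stack, per-day and per-bootstrap
sub-seeds, so the same config + seed reproduces every CSV byte for byte.
Stacks can instead be ingested from (OME-)TIFF files on disk; a declared
condition with missing files is a hard error listing the absences, and
calibrated thresholding is refused for ingested data (no ground truth).

Default problem sizes in the packaged tests and the reproduction script
use reduced render volumes (25–40 µm boxes, 0.25 µm pixels) and
2000-resample bootstraps; these are the package's validation sizes, chosen
so the whole suite re-runs quickly, and all of them are plain config
values that scale up to the full 60×60×30 µm / ≥5000-resample design.

## What the synthetic validation does and does not show

The generator reproduces the *structure* of the measurement problem —
fibrous geometry at realistic densities and fibril dimensions, anisotropic
voxels, PSF blur, read noise, the CRM blind spot, censored pore runs,
cellular exclusion — with known truth, so recovery, monotonicity, and
coverage claims are checked, not assumed. It does not reproduce fibril
curvature or branching, depth-dependent attenuation, speckle, or the
biology (cell-generated forces, true enzyme kinetics); remodeling is
phenomenological (deposit / degrade / align). Passing tests therefore
certify the estimators and the pipeline plumbing, not any biological
conclusion about real gels.

## Known limitations

* Sub-voxel fibrils render at least one voxel wide; diameters below the
  lateral pixel size are biased upward (warned at render time).
* The binarization calibration transfers across densities with a small
  residual bias (~±0.02 absolute at the extremes of the 0.05–0.30 range).
* Percolated (dense) networks form one connected component, so per-fiber
  morphometry is meaningful only for sparse or well-separated structures;
  the experiment pipeline leaves fiber measurement off by default.
* The three-line center-slice pore protocol is faithful to the imaging
  convention but statistically noisy; use `pore_runs_stack` when a
  per-stack pore estimate must resolve small effects.
* BCa with very small per-group samples (e.g. 3 stack-level fractions)
  gives short, unstable intervals; pool measurements or add replicates.
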