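# Methods

`commissura` is a desk-scale re-implementation of a semiautomated virtual
dissection workflow for commissural white matter tracts — in particular the
dorsal hippocampal commissure (DHC), with the anterior commissure (AC) as a
comparison tract — together with the structure–cognition statistics used to
relate tract microstructure to memory performance. Because the original
human (HCP) and ex vivo primate datasets are external, every input is
emulated by the synthetic module: multi-bundle diffusion phantoms with full
ground truth, protocol ROIs in phantom space, and cohorts with planted
effects. This note records the model, the parameter choices, and what the
synthetic experiments do and do not demonstrate.

## Signal model and tensor estimation

Phantom voxels follow the single-tensor Stejskal–Tanner model
`S(g, b) = S0 exp(-b gᵀ D g)`, with an equal-weight multi-tensor mixture in
voxels shared by two bundles and an isotropic tensor (default diffusivity
0.7 × 10⁻³ mm²/s, a typical parenchymal value) elsewhere. The tensor is
estimated by ordinary least squares on `log S` against the six unique
tensor elements plus `log S0`. Plain LLS was chosen over WLS/robust
variants because the acceptance story rests on noise-free exactness (where
LLS inverts the model exactly) plus tolerance bands under noise; non-positive
signals are floored at the smallest positive float before the log. Volumes
with b < 50 s/mm² count as b = 0; the human-flavor convention restricts the
fit to the b ≤ 1000 shell.

Derived maps use the standard Basser–Pierpaoli definitions: MD is the
eigenvalue mean and `FA = sqrt(3/2) ‖λ − MD‖ / ‖λ‖`, clipped to [0, 1], with
negative eigenvalues clamped to zero for FA only and the affected voxels
flagged. The orientation field for tracking carries one peak per voxel (the
principal eigenvector, FA as amplitude) when derived from a tensor fit, or
one peak per resident bundle when supplied directly by the phantom.

## Deterministic tracking

Streamlines are seeded from the centers of a k×k×k uniform subdivision of
every seed voxel (k = 4, i.e. 64 seeds per voxel) and propagated
bidirectionally with Euler steps at a fixed step size — 0.5 mm for the
human flavor, 0.1 mm for the ex vivo flavor. At each step the peak set of
the nearest voxel is consulted and the peak (or its negation) minimising
the turning angle is followed; an arm stops when it leaves the support
mask, when the best turning angle exceeds the 60° threshold, or when the
combined length of both arms would exceed the cap (250 mm human, 100 mm
ex vivo; the second arm's budget is what the first arm left over).
Streamlines with fewer than 3 vertices are rejected. Nearest-voxel lookup
(no interpolation) was chosen because interpolating discrete multi-peak
sets is ill-posed; Euler rather than Runge–Kutta because steps are at most
half a voxel and the acceptance checks are geometric rather than
curvature-critical. The tracker contains no randomness: reruns are
bit-identical.

A practical limitation, demonstrated by the phantom: a *single-tensor* peak
field cannot carry a crossing, and in two-bundle voxels the blended
principal axis can sit nearly orthogonal to either true tangent, stopping
tracks at the crossing. Multi-peak fields (the phantom's ground-truth
field, or any externally supplied peak image) propagate through crossings
correctly; this is exactly why the workflow is defined over an abstract
per-voxel peak field rather than the tensor itself.

## Virtual dissection

A protocol is one SEED region, one or more AND (waypoint) regions, any
number of NOT (exclusion) regions, and a pair of sagittal cut planes.
A streamline survives iff it has a vertex in every AND mask and none in any
NOT mask; vertex membership is nearest-voxel. Because steps are at most half
a voxel, a streamline cannot jump a full voxel between vertices, so
segment–voxel intersection tests add little; this is a documented
approximation. Passage-through is the default AND semantics;
termination-only (endpoints inside the waypoint) is available via a flag,
since tract-selection conventions differ on this point. Commissural
protocols run bilaterally: the second pass swaps the seed with the
contralateral waypoint, and a run in which both passes are empty raises a
reconstruction-failure signal so cohort code can account for per-subject
success rates. Extra operator-supplied NOT regions are supported but never
auto-generated.

The transverse segment keeps, per streamline, the maximal contiguous vertex
runs strictly between the cut planes (open interval, so the cut is
deterministic and side-symmetric). The planes default to five sagittal
slices either side of the grid midline in native voxel units — ±6.25 mm at
1.25 mm voxels, ±2.5 mm at 0.5 mm — configurable in mm.

## Tractometry

FA/MD are sampled at each retained vertex by trilinear interpolation of the
scalar maps (exact on linear fields; nearest-neighbour available for
sensitivity checks). Per-side means pool all vertices of a side — not
per-streamline averages — matching the vertex counts in the combination
formula. The two sides are combined by the vertex-weighted mean

    VWM = (N_L→R · m̄_L→R + N_R→L · m̄_R→L) / (N_L→R + N_R→L),

which absorbs asymmetries in how many streamlines each seeding direction
yields (the phantom's decoy clips only the left seed blob, so the two sides
genuinely differ).

## The phantom

Geometry is authored in millimetres and scales with the field of view; the
human flavor uses a 48×58×48 grid at 1.25 mm, the ex vivo flavor 60×72×60
at 0.5 mm, with the world origin at the grid center so the midline is the
x = 0 plane. The `dhc_default` preset contains:

* a commissural arc (radius 18 mm in the x–z plane, tube radius 5 mm)
  joining two spherical seed blobs (radius 2.5 mm) at (±18, 0, −5) mm, with
  eigenvalues chosen prolate to reproduce the target tract's observed scale
  (MD 1.478 × 10⁻³ mm²/s, FA 0.318);
* a fornix-like straight decoy (tube radius 4 mm, FA 0.45, MD 1.0 × 10⁻³)
  running anterior–posterior, clipping the upper cap of the left seed blob
  and crossing the arc near its left limb — so raw tractography genuinely
  recruits decoy streamlines that only the NOT slabs remove;
* three NOT slabs (two coronal whole-section planes at y = ±10 mm, one
  axial plane above the arc apex), mirroring the three-exclusion protocol
  structure.

Two deliberate choices make the phantom honest about what it tests. The
seed blobs are strictly inside the bundle tube, so streamlines (which keep
their radial offset under tangent-field propagation) stay in the tube
interior and trilinear sampling is not contaminated by partial-volume
mixing at the tube boundary; the 5% tractometry recovery band therefore
measures pipeline correctness, not boundary blur. And the decoy's FA
amplitude (0.45, a plausible fornix value) deliberately exceeds the arc's
(0.318), so seeds in the shared blob cap start along the decoy and the
exclusion gates do real work.

`ac_default` provides a slab-seeded variant (sagittal SEED/AND boxes at
±6.25 mm, three NOT slabs) over a smaller arc with AC-scale metrics
(FA 0.439, MD 0.854 × 10⁻³ mm²/s).

Noise is Rician: `sqrt((S + ε₁)² + ε₂²)` with Gaussian ε of standard
deviation σ. The default σ = 5 at S0 = 100 gives b0 SNR ≈ 20. The default
gradient scheme is single-shell b = 1000 s/mm² with 90 quasi-uniform
directions plus 9 b0 volumes, emulating one shell of a Connectome-style
acquisition; with sparser schemes the Rician FA floor in the background
rises above the 0.1 support threshold and support masks become meaningless.
At this noise level a per-voxel tensor-fit peak field is still too
angularly incoherent for 36 mm deterministic tracking (a single >60° noisy
jump terminates an arm), so noisy experiments track over the phantom's
ground-truth field and sample the noisy tensor-fit maps; the tensor-route
tracking is validated noise-free, where it is exact. Real multi-fibre
pipelines obtain angular coherence from spherical deconvolution over far
richer acquisitions, which is out of scope here.

What the phantom does not emulate: anatomical ROI placement (slabs and
spheres replace operator judgment), scanner artifacts (eddy, susceptibility,
motion), spatially varying SNR, curved crossing geometries beyond the
two-bundle mixture, and any partial-volume averaging at acquisition
(signal is binary per voxel). Passing phantom tests therefore demonstrates
the correctness of the dissection logic and tractometry arithmetic, not
in vivo reconstruction fidelity.

## Cohort model and statistics

The synthetic cohort draws (tract MD, word-recognition score) bivariate
normal with a planted correlation (default ρ = −0.269 at n = 95, the
observed effect scale), independent marginals for the remaining tract
metrics and task scores at their observed means/SDs, and regional volumes
confounded with intracranial volume (ICV) through a linear slope chosen so
corr(volume, ICV) = 0.5 — a mid-range value for subcortical structures.

The analysis layer follows the study design exactly:

* **ICV adjustment** — `adj_i = raw_i − β (ICV_i − mean ICV)` with β the OLS
  slope; residuals are exactly uncorrelated with ICV.
* **Correlations** — two-tailed Pearson r with t-based p (df = n − 2) and a
  percentile bootstrap 95% CI over 1000 paired resamples (percentile rather
  than BCa, the simplest method consistent with "bootstrapped CIs";
  measured coverage at the planted effect is ~94%).
* **Multiplicity** — Bonferroni–Holm step-down within families: the 6
  structure–cognition tests per tract, and the 15 volume–cognition tests.
  The family size m may exceed the number of p-values supplied (partial
  re-examination of a family).
* **Dependent-correlation comparison** — Steiger's Z for two overlapping
  correlations sharing one variable, in the pooled-r (Z1*) form, one-tailed
  in the direction of the observed difference, with Cohen's
  q = atanh(r₁) − atanh(r₂) reported as a magnitude. The between-tract
  correlation r₁₂ is computed from the cohort itself.
* **Sensitivity** — Spearman's rho; boxplot-rule (1.5 × IQR) outlier
  flagging with a re-run (reported alongside, never replacing, the primary
  analysis); and a Bayes factor.
* **Bayesian correlation test** — BF₁₀ for H₁: ρ ~ stretched-beta(width
  κ = 1, i.e. uniform on (−1, 1)) versus H₀: ρ = 0, computed by adaptive
  quadrature of the sampling density of Pearson's r (the hypergeometric
  form of the null-ρ density ratio), with a central 95% posterior credible
  interval read off a dense grid. At the observed (r = −0.269, n = 95) this
  yields BF₁₀ ≈ 3.92 with credible interval ≈ (−0.44, −0.07).

The cohort pipeline restricts to complete cases across both tracts' metrics
and all tasks before any correlation, so between-tract comparisons are made
on one dependent sample, and the complete-case n is recorded per family.

## Numerical conventions

Voxel indices are 0-based and map to voxel centers; streamline vertices are
world-mm everywhere, with format conventions (TRK offsets) normalised at
the I/O boundary. Peak directions are unit vectors within 1e-6. Ties in the
minimum-turning-angle choice resolve to the first peak listed (bundle
declaration order) — deterministic by construction. Holm adjustment uses a
stable sort. Degenerate inputs (constant ICV, zero-variance correlates,
empty segments on both sides, carve-outs that empty an ROI) raise typed
errors rather than propagating NaNs.

## Problem sizes

Default experiment sizes were chosen so the full suite runs on a laptop:
the human-flavor phantom (48×58×48, 99 volumes) builds in ~5 s and tracks
~4600 gated streamlines in ~1 s; statistical calibration uses 2000
simulated cohorts for recovery/coverage and 1000 for familywise error, with
the bootstrap vectorised across resamples. All simulations are seeded and
reproducible.

## Known limitations

* Single-tensor peak fields cannot represent crossings (see above); the
  package deliberately keeps FOD estimation out of scope and accepts
  external peak fields instead.
* Nearest-voxel gating can in principle miss a diagonal corner clip of a
  mask by a streamline segment; with steps ≤ half a voxel this was never
  observed on the phantom.
* The boxplot outlier rule operates on the tract metric only, mirroring the
  univariate screen it emulates; no multivariate outlier detection.
* The bootstrap CI defaults to percentile; BCa is available behind a flag
  but the calibration experiments quantify percentile coverage only.
* Declarative slab ROIs assume an axis-aligned affine; oblique grids must
  supply explicit masks.
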