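# Methods

This note documents the models, parameter choices, and numerical decisions
behind `bonereg`, and what the synthetic phantom does and does not
establish about behavior on real CT.

## Data model and geometry

Volumes are 3D scalar grids in Hounsfield units with spacing (mm/voxel),
origin (mm), and an orthonormal direction matrix; voxel indices are
0-based and world coordinates follow
`world = origin + direction · (spacing ∘ index)`. Axis 2 is the axial
(superior–inferior) direction for the phantoms; nothing enforces this for
loaded data. File I/O (NIfTI, MetaImage) goes through SimpleITK. A rigid
transform maps **fixed** physical points to **moving** physical points —
`T(x) = R(x − c) + c + t` with rotation center `c` — so resampling pulls
moving values onto the fixed grid and two-phase refinement composes
naturally. NIfTI stores geometry in float32; geometry round-trips exactly
at float32 precision (MetaImage, a text header, round-trips doubles).

Interpolators: nearest neighbor (always used for label maps and masks),
trilinear (used during metric evaluation), and Lanczos windowed sinc for
final image resampling. The Lanczos window half-width is 3 lobes
(configurable); per-axis kernel weights are normalized to sum to one so
constant regions are reproduced exactly, taps beyond the array edge
replicate the edge sample, and query points outside the grid return the
fill value (−1024 HU for CT, 0 for labels). Out-of-domain fill during
*metric evaluation* is 0 HU, because the pipeline zeroes everything
outside the bone mask first — background level 0 is the correct neutral
fill there, where air would invent a 10⁶ HU² penalty.

## Mask machinery

The metric mask is the bone mask dilated **slice-wise** with the discrete
disk {(dx,dy): dx²+dy² ≤ r²} (radius 8 voxels; radius 20 for the cropping
box). Dilation is implemented as a slice-decoupled Euclidean distance
transform thresholded at r, which is exactly equivalent to the disk
dilation (monotone, correctly rounded square roots cannot cross an integer
radius) and an order of magnitude faster than convolving a 41×41 kernel.
Components are 26-connected; per label, only the k = 2 largest components
survive (one bone per side), with ties at rank k broken toward the
component with the smallest linear voxel index. The instance with the
smaller mean world x is called "right" (radiological convention; a flip
flag covers the opposite orientation).

## Registration engine

The metric is masked mean squares over sampled fixed-mask voxel centers.
Samplers: `regular` keeps every ⌈1/f⌉-th true voxel in scan order,
`random` draws ⌊f·n⌋ voxels without replacement under the run seed
(re-seeded per pyramid level as seed+level). The pyramid smooths the
full-resolution image with the level's Gaussian σ (in full-resolution
voxel units) and subsamples every s-th voxel; masks are subsampled, never
smoothed. Parameter weighting follows the physical-shift rule: perturb
each parameter by δ, record the maximum point displacement, and scale so a
unit optimizer step moves every parameter a comparable physical distance
(degenerate parameters floor at 1).

Two optimizers operate in that rescaled space:

* **Powell/Brent** (phase 1): direction-set minimization with Brent line
  searches (SciPy's Brent is the line minimizer), Numerical-Recipes
  direction replacement, step length 1.0, step and relative value
  tolerances 1e-8, caps of 5000 iterations and 500 line iterations per
  level. Exact for quadratics in one sweep.
* **Step-capped gradient descent** (phase 2 and baseline): central-
  difference gradients (h = 1e-4 scaled units), plain update
  `−lr·∇f` capped at the current step bound; a step that fails to decrease
  the objective is reverted and the bound halved (regular-step
  relaxation), so the iterate converges geometrically below the cap
  instead of oscillating at it. With `learning_rate=None` every accepted
  step moves exactly the current bound (pure maximum-step mode, used by
  the refinement preset whose table lists only "maximum step size 0.1").
  Convergence: the least-squares slope of the last 10 metric values,
  *relative to their mean magnitude*, falls below 1e-6 — an HU²-scale
  objective never reaches an absolute 1e-6 slope — or the step bound
  collapses below 1e-5 of the cap. A plain descent with learning rate 0.1
  on an HU² objective diverges (gradients are ~10⁴–10⁵ HU²/mm), so the
  baseline preset carries a 1 mm step cap as stabilization; divergence
  (10× growth) aborts with a diagnostic.

The multiresolution driver fixes the rotation center at the metric-mask
centroid, warm-starts each level from the previous one, and never returns
a transform whose finest-level metric is worse than its initialization's —
without this guard, the coarse levels of an already-converged warm start
can wander inside their smoothed, subsampled objective and hand the fine
levels a deficit they cannot always repay. The optimizer hot loop
(transform + trilinear sample + sum of squares) is a fused numba kernel;
the public resampler and metric run the same mathematics in float64 and
are what the oracle tests check.

Three presets mirror the three registration configurations: the
Powell-driven whole-volume phase (versor, regular sampling 25/50/75/100 %,
shrink 4/2/2/1, σ 4/2/2/1, Lanczos final resampling), the cropped
gradient-descent refinement (versor, 35 % regular sampling, shrink
8/4/2/1, σ 3/2/1/0, per-level iteration caps 1000/500/250/100, max step
0.1, convergence 1e-6 over a 10-value window), and the single-level
baseline (Euler angles, 10 % random sampling, learning rate 0.1, 1500
iterations, linear final resampling, no cropping).

## Pipeline

Phase 1 zeroes both volumes outside their own bone masks (symmetric
treatment), registers with the Powell preset, and resamples the moving
volume with Lanczos onto the crop grid. The phase-2 crop box is the
bounding box of the radius-20 dilated **fixed** mask, which anchors the
difference-image grid to the baseline study; the phase-2 metric mask is
the radius-8 dilated fixed mask restricted to the crop.

**Phase 2 registers the original moving volume, warm-started at T₁**, and
the final image is resampled once under the total transform. The
alternative — registering the already-resampled phase-1 output from
identity and resampling sequentially — was implemented first and measured:
interpolating a once-resampled image is exact on its own lattice and
increasingly smoothed off it, which carves a spike minimum at the identity
plus spurious lower minima about one voxel away into the mean-squares
profile; the refinement then systematically dragged well-aligned bones off
truth (worse MSD in 10 of 15 phantom bone-cases). Composed refinement
removes the artifact and restores the expected ordering (two-phase ≥
one-phase). Masks are always transported once, nearest-neighbor, under the
total transform.

Difference images are `pre − registered(post)` on the crop grid, computed
from the soft-tissue-zeroed volumes (outside bone both operands are zero,
so the subtraction isolates the bone). Density loss in the follow-up is
therefore bright, density gain dark. Evaluation: DSC and MSD compare the
fixed bone mask with the transported moving mask on the full fixed grid
(surface = 6-connectivity boundary voxels at voxel centers, volume edges
count as surface); MSE is computed over the radius-8 dilated fixed mask on
the crop. Summaries report per-bone mean ± sample SD (n−1).

The divergence warning compares phase 2's finest-level final metric to the
same level's *initial* value (the phase-1 alignment seen under identical
smoothing and sampling); comparing across phases at different smoothing
levels would flag healthy runs.

## Synthetic phantom

The generator emulates paired pre/post lower-limb CT at 160×160×120 voxels
and 0.9×0.9×3.0 mm — in-plane and axial spacings representative of
whole-body low-dose CT. Bones are **bowed capsules** (arc axis, sagitta
6/4/3 mm for the femur/tibia/fibula-like shafts): cortical shell +1200 HU,
marrow −60 HU, soft-tissue envelope +40 HU, air −1024 HU. The bow matters:
a straight tube is rotationally symmetric, its axial twist is invisible to
any intensity metric, and an off-axis lesion would be irrecoverably
mislocalized; real long-bone shafts bow by several millimetres, which is
precisely what makes the full 6-DOF motion observable.

The noiseless geometry is blurred with a Gaussian scanner PSF
(σ = 0.8 mm in-plane for the reconstruction kernel, 2.0 mm axially for the
3 mm slice profile) **on each grid separately**, then independent 20 HU
Gaussian noise is added per time point. Without the PSF the phantom has
infinitely sharp edges no scanner produces, and the mean-squares metric at
*perfect* alignment is ~2·10⁴ HU² of pure grid-phase aliasing with false
minima one voxel away; with it, the metric at the ground-truth transform
is a small interpolation residual, far below any misaligned value (the
residual is not zero — 3 mm axial sampling of a σ = 2 mm profile still
leaks ~10 % of the edge spectrum past Nyquist, an honest property of such
data).

The post volume is rasterized analytically from the moved geometry (never
by warping the pre volume), so recovery tests measure a true geometric
motion, not a shared interpolation artifact. Lesions (−400 HU spheres,
clipped to the host bone) and infiltrate (+100 HU) are carved into the
post volume before the PSF; ground-truth masks are recorded on both grids.
Default per-bone motions draw a rotation of up to 10° about a uniformly
random axis through the bone centroid, in-plane translations within
±7 mm, and axial translation within ±15 mm (total norm < 20 mm —
between-visit repositioning of a scanned leg moves mostly along the table
axis); draws that would collide bones are rejected and redrawn
deterministically. The layout spaces the three bones so that no admissible
draw can make them touch.

What the phantom does **not** model: trabecular texture, beam hardening
and metal artifacts, scanner-kernel-specific noise correlation, joint
flexion, and segmentation error (its label maps are exact). Passing tests
therefore demonstrate the pipeline's geometric and numerical correctness
and its behavior under CT-like contrast, sampling, and noise — not
robustness to imperfect CNN segmentations, which on real data bounds the
achievable DSC/MSD.

## Problem sizes and runtime

The registration suite used by the acceptance tests runs 20 seeded pairs
(three bones each) through all three methods at the full 160×160×120 grid,
about 6–7 minutes on one CPU; `scripts/acceptance.py` uses 10 seeds. Unit
tests use one- and six-bone phantoms at 48³–160×96×60.

## Known limitations

* DSC between a fixed mask and a nearest-neighbor-transported moving mask
  is ceiling-limited by discretization at 0.9×0.9×3.0 mm: even the exact
  ground-truth transform yields ≈0.98 / 0.973 / 0.963 for the femur- /
  tibia- / fibula-sized bones, so suite medians sit near 0.976 no matter
  how good the registration is.
* On this phantom, phase 1 essentially always converges, so phase 2's
  contribution is ties-or-small-gains; the large fibula rescues reported
  for patient data arise from phase-1 failure modes (segmentation
  differences between time points) the phantom does not reproduce.
* Difference images retain a halo at the mask boundary where the
  soft-tissue zeroing cuts through the blurred cortex edge at different
  sub-voxel phases on the two grids; quantitative region statistics should
  stay clear of the mask boundary.
* The baseline method's capture range is poor by design (no pyramid); it
  fails outright on thin displaced bones, which is the point of the
  comparison.
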