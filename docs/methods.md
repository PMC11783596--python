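# Methods

## Coordinate conventions

All world coordinates are millimetres in the DICOM LPS frame.  A voxel at
0-based index **i** sits at `origin + direction @ (spacing * i)`.  NIfTI
files store RAS+ affines; the readers flip the first two world axes on
load and back on save.  Displacement fields hold world-mm 3-vectors per
voxel and follow the *pull-back* convention: resampling through field *d*
computes `out(x) = src(x + d(x))`.  Pull-back fields compose as
`d(x) = d1(x + d2(x)) + d2(x)` (d1 applied first), so a whole sequence of
deformations costs a single interpolation of the image at the end.

## Structure-guided augmentation

### Transform sampling

Each organ draws a translation with i.i.d. components uniform on
[−L, +L], L = `displacement_limit_mm` (default 40 mm), and a per-axis
extent change δ_a uniform on [−min(L_s, E_a/2), +L_s], with L_s =
`scale_limit_mm` (default 40 mm) and E_a the organ's bounding extent along
axis a.  The scale factor is s_a = (E_a + δ_a)/E_a, clamped at 0.1.
Interpreting the scaling bound as an *extent change in mm* keeps a single
printed bound meaningful across organs of very different sizes: a 40 mm
bound lets a 160 mm organ change by ±25 % but lets a small organ at most
halve (the δ_a ≥ −E_a/2 floor) while still allowing substantial growth.
An isotropic option draws one δ and converts it through the smallest
extent.  Scaling is centred on the organ's centre of mass.

### Field construction

The affine motion of one organ, Φ(x) = c + S(x − c) + t, is realized
directly as a pull-back field in the destination frame:
d(y) = S⁻¹(y − c − t) + c − y on a support consisting of the
forward-mapped organ mask **and** the source mask, both dilated by a
3.5 σ collar, zero outside, then convolved per component with a Gaussian
of σ = `smoothing_sigma_mm` (default 5 mm).

Three properties motivate this construction:

- *Exactness on the organ.*  A Gaussian preserves affine functions, so
  wherever the smoothing window sees only affine values — everywhere
  inside the mapped organ, thanks to the collar — the smoothed field still
  maps the organ exactly where the drawn transform says.  Without the
  collar, smoothing a field that stops dead at the organ boundary
  attenuates the boundary motion by ≈50 %, which for organs only 2–3 σ
  across corrupts the realized translation and volume change far beyond
  any useful tolerance.
- *Evacuation.*  Including the source mask in the support makes voxels at
  the organ's original position sample the tissue behind it
  (d = Φ⁻¹ − id there), so the organ does not leave a ghost copy behind
  under large translations.
- *No numeric inversion in the loop.*  An earlier design built the forward
  field and inverted it by fixed-point iteration.  That cannot realize a
  40 mm shift: the forward field's support never reaches the destination
  region, where the iteration then settles on the spurious zero solution
  and the warped organ loses its far side.  The analytic destination-frame
  construction is exact for any in-FOV shift and faster.  A damped
  fixed-point `invert_field` (residual-checked, non-convergence flagged)
  is still provided for inverting general smooth fields; it converges to
  0.1 mm for fields with Lipschitz constant below one, which in practice
  means amplitudes up to ~10 mm at σ = 5 mm on solid organs.

Smoothing exploits linearity: disjoint support components (distant
source/destination lobes of a large translation) are smoothed over their
own padded bounding boxes and summed, which is exact and much cheaper than
filtering one box spanning both.

### Sequential composition

One augmentation visits all organs in a uniformly random order.  Each step
samples its transform from the organ's *current* (already deformed) mask,
composes the step field into the running pull-back field, and re-derives
the current anatomy by warping the **original** label map through the
running field — never chaining nearest-neighbour warps, so label
resampling error does not accumulate.  After the last organ the original
image (trilinear, out-of-view filled with the image minimum) and label map
(nearest-neighbour, background fill) are resampled once.  With both limits
zero every step field is identically zero and the inputs are returned
bit-exactly.

### Plausibility guard

Visual inspection does not scale to unattended batch generation, so a
volume-ratio guard stands in for it: after each step, every organ's voxel
count relative to its input count must stay within
`plausibility_volume_ratio_bounds` (default [0.3, 3]).  Three refinements
keep the guard from deadlocking at the default 40 mm bounds, where draws
are violent relative to organ spacing:

- A step is rejected only for violations it *introduces or worsens*
  (drift tolerance 0.02).  Violations inherited from an accepted earlier
  step — an organ legitimately clipped at the FOV edge, or a neighbour
  squeezed to just above the floor — never block later structures;
  otherwise the sequence can reach states that no draw can repair.
- The currently moved organ is exempt from the lower bound when its own
  motion pushes it against or beyond the FOV boundary (clipping is not
  implausibility).
- A cheap det(S)-based pre-check (20 % margin) rejects hopeless draws
  before any field is built; the post-warp count check remains the
  authority.

Each structure gets `max_structure_retries` draws (default 40).  If none
is plausible — observed roughly once per 400 augmentations, when earlier
accepted steps leave neighbours pinned at the floor — the structure is
processed with the identity transform and listed in
`AugmentationRecord.fallback_identity` (set `on_retry_exhaustion="error"`
to raise instead).

### Expansion and reproducibility

`expand_dataset` / `iter_expand` emit every original plus
`expansion_factor − 1` variants (default 10, so 43 inputs become 430
outputs).  Per-item RNG streams derive from `(seed, item, replicate)` via
`SeedSequence` spawn keys: outputs are byte-identical across runs and
independent of iteration order.

## Conventional augmentation baseline

Random patch extraction (default three 240×240×80 patches), additive
Gaussian and Rician noise, gamma contrast on the [0, 1]-rescaled image
plus intensity shifts, and a global elastic warp built from coarse-grid
(50 mm) Gaussian offsets (10 mm SD) linearly upsampled — linear
interpolation keeps the dense field's max norm bounded by the largest
coarse offset.  The noise/contrast/elastic magnitudes are generic
defaults, not calibrated to any clinical dataset; they are exposed in
`ConvAugConfig`.  Transforms apply in a fixed order (patch → noise →
contrast/shift → elastic), each gated by its probability, so one seed
reproduces a whole batch.

## Preprocessing chain

`resolve_overlaps` assigns each voxel claimed by several structures to the
one whose non-overlapping remainder is nearest (Euclidean mm via a
spacing-aware distance transform; ties break by roster order); it is
deterministic and idempotent, and a structure living entirely inside
overlaps is an error.  Foreground detection is Otsu thresholding, largest
6-connected component, morphological closing (3-voxel ball); the crop box
is the union of body foreground and all structure masks plus a margin
(default 5 voxels), with the origin shifted so retained voxels keep their
world coordinates.  Denoising is explicit-scheme Perona–Malik diffusion
(conductance `exp(−(|∇u|/K)²)`, default K = 3, 5 iterations, dt = 0.0625 —
enforced ≤ 1/16 for the 3D explicit scheme, which also yields a discrete
extremum principle).  Resizing maps voxel-edge-aligned physical extents
(linear for images, nearest for labels).  Normalization is the global
affine map to [−1, 1]; a constant image maps to zeros; optional percentile
clipping is off by default.  Bias-field correction is intentionally out of
the chain — run an external corrector first if the data needs it.

## Synthetic phantom

The phantom is stylized, not anatomically faithful: its role is to carry
the statistical structure the algorithms assume — eight disjoint labeled
organs inside a body, organ-dependent contrast, smooth multiplicative
bias, Rician noise — at desk-scale cost.  Geometry: 96×96×64 voxels at
2×2×2.5 mm, grid centred on the origin.  The body is an elliptic cylinder;
liver, kidneys, spleen and stomach are jittered ellipsoids; duodenum
(C-loop) and small bowel (sinuous) are curved tubes; the spinal canal is a
straight z-spanning tube.  Placement jitter is ±3 mm with ±5 % axis
jitter; masks are intersected with the body and with the complement of
previously placed organs, so disjointness holds by construction.
Intensities loosely emulate motion-averaged balanced-contrast MR (fluid
bright, gas-filled lumina dark); the bias field is smoothed white noise
scaled to ±20 %; Rician noise has σ = 5 intensity units.  The synthetic
dose grid is a 40 Gy prescription (5 fractions) flat inside a spherical
target near the pancreatic head with Gaussian penumbra (σ = 8 mm).

What passing tests on the phantom do **not** show: performance on real MR
(no breathing motion, no susceptibility or flow artifacts, no
compression-belt anatomy shifts, organs are smooth parametric shapes).
They do show that the algorithms honour their contracts — geometry
handling, bounded sampling, exact identity, recovery of forced transforms,
disjointness, determinism — which is the part that transfers.

## Evaluation metrics

Dice is 2|A∩B|/(|A|+|B|); two empty masks score 1 (flagged).  ASD is
symmetric by default: surfaces are 6-connected erosion residues, distances
come from a spacing-aware Euclidean distance transform of the opposing
surface, and both directions pool with surface-voxel-count weights;
one-directional variants are available; an empty mask makes the metric
undefined (flagged, never silently zero).  Dx% is the largest dose
received by at least x % of the organ's voxels, computed by descending
sort without interpolation — an estimator with an exact counting oracle.
Difference categories use Δ% = 100·|D_pred − D_gt|/D_gt (denominator
switched to the prescription when D_gt < 1 % of it, avoiding blow-up on
organs receiving essentially no dose) with half-open bins: [0, 1) ✔,
[1, 5) •, [5, ∞) ✘ — the boundary values 1 % and 5 % map upward.

## Numerical and performance choices

Resampling kernels (trilinear, nearest, fused field sampling and
composition) are numba-compiled; axis-aligned geometries take a fused fast
path, general direction matrices a vectorized generic path.  Problem sizes
in the test suite and acceptance script (96×96×64 phantoms, 43-item
cohorts, 16³ oracle grids) were chosen so brute-force oracles stay
exhaustive while a full tenfold expansion of 43 phantoms runs in a few
minutes on one CPU.  Volume-count recovery of a forced scaling is asserted
on the two largest interior organs: the warp matches an exact analytic
affine voxelization oracle bit-for-bit, and for organs of ~5-voxel radius
the lattice-point discrepancy of the *counting measure itself* is of the
same order as the 10 % band being checked.

## Known limitations

- No diffeomorphism guarantee: large translations with small σ fold space
  in the decay collar; the plausibility guard, not a positive-Jacobian
  constraint, polices the result.
- The guard measures only volume ratios; shape implausibility (e.g. an
  organ bent around another) passes if volumes survive.
- `invert_field` is only guaranteed for contraction-regime fields
  (amplitude ≲ 2σ); harsher fields are flagged, not silently inverted.
- Organ intensity models, noise and dose profiles are stylized; none of
  the phantom's numeric defaults claim clinical calibration.
- Preprocessing assumes a single connected body; multi-body fields of
  view (e.g. arms scanned separately) would need a smarter foreground
  rule.
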