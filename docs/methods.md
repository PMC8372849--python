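# Methods

`fetalpose` detects the position and orientation of the fetal head in a
low-resolution full-uterus scout volume (T2*-weighted 2D EPI, roughly
(2–3 mm)² in-plane, 3 mm slices) so that a follow-up anatomical stack could
be prescribed in the fetus's own sagittal/coronal/axial planes. The only
inputs are the scout volume and the gestational age (GA) in weeks; GA indexes
reference diameters — occipitofrontal (OFD), biparietal (BPD) and ocular
(OD) — that drive every size threshold.

## Pipeline

1. **Per-slice preparation.** Each slice is divided by a Gaussian-blurred
   copy of itself (FWHM `f_NU` = 20 mm) to flatten coil shading, and
   multiplied by inverted difference-of-Gaussian weights (FWHM 10 / 5 mm)
   that de-emphasize dark edges. Kernels convert FWHM to sigma via
   `FWHM / (2 sqrt(2 ln 2))`, truncate at 3 sigma, and mirror at
   boundaries (a choice; the boundary rule has no printed convention).
   Flattening maps every broad plateau to ~1, so the brain is not "brighter
   than the background" afterwards — it is a bright region *enclosed by the
   dark skull ring*, which is exactly the structure the region detector
   keys on.
2. **Slice-wise MSER detection.** Bright-polarity maximally stable extremal
   regions are the connected components of upper level sets whose area is
   stable across thresholds. Semantics (shared by the fast detector and the
   brute-force oracle): intensities are quantized to 256 levels; for each
   distinct component C with birth level t_hi, the variation is
   `q(C) = (|A(C, t_hi - delta)| - |C|) / |C|` with `A(C, tau)` the
   component of the upper set at `tau` containing C; a component is kept if
   its area is within bounds, `q < max_variation`, `q` is strictly below
   the parent's and not above any child's, and it is not the full-image
   root; nested candidates with relative area difference < `min_diversity`
   are suppressed greedily, most stable first. Defaults (`delta` 5/256,
   `min_area` 9 px, `max_area` 40% of the slice, `max_variation` 0.5,
   `min_diversity` 0.2) are deliberately loose: the anatomical filter banks
   downstream do the real selection. `detect_msers` computes this on the
   max-tree (`skimage.morphology.max_tree`); `mser_oracle` thresholds
   exhaustively at every level, and the suite checks exact agreement on
   randomized images. With `delta` defined on the quantized scale,
   detection is exactly invariant under affine intensity remaps; strongly
   nonlinear monotone remaps can shift stability scores, as in standard
   implementations.
3. **Age-specific filtering.** An equal-moment ellipse is fitted to every
   region (axes from covariance eigenvalues, `full axis = 4 sqrt(lambda)`
   for a solid ellipse, plus a `spacing^2/12` term for the finite pixel
   extent). Three filter banks bound the normalized area, aspect ratio,
   major axis, region-ellipse Dice overlap, distance to the brain centre
   and (for eyes) local contrast; bounds are listed in
   `fetalpose.regions.FILTER_STAGES` and are config-overridable. Local
   contrast is the median intensity inside the fitted ellipse over the
   median in the ribbon between the ellipse and a copy with 50% longer
   axes, computed on raw (unflattened) intensities since it is defined as
   relative brightness in the image.
4. **Brain localization.** Region barycenters (world mm) are clustered by
   Gaussian mean-shift (kernel FWHM 0.5 x OFD) started from a regular grid
   (spacing 0.5 x OFD, tolerance 1 mm, <= 100 iterations); regions within a
   strict 0.5 x OFD of a converged mode join that cluster (multi-membership
   allowed). Clusters are ranked by the fill factor
   `F = |M and E| - |E \ M|` against the moment-fit ellipsoid E of the
   aggregated mask M, preferring large, nearly ellipsoidal masks; ties
   break on mask size, then centroid z. The winning mask is regularized
   slice-wise — 2D hole fill, interior empty slices filled with the
   intersection of the nearest non-empty neighbours, protrusions removed —
   with the three-step pass repeated to a fixed point so the operation is
   idempotent. Its barycenter is the initial brain centre B.
5. **Brain masking.** Regions are re-detected on partial slices inside a
   box of side `sqrt(2) x OFD` centred on B with the looser stage-B bounds
   and unioned with the global mask. Per-slice major axes are fitted by a
   parabola over the central 50% of non-empty slices; slices whose
   residual z-score exceeds `z_poly` = 1.5 are discarded when the fit is
   concave. The z-score denominator is the SD of the *full* residual
   population: a clean near-ellipsoidal profile has millimetre-scale
   central residuals while its sqrt-shaped margins sit >10 mm from any
   parabola, so normalizing by central residuals alone would discard half
   of a perfect brain (measured on the noise-free phantom; it biased the
   centre by over one voxel). The slice carrying the largest axis is never
   discarded. A 3D moment ellipsoid (full axis `2 sqrt(5 lambda)`, the
   solid-ellipsoid relation) then updates B and provides the major axis
   used for left-right disambiguation.
6. **Eye detection.** The same box is resampled isotropically at half the
   in-plane voxel size (trilinear); stage-C filtering keeps small, round,
   high-contrast regions at plausible distance from B. Every region seeds a
   candidate cluster containing all other regions within 0.75 x OD;
   duplicate member sets merge. Every unordered pair (j, k) is scored by
   `eps = |(u_j+u_k)/OFD - 1| + 2 lambda |u_j-u_k|/(u_j+u_k) +
   |w/d_io - 1| + |(s_j+s_k)/(2 s_max) - 1|` (brain-eye distance prior,
   left/right symmetry with `lambda` = 4, eye-separation prior, multi-slice
   support), and the minimum wins. Each term is wrapped in an absolute
   value so deviations penalize in both directions. The eye-separation
   reference `d_io` defaults to 2 x OD (~28 mm at 31 weeks, close to the
   real centre-to-centre interocular distance) and is exposed in the
   config, as no published constant pins it down.
7. **Anatomical frame.** LR runs through the eyes, PA from B through the
   eye midpoint, IS by perpendicularity; LR is replaced by PA x IS for
   exact orthonormality. The LR sign is resolved from the brain ellipsoid:
   the plane containing the major axis and parallel to LR splits the brain,
   and IS must point away from the half containing the eyes; if the mask is
   near-spherical (anisotropy < 1.05) or the major axis lies within 10 deg
   of LR, the frame is returned flagged ambiguous instead. Resolution runs
   before the `theta` = 30 deg tilt about LR that moves the frame from the
   eye plane to the brain's axial plane (tilting first would reverse the
   tilt sense whenever a flip is needed). Output is RAS and right-handed;
   the +LR eye is the anatomical right eye.

## Biometry

The reference table ships as a TSV over 14-40 weeks with linear
interpolation. The published growth references are not reprinted in the
source material, so the bundled table is a synthetic stand-in: smooth
monotone quadratics anchored at the two printed values OD(31 wk) = 14 mm
and OFD(31 wk) = 96 mm, with BPD chosen to keep a realistic cephalic
proportion (OFD/BPD ~ 1.2). Exact published norms can be supplied with
`--biometry <tsv>`.

## Synthetic phantom

The generator renders the study conditions end-to-end: a bright brain
ellipsoid (axes OFD x BPD x BPD, intensity 1.0) inside a 3 mm dark skull
shell (0.2); two eye spheres of diameter OD (1.2) inside 3 mm dark orbital
shells (0.25), placed so each is OFD/2 from the brain centre, separated by
2 x OD, with the eye plane tilted 30 deg below the brain's axial plane;
smooth maternal texture around 0.5; bright decoy blobs (3 by default, some
inside the eye-search annulus); a slow multiplicative shading field (+/-30%)
exercising the flattening; additive Gaussian noise (sigma 0.05 of brain
intensity); and an optional +/- shift/2 in-plane displacement between odd
and even slices emulating interleaved-acquisition motion (1 mm default).
Default geometry is 240 x 240 x 180 mm at (3 mm)² x 3 mm — 60 slices,
inside the 30-90 slice range of the targeted scouts; the in-plane matrix
(80²) is smaller than a full-abdomen acquisition because the phantom models
the uterus region only, which keeps a 40-phantom cohort tractable on one
CPU. The orbital shell thickness matters: below ~2 resampled voxels it
partial-volumes away and the true eyes fail their own contrast prior, which
is an artefact of the rendering, not of the method.

What the phantom does *not* emulate: EPI distortion and signal dropout,
spin-history stripes, wrap-around, maternal structures that mimic fetal
anatomy (bladder, cysts), truncated fields of view, and second-trimester
contrast (thin skull). Passing the cohort therefore shows the geometry and
selection logic work under noise, shading, decoys and inter-slice motion —
not that clinical success rates transfer.

## Evaluation

A detection is successful when each labeled eye lies within 1.2 x OD of its
true landmark (strict inequality; a label-agnostic variant takes the better
pairing). Orientation error dR is the magnitude of the Kabsch rotation
aligning the detected {B, E1, E2} triangle to the truth after centroid
subtraction (proper rotation enforced); per-axis components are intrinsic
x-y-z Euler angles of that rotation, a convention choice. Translation
errors are per-landmark Euclidean distances with per-axis magnitudes.
Cohort summaries report Minimum/Maximum/Mean/SD per metric; rotation rows
cover successful cases only, since a failed landmark pair carries no
meaningful orientation.

## Numerical choices and degenerate inputs

- Flattening guard: divisor + 1e-6 x slice max (1 if all-zero), keeping
  the operation scale-free; an all-zero slice maps to zeros.
- Degenerate DOG rescale (constant slice) returns weights of 1.
- Collinear pixel sets get a one-pixel-wide minor axis and a degeneracy
  flag; masks with < 4 non-coplanar voxels take a -inf fill factor and can
  never be selected; ellipsoid fits require >= 10 non-coplanar voxels.
- Contrast ribbons clipped to the slice; an empty ribbon rejects the
  region.
- Single-slice masks skip protrusion removal (there is no neighbour to
  consult; deleting the whole mask would be destructive).
- Mean-shift modes closer than 10 x tolerance merge; assignment uses
  strict inequality at the 0.5 x OFD radius.
- All ties (brain selection, eye-pair selection, MSER ordering) break
  deterministically; the pipeline is deterministic given the input volume.

## Known limitations

- The bundled biometry is anchored at two printed values only; absolute
  sizes between anchors are plausible but not authoritative.
- Exactly adjacent intensity plateaus (a perfectly flat region inside
  another) yield a single region for the pair; transition gradients in real
  data make this configuration vanishingly rare.
- Single best cluster only: twins are out of scope.
- The eye-separation prior `d_io` is a configurable default, not a
  published constant.
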