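# fetalpose

Fetal head-pose detection from low-resolution full-uterus MRI scout volumes.

In fetal-brain MRI, the head moves between the moment a technologist
prescribes a stack of slices and the moment it is acquired, so the standard
sagittal/coronal/axial views are frequently lost and the ~55 s anatomical
stack has to be repeated while "chasing the fetus". `fetalpose` addresses
the upstream problem: given a fast (~5 s) full-uterus T2\*-weighted EPI
scout — roughly (2–3 mm)² in-plane, 3 mm slices — and the gestational age
(GA), it locates the fetal brain and both eyes and returns the anatomical
left–right (LR), posterior–anterior (PA) and inferior–superior (IS) axes,
i.e. the rigid transform that would let the scanner prescribe the next
stack in the fetus's own planes. It is intended for researchers working on
automated slice prescription and fetal image analysis.

## Method

The pipeline is classical image analysis, fast enough for on-line use and
fully inspectable:

1. each slice is intensity-flattened (division by a blurred copy of
   itself, FWHM 20 mm) and dark edges are enhanced with inverted
   difference-of-Gaussian weights (FWHM 10 / 5 mm);
2. **maximally stable extremal regions** (MSERs) — connected components of
   upper level sets whose area is stable across thresholds — are detected
   on every slice (brain, CSF and eyes are bright in T2\*-EPI);
3. regions are filtered by GA-specific anatomy: fitted-ellipse area, axes,
   aspect ratio and Dice overlap are bounded relative to the
   occipitofrontal (OFD), biparietal (BPD) and ocular (OD) reference
   diameters at that age;
4. surviving regions are clustered across slices by mean-shift
   (kernel FWHM 0.5 × OFD); the cluster whose aggregated 3D mask best
   fills its own moment-fit ellipsoid (fill factor |M∩E| − |E∖M|) is the
   brain, and the regularized mask's barycenter is the brain centre *B*;
5. a local re-detection inside a √2 × OFD box refines the mask, a
   parabola fit over per-slice major axes prunes outlier slices, and a 3D
   ellipsoid fit updates *B*;
6. the box is resampled at half the in-plane voxel size and candidate eye
   clusters (radius 0.75 × OD, local contrast ≥ 2) are scored in pairs by

   ε(j,k) = |(u_j+u_k)/OFD − 1| + 2λ·|u_j−u_k|/(u_j+u_k)
          + |w/d_io − 1| + |(s_j+s_k)/(2·s_max) − 1|,   λ = 4,

   mixing a brain–eye distance prior, left/right symmetry, an
   eye-separation prior and multi-slice support; the minimal-ε pair wins;
7. LR = (E₂−E₁)/‖·‖, PA from *B* through the eye midpoint, IS by
   perpendicularity (LR re-orthogonalized as PA × IS); the plane through
   the brain ellipsoid's major axis parallel to LR tells which half of the
   brain holds the eyes (the inferior half), fixing the LR sign and the
   left/right eye labels; finally the frame is tilted 30° about LR from
   the eye plane to the brain's axial plane. Output is RAS, right-handed.

A seeded synthetic phantom generator (bright brain ellipsoid, dark skull,
eye spheres, maternal texture, shading, noise, decoys, odd/even-slice
motion) provides ground truth for every stage, and an evaluation module
implements the success criterion (both labeled eyes within 1.2 × OD of
truth) and the translation/rotation error metrics. See `docs/methods.md`
for assumptions, parameter defaults and limitations.

## Worked example

Generate a phantom scout at 31 weeks (noise, shading, decoys and 1 mm
inter-slice motion on by default), detect the head pose, and score it
against the generator's ground truth:

```sh
fetalpose phantom --ga 31 --seed 3 --out scout.nii.gz --truth truth.json
fetalpose detect scout.nii.gz --ga 31 --out-dir .
fetalpose evaluate --pred pose.json --truth truth.json
```

which prints

```json
{
  "success": true,
  "success_label_agnostic": true,
  "dT_B_mm": 0.42361760789521075,
  "dT_E_left_mm": 0.40629713251280525,
  "dT_E_right_mm": 0.8599802965505372,
  "dR_deg": 0.8776529046432597,
  ...
}
```

`success` means both labeled eyes were found within 1.2 × OD (16.8 mm at
31 weeks) of their true positions; here the brain centre is off by 0.42 mm,
the eyes by under a millimetre, and the recovered anatomical frame is
0.88° from the true head pose — comfortably below the ~3 mm voxel size.
`pose.json` carries the landmarks, the LR/PA/IS axes and the 4×4
world→anatomical transform a scanner would use to orient the next stack.

The same API is available in Python:

```python
from fetalpose import PhantomSpec, generate, detect_head_pose

vol, truth = generate(PhantomSpec(ga=31, seed=3))
result = detect_head_pose(vol, ga=31)
print(result.b, result.labels["left"], result.frame.lr)
```

Real scouts are read from NIfTI with `fetalpose detect scout.nii --ga 29`;
a custom biometry table (TSV: `ga_weeks ofd_mm bpd_mm od_mm`) can replace
the bundled growth curves via `--biometry`.

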