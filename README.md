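# sgdefaug

Structure-guided deformable augmentation and contour evaluation for 3D
labeled medical images.

Auto-segmentation of abdominal organs at risk (OARs) for MRI-guided
adaptive radiotherapy is chronically data-starved: a clinic may have only
a few dozen contoured volumes, far too few to train a robust 3D network.
`sgdefaug` implements a *structure-guided* deformation augmentation
(sgDefAug) that multiplies such a dataset tenfold by deforming each organ
individually — every organ in turn draws a random bounded displacement and
scaling, the motions are smoothed into displacement fields and composed
into one transform, and the image and its label map are each resampled
once through the result.  Because deformations are anchored to anatomy,
the synthetic variants look like plausible new patients rather than
randomly warped images.

The package also provides everything needed to use and evaluate the method
end-to-end with no patient data:

- **core_io / preprocess** — NIfTI volumes with LPS-mm geometry; overlap
  resolution (each contested voxel goes to the nearest structure),
  foreground cropping, Perona–Malik diffusion denoising, grid resizing,
  [-1, 1] intensity normalization.
- **sgdef** — the augmentation engine: bounded uniform transform sampling
  (default ±40 mm for displacement and extent change), per-structure
  displacement-field construction with 5 mm Gaussian smoothing, field
  composition and inversion, sequential multi-organ deformation with an
  automated plausibility guard, and dataset expansion (N → 10 N).
- **convaug** — the conventional baseline: random 240×240×80 patches,
  Rician/Gaussian noise, gamma contrast and intensity jitter, global
  elastic warps.
- **phantom** — a synthetic abdominal phantom with the 8 canonical OARs
  (duodenum, liver, left/right kidney, spleen, stomach, spinal canal,
  small bowel), MR-like contrast, bias field, Rician noise, and a
  synthetic dose grid (40 Gy in 5 fractions with Gaussian penumbra).
- **metrics_geom / dosimetry** — Dice and symmetric average surface
  distance (ASD); cumulative DVH curves, D2%/D50% extraction, and the
  three-way difference stratification (<1 % ✔, 1–5 % •, ≥5 % ✘).

## The model in brief

For organ *k* with mask *M\_k*, draw translation **t** ~ U(−L, L)³ and
per-axis extent changes δ\_a ~ U(−min(L, E\_a/2), L) (L = 40 mm, E\_a =
organ extent), giving scale factors s\_a = (E\_a + δ\_a)/E\_a about the
organ centroid **c**.  The affine motion Φ(x) = c + S(x − c) + t is
realized as a dense pull-back displacement field, exact on the moved organ
and tapered to zero over a 3σ collar by a Gaussian of σ = 5 mm.  Fields
from sequential organ steps compose as d(x) = d₁(x + d₂(x)) + d₂(x); the
original image (linear) and label map (nearest-neighbour) are resampled
once through the composite.  A volume-ratio guard (default [0.3, 3])
rejects and redraws transforms that would implausibly crush or inflate any
organ.

## Worked example

Generate a phantom, simulate auto-contours by mildly perturbing the ground
truth, and evaluate them geometrically and dosimetrically:

```python
import numpy as np
import sgdefaug as sg

img, ss = sg.generate_phantom(sg.PhantomSpec(seed=7))

# simulate auto-contours: a mild structure-guided perturbation of the truth
mild = sg.SgDefParams(displacement_limit_mm=3.0, scale_limit_mm=3.0, seed=7)
_, pred, record = sg.sgdef_augment(img, ss, mild, np.random.default_rng(7))

print(sg.evaluate_structure_sets(pred, ss).to_string(index=False))

dose = sg.generate_dose(img.geometry, sg.DoseSpec())
table, frac = sg.evaluate_dosimetry(dose, pred, ss, prescription_gy=40.0)
print(f"organs with both deltas < 1%: {frac:.3f}")
```

prints (abridged):

```
       organ  dice  asd_mm
    duodenum 0.543   2.643
       liver 0.915   1.612
 left_kidney 0.657   2.624
right_kidney 0.807   1.629
      spleen 0.792   1.540
     stomach 0.849   1.651
spinal_canal 0.701   1.420
 small_bowel 0.784   1.662
        mean 0.756   1.848

organs with both deltas < 1%: 0.500
```

Dice is volumetric overlap in [0, 1]; ASD is the mean surface-to-surface
distance in mm (lower is better).  The dosimetric summary is the fraction
of organs whose near-maximum (D2%) and median (D50%) dose both change by
less than 1 % when the dose plan is read through the perturbed contours
instead of the truth — small geometric errors on organs far from the dose
gradient are dosimetrically free, while the duodenum, hugging the target,
is not.

The same pipeline is scriptable from the shell:

```bash
sgdefaug phantom --n 43 --seed 1 --out-dir data/ --dose
sgdefaug augment expand --manifest data/manifest.csv --factor 10 --seed 1 --out-dir expanded/
sgdefaug evaluate geom --pred pred_labels.nii.gz --gt gt_labels.nii.gz --out metrics.csv
```

The expansion turns the 43 phantoms into 430 images (originals plus 9
deformed variants each), with a JSON provenance record per variant.

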