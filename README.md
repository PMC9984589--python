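# segrepeat

Repeatability analysis of repeated 3D muscle segmentations on clinical MRI.

## The problem

Skeletal-muscle volumes segmented slice-by-slice from MRI feed sarcopenia
assessment and subject-specific musculoskeletal models, and manual
segmentation is still the reference against which automatic methods are
validated. But how repeatable is the manual reference itself — and is the
segmentation error spread evenly over the muscle, or concentrated at the
extremities, where aponeuroses fade and contours are hard to call? This
package implements the analysis pipeline for answering those questions from
repeated binary segmentations of hip muscles (gluteus medius, iliopsoas),
and a synthetic phantom generator that makes the whole chain testable when
the underlying clinical images cannot be shared.

It is aimed at researchers quantifying intra-/inter-operator segmentation
variability and at developers of segmentation tools who need a principled,
fully reproducible reference analysis.

## The method

For each subject and muscle, with ≥2 repeated segmentations:

1. **Attachment morphing.** Muscle origin/insertion points are invisible on
   MRI, so they are transferred from a generic atlas: a 12-DOF affine
   `T(p) = Ap + t` is least-squares fitted (via SVD) to named bony-landmark
   pairs and applied to the atlas attachment points, optionally snapping
   them to a bone surface mesh.
2. **Sub-volume decomposition.** The origin–insertion line defines the
   muscle axis (length *L*). From the attachment mid-point, two parallel
   planes orthogonal to the axis move apart in 5 %·*L* steps; level *k*
   keeps the central 10·*k* % of the muscle length, level 10 being the
   complete segmentation. The iliopsoas is first standardized by removing
   its proximal end above the iliac-crest plane.
3. **Agreement metrics**, per level, averaged over all repeat pairs:
   - Jaccard index `JI = |A∩B| / |A∪B|` on the voxel masks;
   - maximal symmetric Hausdorff distance
     `HD = max( max_x min_y ‖x−y‖, max_y min_x ‖x−y‖ )` between the
     isosurface vertex sets (mm);
   - normalized volume variance `nVV = s²(V₁..Vₙ) / V̄ × 100`
     (a CoV variant `s/V̄ × 100` is also provided).
4. **Statistics.** Each metric's subjects × levels matrix is compared
   across levels with a normality-gated chain: Shapiro–Wilk per level, then
   one-way repeated-measures ANOVA + Bonferroni-corrected paired *t* tests
   (parametric) or Friedman + Wilcoxon signed-rank (nonparametric).
   Shrout–Fleiss ICC(1,1)/ICC(3,1) with F-based confidence intervals are
   available for agreement studies.

The phantom generator produces tube-like muscles on anisotropic grids
emulating coronal T1-weighted acquisitions (0.817 mm pixels, 4 mm slices)
and simulates re-segmentations by displacing each slice contour with a
smooth random field whose SD grows from the muscle belly toward the
extremities — so every stage can be verified against a known ground truth.

## Worked example

```python
from segrepeat import (PhantomSpec, NoiseModel, make_phantom,
                       simulate_repeats, cut_series, compare_repeats)

study = make_phantom(PhantomSpec(seed=4))
noise = NoiseModel(belly_sigma_mm=0.5, extremity_sigma_mm=3.0, seed=5)
repeats = simulate_repeats(study.truth, study.true_axis, noise, 3)
series = [cut_series(r, study.true_axis) for r in repeats]
for rec in compare_repeats(series, "demo", "gluteus_medius"):
    print(f"{rec.level_percent:>4d}%  {rec.ji_mean:.3f}  {rec.hd_mean_mm:6.2f}")
```

prints (abridged):

```
  10%  0.971    2.20
  50%  0.899    5.10
  70%  0.867    6.26
 100%  0.834    6.86
```

The Jaccard index falls and the Hausdorff distance rises as more of the
muscle is included: with extremity-weighted noise the muscle ends are the
least repeatable part, so full segmentations agree least — the central
belly region is the safest target when only partial coverage is feasible.
See `examples/` for one narrative script per capability (phantoms,
morphing, cutting, metrics, full study).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the complete synthetic study from scratch: 20 subjects per
muscle, 3 repeats each, attachment morphing, iliopsoas standardization,
ten-level decomposition, the JI/HD/nVV table (`mean (min, max)` per level)
and the omnibus statistics, printing the results and writing the JSON
result object to `--out`. `--seed` drives every source of randomness; the
run is deterministic given a seed.
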