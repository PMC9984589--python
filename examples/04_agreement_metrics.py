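"""Score agreement between repeated segmentations, level by level.

Three metrics per sub-volume level, averaged over the three repeat pairs
(1st vs 2nd, 2nd vs 3rd, 1st vs 3rd): Jaccard index (shape overlap, 1 =
identical), maximal Hausdorff distance (worst surface disagreement, mm) and
normalized volume variance (volumetric spread, %).
"""

from segrepeat import (
    NoiseModel,
    PhantomSpec,
    compare_repeats,
    cut_series,
    make_phantom,
    simulate_repeats,
)

study = make_phantom(PhantomSpec(seed=4))
noise = NoiseModel(belly_sigma_mm=0.5, extremity_sigma_mm=3.0, seed=5)
repeats = simulate_repeats(study.truth, study.true_axis, noise, 3)

series = [cut_series(r, study.true_axis) for r in repeats]
records = compare_repeats(series, subject_id="demo", muscle="gluteus_medius")

print("level    JI     HD_mm   nVV_%")
for rec in records:
    print(f"{rec.level_percent:>4d}%  {rec.ji_mean:.3f}  {rec.hd_mean_mm:>6.2f}  "
          f"{rec.nvv_percent:>8.1f}")
# JI falls and HD rises toward the full segmentation: the extremity-weighted
# noise makes the muscle ends the least repeatable part, as expected.
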