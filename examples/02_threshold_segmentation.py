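"""Semi-automatic IPH segmentation at the three muscle-referenced thresholds.

A voxel is IPH when its intensity exceeds 150%, 175% or 200% of the mean of
three sternocleidomastoid-muscle sample points, and its connected component
persists over at least two consecutive slices.
"""

from iphquant import (
    ThresholdCriterion, default_scm_roi, generate_subject,
    sample_muscle_reference, segment_iph,
)
from iphquant.phantom import PhantomConfig, IPHSpec

config = PhantomConfig(iph=IPHSpec(intensity_ratio=1.9), seed=7)
volume, truth = generate_subject(config)
roi = default_scm_roi(config)

ref = sample_muscle_reference(volume, roi)
print(f"muscle reference mean: {ref.mean:.1f} a.u. from points {ref.point_values}")
print(f"true IPH volume      : {truth.true_iph_volume:.2f} mm^3\n")
for ratio in (1.5, 1.75, 2.0):
    seg = segment_iph(volume, truth.plaque_mask, roi, ThresholdCriterion(ratio))
    m = seg.metrics
    print(f">{ratio * 100:.0f}% of muscle: total {m.total_volume:7.2f} mm^3 | "
          f"max axial {m.max_axial_volume:6.2f} mm^3 | length {m.length:4.1f} mm")
# With an IPH at 1.9x muscle, the 150%/175% thresholds recover the lesion
# while the 200% threshold truncates it - the mechanism behind the lower
# agreement of the strictest criterion.
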