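"""Measure the image-derived thrombus parameters on a synthetic microscopy field.

Builds one platelet field, a flow time series and a confocal z-stack with
known ground truth, then runs the standard quantification operators on them.
"""

import thromboquant as tq

# an end-stage field: 30 platelet features, ~10% coverage, default noise
scene = tq.gen_scene(30, seed=42, shape=(256, 256), mean_area=150)
mask, coverage = tq.segment_coverage(scene.pixel_grid)
features = tq.feature_areas(mask)
ifs = tq.integrated_feature_size(features)
score = tq.morphological_score(mask, features)

print(f"platelet deposition : {coverage:.2f}% (truth {100 * scene.truth_coverage:.2f}%)")
print(f"features found      : {features.n} (truth {len(scene.truth_features)})")
print(f"integrated feature size: {ifs:.1f} px (size-weighted mean feature area)")
print(f"morphological score : {score} / 5")

# a 1-min, 2-s-interval series in which half the deposited area is stable
series = tq.gen_series(scene, stable_fraction=0.5, seed=42)
stable = tq.stable_adhesion(series.frames)
truth = 100 * series.stable_mask.sum() / series.stable_mask.size
print(f"stable adhesion     : {stable:.2f}% of the field (truth {truth:.2f}%)")

# a 0.5-μm-spaced z-stack: volume per unit area = mean occupied height
stack = tq.gen_stack(seed=42)
volume = tq.thrombus_volume(stack.slices, stack.slice_spacing, stack.pixel_size)
print(f"thrombus volume     : {volume:.3f} μm³/μm² (truth {stack.truth_volume_per_area:.3f})")

# Coverage and volume should track their truths closely; the integrated
# feature size exceeds the mean feature area whenever aggregates dominate.
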