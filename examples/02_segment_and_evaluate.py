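"""Segment a dendrite by ellipse growth and score it against ground truth.

Also scores the naive 'straight dendrite' baseline (a 2-um chord between
the endpoints) to show why the curvature-following segmentation wins.
"""
import numpy as np

import dendrotrace as dt
from dendrotrace.synthetic import fixture_gallery

spec, stack, truth = fixture_gallery(seed=0)["curved_tube"]
frame = stack.frame(0, 0)
start, end = tuple(truth.centreline[0]), tuple(truth.centreline[-1])

path, _, _ = dt.trace_dendrite(frame, start, end)
edges = dt.detect_edges(frame)
profile = dt.compute_profile(path, edges)
seg = dt.build_mask(path, profile, frame.shape, stack=stack)

recall, precision, f1 = dt.evaluate_segmentation(seg.mask, truth.dendrite_mask)
print(f"mean width: {profile.widths.mean():.1f} px (truth {truth.widths.mean():.0f} px)")
print(f"segmentation recall {recall:.2f}, precision {precision:.2f}, F1 {f1:.2f}")

baseline = dt.straight_baseline(start, end, frame.shape, thickness_um=2.0,
                                pixel_size=spec.pixel_size)
_, _, f1_base = dt.evaluate_segmentation(baseline, truth.dendrite_mask)
print(f"straight-chord baseline F1 {f1_base:.2f}  (cannot follow the curve)")
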