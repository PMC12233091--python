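"""Trace a dendrite's medial axis on a synthetic curved tube.

Builds a noisy curved dendrite with known centreline, binarizes it,
runs the boundary-distance-weighted shortest path between the two
endpoints and prints how close the traced path stays to the truth.
"""
import numpy as np
from scipy import ndimage as ndi

import dendrotrace as dt
from dendrotrace.synthetic import DendriteSpec, FixtureSpec, render_fixture

spec = FixtureSpec(
    shape=(128, 128),
    dendrite=DendriteSpec([(100, 10), (72, 36), (52, 64), (72, 92), (100, 118)], width=10.0),
    snr=4.0,
    seed=0,
)
stack, truth = render_fixture(spec)
frame = stack.frame(0, 0)

path, mask, field = dt.trace_dendrite(frame, (100, 10), (100, 118))

line = np.zeros(frame.shape, bool)
line[truth.centreline[:, 0], truth.centreline[:, 1]] = True
deviation = ndi.distance_transform_edt(~line)[path.full_rank[:, 0], path.full_rank[:, 1]]

print(f"full-rank path: {len(path.full_rank)} pixels")
print(f"compressed to {len(path.control_points)} control points")
print(f"mean distance from true centreline: {deviation.mean():.2f} px")
# a sub-pixel mean deviation means the path hugs the middle of the tube,
# which is what the boundary-distance cost term is for
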