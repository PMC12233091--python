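"""Grow spine head ROIs from centre points and classify each spine.

Eight rays walk outward from each centre, counting rule violations
(luminosity drop-off, other-spine proximity, dendrite intersection,
fall-back extent); their terminal points form an octagonal head ROI.
The neck is traced with the medial-axis machinery and the neck/head
width ratio assigns stubby / mushroom / thin / outlier.
"""
import dendrotrace as dt
from dendrotrace.synthetic import DendriteSpec, FixtureSpec, SpineSpec, render_fixture

# a clean six-spine scene spanning all four morphology classes
spec = FixtureSpec(
    shape=(160, 160),
    dendrite=DendriteSpec([(80, 8), (80, 152)], width=10.0),
    spines=[
        SpineSpec((71, 20), 5.0, 0, 0),    # stubby: flush with the shaft
        SpineSpec((61, 45), 6.0, 8, 2),    # mushroom: big head, thin neck
        SpineSpec((99, 70), 5.0, 8, 3),    # mushroom
        SpineSpec((62, 95), 4.0, 9, 6),    # thin: neck almost as wide as head
        SpineSpec((98, 120), 4.0, 8, 7),   # thin
        SpineSpec((64, 140), 3.0, 10, 8),  # outlier: neck wider than head
    ],
    snr=None,
    seed=0,
)
stack, truth = render_fixture(spec)
frame = stack.frame(0, 0)

path, _, _ = dt.trace_dendrite(frame, (80, 8), (80, 152))
seg = dt.build_mask(path, dt.compute_profile(path, dt.detect_edges(frame)), frame.shape)

centers = [dt.SpineCenter(s.center) for s in spec.spines]
for i, center in enumerate(centers):
    rec = dt.build_spine_record(stack, center, centers, seg.mask)
    nw = rec.neck.neck_width if rec.neck else 0.0
    print(
        f"spine {i} at {center.s0}: head width {rec.head_width:.1f} px, "
        f"neck width {nw:.1f} px -> {rec.class_label} (intended {truth.spine_classes[i]})"
    )
# NW/HW < 0.5 is a mushroom, 0.5..1.1 thin, > 1.1 an outlier; NW = 0 stubby
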