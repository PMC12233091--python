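"""Count fluorescent puncta inside a soma polygon and along a dendrite.

Each ROI gets its own adaptive LoG threshold tR = max(ROI) * gamma/100;
dendrites are scanned through local rectangles along the medial axis and
every punctum is tagged with its arclength position.
"""
import dendrotrace as dt
import dendrotrace.spine_analysis as sa
from dendrotrace.synthetic import fixture_gallery

spec, stack, truth = fixture_gallery(seed=0)["puncta_field"]
img = stack.frame(0, 0)

soma_roi = sa._mask_to_polygon(truth.spine_masks[0])
path, _, _ = dt.trace_dendrite(img, tuple(truth.centreline[0]), tuple(truth.centreline[-1]))
profile = dt.compute_profile(path, dt.detect_edges(img))

policy = dt.ThresholdPolicy(gamma_synapse=30.0, gamma_dendrite=30.0,
                            min_sigma=1.0, max_sigma=5.0)
soma = dt.detect_in_polygon(img, soma_roi, policy, roi_id="soma")
dend = dt.detect_in_dendrite(img, path, profile, policy, roi_id="dendrite")

print(f"somatic puncta: {len(soma)} (truth 8)")
print(f"dendritic puncta: {len(dend)} (truth 2) at arclengths",
      [round(p.arclength, 1) for p in dend])
frac = dt.localization_fractions(soma + dend, {"soma": "soma", "dendrite": "neurite"})
print("soma/neurite localization fractions:", frac["fractions"][0])
# the fractions mirror the classic smFISH readout: what share of the
# transcript pool sits in the soma versus out in the neurites
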