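"""Run the complete workflow on a six-spine scene and inspect the bundle.

Dendrite tracing -> segmentation -> spine ROIs, necks, classes,
backgrounds -> puncta -> CSV/JSON/PNG/.roi export, with the resolved
config written next to the outputs for exact re-runs.
"""
from pathlib import Path

import dendrotrace as dt
from dendrotrace.synthetic import fixture_gallery

spec, stack, truth = fixture_gallery(seed=0)["four_class_spines"]
cfg = dt.AnalysisConfig(
    dendrite_endpoints=[[[80, 8], [80, 152]]],
    spine_centers=[list(s.center) for s in spec.spines],
    pixel_size=spec.pixel_size,
)
outdir = Path("scratch/example_bundle")
results = dt.run_pipeline(cfg, outdir, stack=stack)

print(f"dendrites segmented: {len(results['dendrites'])}")
print(f"spine records: {len(results['spines'])}")
print(f"puncta found: {len(results['puncta'])}")
print("bundle files:", sorted(p.name for p in outdir.iterdir())[:8], "...")
# rerunning with outdir/resolved_config.json reproduces every table byte-for-byte
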