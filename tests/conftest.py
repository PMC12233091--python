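import numpy as np
import pytest

import dendrotrace as dt
from dendrotrace.synthetic import fixture_gallery


@pytest.fixture(scope="session")
def gallery():
    """The canonical synthetic scene collection, rendered once per run."""
    return fixture_gallery(seed=0)


@pytest.fixture(scope="session")
def segment_dendrite():
    """Run the full dendrite stage (trace + edges + profile + mask) on a fixture."""

    def _run(stack, truth, **overrides):
        frame = stack.frame(0, 0)
        start = tuple(int(v) for v in truth.centreline[0])
        end = tuple(int(v) for v in truth.centreline[-1])
        path, bm, fld = dt.trace_dendrite(frame, start, end)
        edges = dt.detect_edges(frame)
        profile = dt.compute_profile(path, edges, **overrides)
        seg = dt.build_mask(path, profile, frame.shape, stack=stack)
        return path, profile, seg

    return _run


@pytest.fixture()
def gaussian_spot():
    """Isolated Gaussian intensity spot (sigma 3, peak 100, zero background)."""
    rr, cc = np.mgrid[:41, :41]
    return 100.0 * np.exp(-((rr - 20) ** 2 + (cc - 20) ** 2) / (2 * 3.0**2))
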