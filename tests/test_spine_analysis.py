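import numpy as np
import pytest

import dendrotrace as dt
import dendrotrace.spine_analysis as sa
from dendrotrace.synthetic import DendriteSpec, FixtureSpec, SpineSpec, render_fixture


class TestFilterDetections:
    def test_threshold_filter(self):
        cands = [sa.SpineCenter((1, 1), c) for c in (0.3, 0.6, 0.9)]
        assert len(sa.filter_detections(cands, 0.5)) == 2

    def test_zero_threshold_keeps_all(self):
        cands = [sa.SpineCenter((1, 1), c) for c in (0.0, 0.5, 1.0)]
        assert sa.filter_detections(cands, 0.0) == cands

    def test_unit_threshold_keeps_only_manual(self):
        cands = [sa.SpineCenter((1, 1), 0.99), sa.SpineCenter((2, 2), 1.0)]
        kept = sa.filter_detections(cands, 1.0)
        assert [c.confidence for c in kept] == [1.0]

    def test_detector_contract_adapts_callables(self):
        detector = lambda img: [((3.0, 4.0), 0.8), ((5.0, 6.0), 0.2)]
        centers = sa.run_detector(detector, np.zeros((10, 10)))
        assert [c.s0 for c in centers] == [(3.0, 4.0), (5.0, 6.0)]


class TestGrowSpineRoi:
    def test_gaussian_spot_octagon_radii_near_fwhm(self, gaussian_spot):
        roi = sa.grow_spine_roi(
            gaussian_spot,
            (20, 20),
            params=sa.RuleParams(drop_factor=0.5, n=1, max_extent=15),
        )
        radii = np.linalg.norm(roi.vertices - [20, 20], axis=1)
        target = 3.0 * np.sqrt(2 * np.log(2))  # half-intensity radius of sigma=3
        assert len(roi.vertices) == 8
        assert np.all(np.abs(radii - target) <= 1.0)

    def test_other_spine_rule_stops_at_bisector(self):
        flat = np.full((41, 41), 10.0)
        roi = sa.grow_spine_roi(
            flat,
            (20, 20),
            all_centers=[sa.SpineCenter((20, 26))],
            params=sa.RuleParams(drop_factor=0.0, n=1, max_extent=15),
        )
        east = roi.vertices[2]  # E direction
        assert np.linalg.norm(east - [20, 20]) <= 3.0

    def test_fallback_rule_yields_regular_octagon(self):
        flat = np.full((41, 41), 10.0)
        roi = sa.grow_spine_roi(
            flat, (20, 20), params=sa.RuleParams(drop_factor=0.0, n=1, max_extent=10)
        )
        radii = np.linalg.norm(roi.vertices - [20, 20], axis=1)
        assert np.allclose(radii, 10.0)

    def test_dendrite_rule_blocks_rays(self):
        flat = np.full((41, 41), 10.0)
        dend = np.zeros((41, 41), bool)
        dend[26:, :] = True  # wall 6 px south of the seed
        roi = sa.grow_spine_roi(
            flat, (20, 20), dendrite_mask=dend,
            params=sa.RuleParams(drop_factor=0.0, n=1, max_extent=10),
        )
        south = roi.vertices[4]
        assert south[0] <= 25

    def test_seed_outside_image_raises(self):
        with pytest.raises(ValueError):
            sa.grow_spine_roi(np.ones((10, 10)), (20, 20))

    def test_zero_luminosity_seed_raises(self):
        with pytest.raises(ValueError, match="degenerate seed"):
            sa.grow_spine_roi(np.zeros((10, 10)), (5, 5))

    def test_ray_independence_under_local_perturbation(self, gaussian_spot):
        """Halting one ray early (by darkening pixels strictly on its axis)
        never moves any other ray's terminal point: the counters are
        independent per direction."""
        params = sa.RuleParams(drop_factor=0.5, n=1, max_extent=15, ray_filter_size=1)
        base = sa.grow_spine_roi(gaussian_spot, (20, 20), params=params)
        altered = gaussian_spot.copy()
        altered[20, 23:] = 0.0  # kill the E ray beyond radius 2
        blocked = sa.grow_spine_roi(altered, (20, 20), params=params)
        east = np.linalg.norm(blocked.vertices[2] - [20, 20])
        assert east < np.linalg.norm(base.vertices[2] - [20, 20])
        for d in range(8):
            if d == 2:
                continue
            assert np.allclose(base.vertices[d], blocked.vertices[d])

    def test_drop_factor_monotonicity(self, gaussian_spot):
        """A more permissive (smaller) drop factor never shrinks a ray."""
        radii = {}
        for f in (0.7, 0.5, 0.3):
            roi = sa.grow_spine_roi(
                gaussian_spot, (20, 20), params=sa.RuleParams(drop_factor=f, n=1, max_extent=18)
            )
            radii[f] = np.linalg.norm(roi.vertices - [20, 20], axis=1)
        assert np.all(radii[0.5] >= radii[0.7] - 1e-9)
        assert np.all(radii[0.3] >= radii[0.5] - 1e-9)


class TestAveragePerturbedRois:
    def test_symmetric_spot_average_matches_single(self, gaussian_spot):
        params = sa.RuleParams(drop_factor=0.5, n=1, max_extent=15)
        single = sa.grow_spine_roi(gaussian_spot, (20, 20), params=params)
        avg = sa.average_perturbed_rois(gaussian_spot, (20, 20), params=params)
        assert np.abs(avg.vertices - single.vertices).max() <= 0.5

    def test_five_polygons_averaged_on_interior_seed(self, gaussian_spot, monkeypatch):
        calls = []
        orig = sa._grow_rays

        def counting(*a, **k):
            calls.append(1)
            return orig(*a, **k)

        monkeypatch.setattr(sa, "_grow_rays", counting)
        sa.average_perturbed_rois(
            gaussian_spot, (20, 20), params=sa.RuleParams(drop_factor=0.5, n=1, max_extent=15)
        )
        assert len(calls) == 5

    def test_corner_seed_skips_out_of_bounds_candidates(self):
        img = np.full((30, 30), 50.0)
        roi = sa.average_perturbed_rois(
            img, (0, 0), params=sa.RuleParams(drop_factor=0.0, n=1, max_extent=5)
        )
        assert len(roi.vertices) == 8  # no error, averaged over in-bounds seeds


class TestBackground:
    def test_background_abuts_spine_without_overlap(self):
        spine = dt.RoiPolygon([(20, 20), (20, 30), (30, 30), (30, 20)])
        occupied = spine.rasterize((100, 100))
        bg = sa.place_background(spine, occupied, (100, 100))
        assert not (bg.rasterize((100, 100)) & occupied).any()
        assert np.linalg.norm(bg.centroid() - spine.centroid()) <= 25

    def test_fully_occupied_frame_raises(self):
        spine = dt.RoiPolygon([(5, 5), (5, 10), (10, 10), (10, 5)])
        with pytest.raises(ValueError, match="background"):
            sa.place_background(spine, np.ones((30, 30), bool), (30, 30))

    def test_background_mean_on_constant_field(self):
        img = np.full((100, 100), 50.0)
        spine = dt.RoiPolygon([(20, 20), (20, 30), (30, 30), (30, 20)])
        occupied = spine.rasterize((100, 100))
        bg = sa.place_background(spine, occupied, (100, 100))
        assert img[bg.rasterize((100, 100))].mean() == 50.0


@pytest.fixture(scope="module")
def mushroom_scene():
    """Clean mushroom spine: head disc r=6 joined to a 10-px tube by a
    2-px-wide bridge with an 8-px free span."""
    spec = FixtureSpec(
        shape=(96, 96),
        dendrite=DendriteSpec([(60, 4), (60, 92)], width=10.0),
        spines=[SpineSpec((41, 48), head_radius=6.0, neck_length=8.0, neck_width=2.0)],
        snr=None,
        seed=0,
    )
    stack, truth = render_fixture(spec)
    frame = stack.frame(0, 0)
    path, _, _ = dt.trace_dendrite(frame, (60, 4), (60, 92))
    seg = dt.build_mask(
        path, dt.compute_profile(path, dt.detect_edges(frame)), frame.shape
    )
    return stack, truth, frame, seg


class TestTraceNeck:
    def test_mushroom_bridge_geometry(self, mushroom_scene):
        stack, truth, frame, seg = mushroom_scene
        center = sa.SpineCenter((41, 48))
        head = sa.average_perturbed_rois(frame, center, [center], seg.mask)
        neck = sa.trace_neck(frame, center, head, seg.mask)
        assert neck is not None
        assert neck.length_px == pytest.approx(8, abs=2)
        # the 2-px nominal bridge rasterizes to 3 pixel columns
        assert neck.neck_width == pytest.approx(3, abs=1)

    def test_neck_mask_never_overlaps_head(self, mushroom_scene):
        stack, truth, frame, seg = mushroom_scene
        center = sa.SpineCenter((41, 48))
        head = sa.average_perturbed_rois(frame, center, [center], seg.mask)
        neck = sa.trace_neck(frame, center, head, seg.mask)
        assert not (neck.mask & head.rasterize(frame.shape)).any()

    def test_center_inside_dendrite_reports_absence(self, mushroom_scene):
        stack, truth, frame, seg = mushroom_scene
        center = sa.SpineCenter((60, 48))  # on the tube itself
        head = dt.RoiPolygon([(55, 44), (55, 52), (65, 52), (65, 44)])
        assert sa.trace_neck(frame, center, head, seg.mask) is None


class TestClassifySpine:
    @pytest.mark.parametrize(
        "nw,hw,label",
        [
            (0.0, 10.0, "stubby"),
            (3.0, 10.0, "mushroom"),
            (8.0, 10.0, "thin"),
            (12.0, 10.0, "outlier"),
            (5.0, 10.0, "thin"),  # boundary 0.5 inclusive
            (11.0, 10.0, "thin"),  # boundary 1.1 inclusive
        ],
    )
    def test_published_boundaries(self, nw, hw, label):
        assert sa.classify_spine(nw, hw) == label

    def test_partition_is_exhaustive_and_exclusive(self):
        """Every (NW >= 0, HW > 0) pair maps to exactly one of 4 labels."""
        labels = set()
        for nw in np.linspace(0, 30, 121):
            for hw in np.linspace(0.5, 20, 40):
                lab = sa.classify_spine(nw, hw)
                assert lab in sa.CLASS_LABELS
                labels.add(lab)
        assert labels == set(sa.CLASS_LABELS)

    def test_invalid_head_width_raises(self):
        with pytest.raises(ValueError):
            sa.classify_spine(1.0, 0.0)

    def test_four_class_scene_recovered_end_to_end(self):
        """On a clean six-spine scene the full pipeline estimate of NW/HW
        reproduces every intended morphology class."""
        sp = [
            SpineSpec((71, 20), 5.0, 0, 0),
            SpineSpec((61, 45), 6.0, 8, 2),
            SpineSpec((99, 70), 5.0, 8, 3),
            SpineSpec((62, 95), 4.0, 9, 6),
            SpineSpec((98, 120), 4.0, 8, 7),
            SpineSpec((64, 140), 3.0, 10, 8),
        ]
        spec = FixtureSpec(
            shape=(160, 160),
            dendrite=DendriteSpec([(80, 8), (80, 152)], width=10.0),
            spines=sp,
            snr=None,
            seed=0,
        )
        stack, truth = render_fixture(spec)
        frame = stack.frame(0, 0)
        path, _, _ = dt.trace_dendrite(frame, (80, 8), (80, 152))
        seg = dt.build_mask(
            path, dt.compute_profile(path, dt.detect_edges(frame)), frame.shape
        )
        centers = [sa.SpineCenter(s.center) for s in sp]
        got = [
            dt.build_spine_record(stack, c, centers, seg.mask).class_label
            for c in centers
        ]
        assert got == truth.spine_classes


class TestSpineStats:
    def test_constant_roi_statistics(self):
        img = np.full((60, 60), 42.0)
        stack = dt.ImageStack(img[None, None], pixel_size=0.2)
        roi = dt.RoiPolygon([(10, 10), (10, 20), (20, 20), (20, 10)])
        rec = sa.SpineRecord(center=sa.SpineCenter((15, 15)), head_rois=[roi])
        rec.background_roi = roi.translated(25, 0)
        rows = sa.spine_stats(rec, stack)
        assert rows[0]["mean_luminosity"] == 42.0
        assert rows[0]["corrected_luminosity"] == 0.0
        assert rows[0]["area_um2"] == pytest.approx(rows[0]["area_px2"] * 0.04)

    def test_luminosity_mode_tracks_brightening(self):
        frames = np.stack([np.full((40, 40), v) for v in (10.0, 20.0, 30.0)])
        stack = dt.ImageStack(frames[:, None])
        roi = dt.RoiPolygon([(10, 10), (10, 20), (20, 20), (20, 10)])
        rec = sa.SpineRecord(center=sa.SpineCenter((15, 15)), head_rois=[roi])
        rows = sa.spine_stats(rec, stack)
        series = [r["mean_luminosity"] for r in rows]
        assert series == sorted(series) and series[0] < series[-1]

    def test_area_mode_one_roi_per_timepoint(self):
        spec = FixtureSpec(
            shape=(64, 64),
            n_timepoints=3,
            spines=[SpineSpec((32, 32), head_radius=5.0)],
            snr=None,
            seed=0,
        )
        stack, _ = render_fixture(spec)
        rec = dt.build_spine_record(
            stack, sa.SpineCenter((32, 32)), mode="area", trace_necks=False
        )
        assert len(rec.head_rois) == stack.n_timepoints

    def test_luminosity_mode_single_roi(self):
        spec = FixtureSpec(
            shape=(64, 64),
            n_timepoints=3,
            spines=[SpineSpec((32, 32), head_radius=5.0)],
            snr=None,
            seed=0,
        )
        stack, _ = render_fixture(spec)
        rec = dt.build_spine_record(
            stack, sa.SpineCenter((32, 32)), mode="luminosity", trace_necks=False
        )
        assert len(rec.head_rois) == 1


class TestHeadRoiQuality:
    def test_head_recall_precision_on_noisy_scene(self, gallery):
        """Averaged octagon ROIs recover the disc ground truth at SNR 3."""
        spec, stack, truth = gallery["snr_3"]
        frame = stack.frame(0, 0)
        path, _, _ = dt.trace_dendrite(frame, (64, 8), (64, 120))
        seg = dt.build_mask(
            path, dt.compute_profile(path, dt.detect_edges(frame)), frame.shape
        )
        centers = [sa.SpineCenter(s.center) for s in spec.spines]
        recalls, precisions = [], []
        for i, c in enumerate(centers):
            roi = sa.average_perturbed_rois(frame, c, centers, seg.mask)
            r, p, _ = dt.evaluate_segmentation(
                roi.rasterize(frame.shape), truth.spine_masks[i]
            )
            recalls.append(r)
            precisions.append(p)
        assert np.mean(recalls) >= 0.7
        assert np.mean(precisions) >= 0.7

    def test_crowded_pair_rois_stay_separated(self, gallery):
        spec, stack, truth = gallery["crowded_pair"]
        frame = stack.frame(0, 0)
        centers = [sa.SpineCenter(s.center) for s in spec.spines]
        r0 = sa.average_perturbed_rois(frame, centers[0], centers)
        r1 = sa.average_perturbed_rois(frame, centers[1], centers)
        # each ROI's centroid stays on its own side of the 6-px bisector
        assert r0.centroid()[1] < (45 + 51) / 2 + 0.5
        assert r1.centroid()[1] > (45 + 51) / 2 - 0.5


class TestEditability:
    def test_vertex_move_insert_delete_revalidate(self):
        roi = dt.RoiPolygon([(0, 0), (0, 10), (10, 10), (10, 0)])
        moved = dt.RoiPolygon(np.vstack([roi.vertices[:3], [(12, -1)]]))
        assert len(moved.vertices) == 4
        inserted = dt.RoiPolygon(np.vstack([roi.vertices, [(5, -2)]]))
        assert len(inserted.vertices) == 5
        deleted = dt.RoiPolygon(roi.vertices[:3])
        assert len(deleted.vertices) == 3
        with pytest.raises(ValueError):
            dt.RoiPolygon(roi.vertices[:2])
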