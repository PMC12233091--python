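"""Spine ROI generation, neck tracing, classification and statistics.

From a point interior to a spine, s0, eight rays step outward along the
cardinal and ordinal directions, s_{i,d} = s0 + i * v_d.  Each ray keeps
a rule-violation counter c_d; the rules (luminosity drop-off, other-spine
proximity, dendrite intersection, fall-back extent) each increment the
counter once per violating step, and the ray halts where c_d reaches n.
The eight terminal points form an octagonal head ROI; averaging that
octagon with four seed-perturbed copies desensitizes it to the exact
click position.  The neck reuses the medial-axis machinery on a crop
between the spine centre and the nearest dendrite pixel, and the
NW/HW (neck-width / head-width) ratio assigns the morphological class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from . import dendrite_geometry, medial_axis
from .image_io import ImageStack, RoiPolygon, SegmentedLineRoi

#: unit ray directions N, NE, E, SE, S, SW, W, NW in (row, col), row axis down;
#: diagonals are Euclidean-normalized so step i sits at radius i in every direction
DIRECTIONS = np.array(
    [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)], dtype=float
)
DIRECTIONS /= np.linalg.norm(DIRECTIONS, axis=1, keepdims=True)

CLASS_LABELS = ("stubby", "mushroom", "thin", "outlier")

#: NW/HW boundary below which a necked spine is a mushroom
MUSHROOM_THIN_BOUNDARY = 0.5
#: NW/HW boundary above which a spine is an outlier
THIN_OUTLIER_BOUNDARY = 1.1


@dataclass
class SpineCenter:
    s0: tuple[int, int]
    confidence: float = 1.0
    flagged: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")


@dataclass
class RuleParams:
    """Tunables of the ray-growth rules (all overridable in config)."""

    drop_factor: float = 0.4  # luminosity drop-off fraction of l0
    n: int = 2  # violations required to halt a ray
    max_extent: int = 30  # fall-back radius in px
    ray_filter_size: int = 3  # median window for the luminosity lookups


@dataclass
class NeckResult:
    path: SegmentedLineRoi
    roi: RoiPolygon | None
    mask: np.ndarray
    length_px: float
    neck_width: float


@dataclass
class SpineRecord:
    center: SpineCenter
    head_rois: list[RoiPolygon]
    mode: str = "luminosity"  # or "area"
    neck: NeckResult | None = None
    background_roi: RoiPolygon | None = None
    local_shifts: np.ndarray | None = None  # (T, 2)
    compensatory: np.ndarray | None = None  # (T, 2)
    class_label: str | None = None
    head_width: float | None = None
    stats: list[dict] = field(default_factory=list)

    def head_roi_at(self, t: int) -> RoiPolygon:
        roi = self.head_rois[t] if self.mode == "area" else self.head_rois[0]
        shift = np.zeros(2)
        if self.local_shifts is not None:
            shift += self.local_shifts[t]
        if self.compensatory is not None:
            shift += self.compensatory[t]
        return roi.translated(*shift) if np.any(shift) else roi

    def total_shift(self, t: int) -> np.ndarray:
        shift = np.zeros(2)
        if self.local_shifts is not None:
            shift += self.local_shifts[t]
        if self.compensatory is not None:
            shift += self.compensatory[t]
        return shift


# ---------------------------------------------------------------------------
# detection filtering (pluggable detector contract)
# ---------------------------------------------------------------------------


def filter_detections(
    candidates: list[SpineCenter], min_confidence: float
) -> list[SpineCenter]:
    """Keep candidates at or above the confidence threshold.

    Manual centres carry confidence 1.0 and therefore always survive.
    Order is preserved.
    """
    return [c for c in candidates if c.confidence >= min_confidence]


def run_detector(detector, image: np.ndarray) -> list[SpineCenter]:
    """Adapt any callable ``image -> [(center, confidence), ...]``.

    This is the pluggable contract replacing a bundled learned detector:
    anything that takes a 2D image and returns (row, col) locations with
    confidences can supply spine candidates.
    """
    return [
        SpineCenter(s0=(float(p[0]), float(p[1])), confidence=float(conf))
        for p, conf in detector(image)
    ]


# ---------------------------------------------------------------------------
# ray growth
# ---------------------------------------------------------------------------


def _grow_rays(
    image: np.ndarray,
    s0: np.ndarray,
    other_centers: np.ndarray,
    dendrite_mask: np.ndarray | None,
    params: RuleParams,
) -> np.ndarray:
    """Terminal point of each of the eight rays (rows of an (8, 2) array)."""
    h, w = image.shape
    l0 = float(image[int(round(s0[0])), int(round(s0[1]))])
    if l0 <= 0:
        raise ValueError(f"degenerate seed: luminosity at {tuple(s0)} is not > 0")
    terminals = np.zeros((8, 2))
    for d, v in enumerate(DIRECTIONS):
        c_d = 0
        i = 0
        prev = np.array(s0, dtype=float)  # last accepted point = ROI edge so far
        while True:
            i += 1
            p = s0 + i * v
            ri, ci = int(round(p[0])), int(round(p[1]))
            if not (0 <= ri < h and 0 <= ci < w):
                break  # image border halts the ray at the last in-bounds point
            violations = 0
            if image[ri, ci] < params.drop_factor * l0:
                violations += 1
            if len(other_centers):
                d_own = np.linalg.norm(p - s0)
                d_other = np.linalg.norm(other_centers - p, axis=1).min()
                if d_other < d_own:
                    violations += 1
            if dendrite_mask is not None and dendrite_mask[ri, ci]:
                violations += 1
            if i > params.max_extent:
                violations += 1
            c_d += violations
            if c_d >= params.n:
                break
            prev = p
        terminals[d] = prev
    return terminals


def grow_spine_roi(
    image: np.ndarray,
    s0: SpineCenter | tuple[int, int],
    all_centers: list[SpineCenter] | None = None,
    dendrite_mask: np.ndarray | None = None,
    params: RuleParams | None = None,
) -> RoiPolygon:
    """Grow the octagonal head ROI from a single seed point."""
    params = params or RuleParams()
    seed = np.asarray(s0.s0 if isinstance(s0, SpineCenter) else s0, dtype=float)
    h, w = image.shape
    if not (0 <= seed[0] < h and 0 <= seed[1] < w):
        raise ValueError(f"spine centre {tuple(seed)} outside image")
    others = _other_center_array(seed, all_centers)
    terminals = _grow_rays(_ray_image(image, params), seed, others, dendrite_mask, params)
    return RoiPolygon(terminals)


def _ray_image(image: np.ndarray, params: RuleParams) -> np.ndarray:
    """Denoised view for the luminosity rules (single noisy pixels should
    not halt or extend a ray)."""
    if params.ray_filter_size and params.ray_filter_size > 1:
        return ndi.median_filter(np.asarray(image, float), size=params.ray_filter_size)
    return np.asarray(image, float)


def _other_center_array(
    seed: np.ndarray, all_centers: list[SpineCenter] | None
) -> np.ndarray:
    if not all_centers:
        return np.empty((0, 2))
    pts = np.array(
        [c.s0 if isinstance(c, SpineCenter) else c for c in all_centers], dtype=float
    )
    keep = np.linalg.norm(pts - seed, axis=1) > 1e-9
    return pts[keep]


def average_perturbed_rois(
    image: np.ndarray,
    s0: SpineCenter | tuple[int, int],
    all_centers: list[SpineCenter] | None = None,
    dendrite_mask: np.ndarray | None = None,
    params: RuleParams | None = None,
) -> RoiPolygon:
    """Vertex-wise mean of five seed candidates (centre +/- 1 px N/S/E/W).

    Perturbed seeds that fall outside the image or onto zero luminosity
    are skipped; the average runs over the surviving polygons (>= 1).
    """
    params = params or RuleParams()
    seed = np.asarray(s0.s0 if isinstance(s0, SpineCenter) else s0, dtype=float)
    h, w = image.shape
    others = _other_center_array(seed, all_centers)
    filtered = _ray_image(image, params)
    polys = []
    for off in [(0, 0), (-1, 0), (1, 0), (0, -1), (0, 1)]:
        p = seed + off
        ri, ci = int(round(p[0])), int(round(p[1]))
        if not (0 <= ri < h and 0 <= ci < w):
            continue
        if filtered[ri, ci] <= 0:
            continue
        polys.append(_grow_rays(filtered, p, others, dendrite_mask, params))
    if not polys:
        raise ValueError("no valid seed among the five candidates")
    return RoiPolygon(np.mean(polys, axis=0))


# ---------------------------------------------------------------------------
# background placement
# ---------------------------------------------------------------------------


def place_background(
    spine_roi: RoiPolygon,
    occupied: np.ndarray,
    image_shape: tuple[int, int],
    start_scale: float = 1.5,
    step: float = 2.0,
    max_radius: float = 50.0,
) -> RoiPolygon:
    """Translate a copy of the head ROI to the nearest unoccupied spot.

    Candidate positions spiral outward from 1.5x the head circumradius in
    2 px increments; the first translated copy that stays in bounds and
    does not intersect ``occupied`` (all ROIs plus the dendrite mask) is
    the local-background ROI.
    """
    center = spine_roi.centroid()
    radius = start_scale * max(spine_roi.circumradius(), 1.0)
    while radius <= max_radius:
        n_angles = max(8, int(np.ceil(2 * np.pi * radius / step)))
        for ang in np.linspace(0, 2 * np.pi, n_angles, endpoint=False):
            offset = radius * np.array([np.sin(ang), np.cos(ang)])
            cand = spine_roi.translated(*offset)
            v = cand.vertices
            if v[:, 0].min() < 0 or v[:, 1].min() < 0:
                continue
            if v[:, 0].max() > image_shape[0] - 1 or v[:, 1].max() > image_shape[1] - 1:
                continue
            raster = cand.rasterize(image_shape)
            if not (raster & occupied).any():
                return cand
        radius += step
    raise ValueError("no unoccupied background position within search radius")


# ---------------------------------------------------------------------------
# neck tracing
# ---------------------------------------------------------------------------


def trace_neck(
    image: np.ndarray,
    s0: SpineCenter | tuple[int, int],
    head_roi: RoiPolygon,
    dendrite_mask: np.ndarray,
    filter_size: int = 3,
    threshold: float | str = "mean",
    min_length: float = 3.0,
    pad: int = 20,
) -> NeckResult | None:
    """Trace and segment the spine neck; ``None`` marks a failed attempt.

    The medial-axis machinery runs on a small crop between the spine
    centre and the nearest dendrite pixel.  Absence (not an error) is
    reported when the centre already lies on the dendrite, when no
    admissible path exists (unilluminated neck), or when the path is
    shorter than ``min_length`` (spine flush with the dendrite).  Head
    pixels are removed from the returned neck ROI.
    """
    seed = np.asarray(s0.s0 if isinstance(s0, SpineCenter) else s0, dtype=float)
    sr, sc = int(round(seed[0])), int(round(seed[1]))
    h, w = image.shape
    if dendrite_mask[sr, sc]:
        return None
    _, (ir, ic) = ndi.distance_transform_edt(~dendrite_mask, return_indices=True)
    target = np.array([ir[sr, sc], ic[sr, sc]])

    r0 = max(0, min(sr, target[0]) - pad)
    r1 = min(h, max(sr, target[0]) + pad + 1)
    c0 = max(0, min(sc, target[1]) - pad)
    c1 = min(w, max(sc, target[1]) + pad + 1)
    crop = image[r0:r1, c0:c1]
    try:
        bm = medial_axis.binarize(crop, filter_size=filter_size, threshold=threshold)
        if not bm.mask.any():
            return None
        fld = medial_axis.build_cost_field(bm)
        path = medial_axis.shortest_path(
            fld, (sr - r0, sc - c0), (target[0] - r0, target[1] - c0), tolerance=1.0
        )
    except (ValueError, medial_axis.UnreachableError):
        return None
    full = path.full_rank + np.array([r0, c0])
    # the neck proper is the path portion outside both head and dendrite
    head_mask = head_roi.rasterize((h, w))
    outside = ~head_mask[full[:, 0], full[:, 1]] & ~dendrite_mask[full[:, 0], full[:, 1]]
    if not outside.any():
        return None
    steps = np.hypot(*np.diff(full, axis=0).T) if len(full) > 1 else np.array([])
    length = float(steps[outside[:-1] & outside[1:]].sum()) if len(steps) else 0.0
    if length < min_length:
        return None

    # gentler hysteresis quantiles: the faint neck sides must survive next
    # to the much stronger head/dendrite boundaries in the same crop
    edges = dendrite_geometry.detect_edges(
        crop, gaussian_sigma=1.0, filter_size=filter_size, threshold=threshold,
        low_quantile=0.30, high_quantile=0.70,
    )
    # no continuity clamp here: the neck profile is short and its width
    # readout is already a median over the free-standing portion
    profile = dendrite_geometry.compute_profile(
        path, edges, semi_minor=1.0, max_semi_major=8.0, smoothing_strength=np.inf
    )
    seg = dendrite_geometry.build_mask(path, profile, crop.shape)
    neck_mask = np.zeros((h, w), dtype=bool)
    neck_mask[r0:r1, c0:c1] = seg.mask
    neck_mask &= ~head_mask  # zero overlap with the head ROI
    roi = _mask_to_polygon(neck_mask)
    neck_width = float(np.median(profile.widths[outside]))
    return NeckResult(
        path=SegmentedLineRoi(full, widths=profile.widths / 2.0),
        roi=roi,
        mask=neck_mask,
        length_px=length,
        neck_width=neck_width,
    )


def _mask_to_polygon(mask: np.ndarray) -> RoiPolygon | None:
    from skimage import measure

    if not mask.any():
        return None
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        return None
    contour = max(contours, key=len)
    contour = measure.approximate_polygon(contour, 0.5)
    if len(contour) < 3:
        return None
    try:
        return RoiPolygon(contour)
    except ValueError:
        return None


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify_spine(neck_width: float, head_width: float) -> str:
    """Assign stubby / mushroom / thin / outlier from the NW/HW ratio.

    No distinct neck (NW = 0) is stubby.  Otherwise the ratio NW/HW
    decides: < 0.5 mushroom (thick head, narrow neck), within [0.5, 1.1]
    thin (no clear head), > 1.1 an outlier.
    """
    if head_width <= 0:
        raise ValueError("head width must be > 0")
    if neck_width < 0:
        raise ValueError("neck width must be >= 0")
    if neck_width == 0:
        return "stubby"
    ratio = neck_width / head_width
    if ratio < MUSHROOM_THIN_BOUNDARY:
        return "mushroom"
    if ratio <= THIN_OUTLIER_BOUNDARY:
        return "thin"
    return "outlier"


def head_width(roi: RoiPolygon) -> float:
    """Maximal caliper width of the head polygon, in pixels."""
    v = roi.vertices
    d = np.linalg.norm(v[:, None, :] - v[None, :, :], axis=-1)
    return float(d.max())


# ---------------------------------------------------------------------------
# record assembly and statistics
# ---------------------------------------------------------------------------


def build_spine_record(
    stack: ImageStack,
    center: SpineCenter,
    all_centers: list[SpineCenter] | None = None,
    dendrite_mask: np.ndarray | None = None,
    params: RuleParams | None = None,
    mode: str = "luminosity",
    channel: int = 0,
    trace_necks: bool = True,
) -> SpineRecord:
    """Generate head ROI(s), neck, head width and class for one spine.

    Luminosity mode grows a single ROI on the per-pixel temporal maximum
    projection (the maximal extent of the spine over the whole period);
    area mode regrows the ROI independently at every timepoint.
    """
    if mode not in ("luminosity", "area"):
        raise ValueError("mode must be 'luminosity' or 'area'")
    params = params or RuleParams()
    if mode == "luminosity":
        img = stack.data[:, channel].max(axis=0)
        rois = [average_perturbed_rois(img, center, all_centers, dendrite_mask, params)]
        roi_for_neck = rois[0]
        neck_image = img
    else:
        rois = [
            average_perturbed_rois(
                stack.data[t, channel], center, all_centers, dendrite_mask, params
            )
            for t in range(stack.n_timepoints)
        ]
        roi_for_neck = rois[0]
        neck_image = stack.data[0, channel]

    record = SpineRecord(center=center, head_rois=rois, mode=mode)
    if trace_necks and dendrite_mask is not None and dendrite_mask.any():
        record.neck = trace_neck(neck_image, center, roi_for_neck, dendrite_mask)
    hw = head_width(roi_for_neck)
    nw = record.neck.neck_width if record.neck is not None else 0.0
    record.head_width = hw
    record.class_label = classify_spine(nw, hw)
    return record


def spine_stats(record: SpineRecord, stack: ImageStack) -> list[dict]:
    """Per-(t, c) luminosity/area statistics for one spine record.

    Background-corrected luminosity is head mean minus background mean;
    neck length and mean neck luminosity are included when a neck was
    traced.  Results are cached on the record and returned.
    """
    shape = stack.frame_shape
    rows: list[dict] = []
    bg_mask = (
        record.background_roi.rasterize(shape)
        if record.background_roi is not None
        else None
    )
    for t in range(stack.n_timepoints):
        roi = record.head_roi_at(t).clamp(shape)
        head_mask = roi.rasterize(shape)
        area_px = roi.area()
        for c in range(stack.n_channels):
            frame = stack.data[t, c]
            head_vals = frame[head_mask] if head_mask.any() else np.array([0.0])
            row = {
                "t": t,
                "c": c,
                "mean_luminosity": float(head_vals.mean()),
                "integrated_luminosity": float(head_vals.sum()),
                "area_px2": float(area_px),
                "class": record.class_label,
            }
            if stack.pixel_size is not None:
                row["area_um2"] = float(area_px * stack.pixel_size**2)
            if bg_mask is not None and bg_mask.any():
                bg_mean = float(frame[bg_mask].mean())
                row["background_mean"] = bg_mean
                row["corrected_luminosity"] = row["mean_luminosity"] - bg_mean
            if record.neck is not None:
                row["neck_length_px"] = record.neck.length_px
                if record.neck.mask.any():
                    row["neck_mean_luminosity"] = float(frame[record.neck.mask].mean())
            if record.local_shifts is not None:
                row["local_shift_row"] = float(record.local_shifts[t][0])
                row["local_shift_col"] = float(record.local_shifts[t][1])
            rows.append(row)
    record.stats = rows
    return rows
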