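"""Medial-axis tracing of a dendrite between two user endpoints.

The dendrite centreline is posed as a shortest-path problem on the
binarized image: admissible pixels are those above a luminosity
threshold, and the per-pixel traversal cost is augmented by the
Euclidean distance to the nearest inadmissible pixel so that the
optimal path hugs the middle of the tube rather than its edges.
Images larger than 512 px on a side are searched at a coarser integer
scale and the path is refined back at full resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as _sparse_dijkstra

from .image_io import SegmentedLineRoi

#: image side length above which the search runs on a downsampled field
DOWNSAMPLE_TRIGGER = 512

#: default Douglas-Peucker tolerance for control-point compression (px)
DEFAULT_TOLERANCE = 2.0

#: how far (px) an endpoint may be snapped onto the admissible region
SNAP_RADIUS = 10.0


class NoDendriteError(ValueError):
    """Binary mask has no foreground; nothing to trace."""


class UnreachableError(ValueError):
    """Start and end lie in different connected components."""


class EmptyMaskWarning(UserWarning):
    pass


# ---------------------------------------------------------------------------
# binarization and cost field
# ---------------------------------------------------------------------------


@dataclass
class BinaryMask:
    mask: np.ndarray
    threshold_used: float
    filter_size: int


@dataclass
class CostField:
    """Admissibility plus boundary-distance-derived traversal cost.

    ``step_cost = 1 / (1 + d)`` with ``d`` the Euclidean distance
    transform: deep-interior pixels are cheap, edge pixels expensive,
    inadmissible pixels untraversable (infinite cost).
    """

    admissible: np.ndarray
    boundary_distance: np.ndarray
    step_cost: np.ndarray


def binarize(
    image: np.ndarray,
    filter_size: int = 7,
    threshold: float | str = "mean",
) -> BinaryMask:
    """Median-filter then threshold an image into an admissibility mask.

    ``threshold="mean"`` resolves to the mean of the filtered image
    (the default rough fore/background split).
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    filtered = ndi.median_filter(image, size=int(filter_size))
    thr = float(filtered.mean()) if threshold == "mean" else float(threshold)
    mask = filtered > thr
    if not mask.any():
        warnings.warn("binarization produced an empty mask", EmptyMaskWarning)
    return BinaryMask(mask=mask, threshold_used=thr, filter_size=int(filter_size))


def build_cost_field(mask: BinaryMask | np.ndarray) -> CostField:
    """Distance-transform the admissible region into a traversal cost.

    The image border is treated as inadmissible, so an all-true mask
    yields the distance to the nearest image edge.
    """
    admissible = mask.mask if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    if not admissible.any():
        raise NoDendriteError("mask has no admissible pixels")
    padded = np.pad(admissible, 1, constant_values=False)
    dist = ndi.distance_transform_edt(padded)[1:-1, 1:-1]
    step = np.full(admissible.shape, np.inf)
    step[admissible] = 1.0 / (1.0 + dist[admissible])
    return CostField(admissible=admissible, boundary_distance=dist, step_cost=step)


# ---------------------------------------------------------------------------
# Dijkstra on the 8-connected pixel graph
# ---------------------------------------------------------------------------

_OFFSETS = [(-1, 0), (0, -1), (0, 1), (1, 0), (-1, -1), (-1, 1), (1, -1), (1, 1)]


def _grid_graph(field: CostField) -> coo_matrix:
    """Sparse weighted adjacency over admissible pixels.

    Edge weight = geometric step length (1 or sqrt(2)) times the mean of
    the two endpoint step costs.
    """
    h, w = field.admissible.shape
    idx = np.arange(h * w).reshape(h, w)
    cost = field.step_cost
    adm = field.admissible
    rows, cols, data = [], [], []
    for dr, dc in _OFFSETS:
        src = idx[max(0, -dr) : h - max(0, dr), max(0, -dc) : w - max(0, dc)]
        dst = idx[max(0, dr) : h + min(0, dr), max(0, dc) : w + min(0, dc)]
        ok = adm.flat[src.ravel()] & adm.flat[dst.ravel()]
        s, d = src.ravel()[ok], dst.ravel()[ok]
        step = np.hypot(dr, dc)
        wgt = step * 0.5 * (cost.flat[s] + cost.flat[d])
        rows.append(s)
        cols.append(d)
        data.append(wgt)
    return coo_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(h * w, h * w),
    ).tocsr()


def snap_to_admissible(
    point: tuple[int, int], admissible: np.ndarray, radius: float = SNAP_RADIUS
) -> tuple[int, int]:
    """Snap a point to the nearest admissible pixel within ``radius``."""
    r, c = int(round(point[0])), int(round(point[1]))
    h, w = admissible.shape
    r, c = min(max(r, 0), h - 1), min(max(c, 0), w - 1)
    if admissible[r, c]:
        return (r, c)
    _, (ir, ic) = ndi.distance_transform_edt(~admissible, return_indices=True)
    nr, nc = int(ir[r, c]), int(ic[r, c])
    if np.hypot(nr - r, nc - c) > radius:
        raise ValueError(
            f"point {point} is more than {radius} px from any admissible pixel"
        )
    return (nr, nc)


def _run_dijkstra(
    field: CostField, start: tuple[int, int], end: tuple[int, int]
) -> tuple[np.ndarray, float]:
    """Minimum-cost 8-connected pixel chain and its total cost."""
    h, w = field.admissible.shape
    graph = _grid_graph(field)
    s = start[0] * w + start[1]
    e = end[0] * w + end[1]
    dist, pred = _sparse_dijkstra(
        graph, directed=False, indices=s, return_predecessors=True
    )
    if not np.isfinite(dist[e]):
        raise UnreachableError(
            f"no admissible path between start {tuple(start)} and end {tuple(end)}"
        )
    chain = [e]
    while chain[-1] != s:
        chain.append(int(pred[chain[-1]]))
    chain = np.array(chain[::-1])
    pixels = np.column_stack(np.unravel_index(chain, (h, w)))
    return pixels, float(dist[e])


def path_cost(field: CostField, pixels: np.ndarray) -> float:
    """Total edge cost of a pixel chain under the field's weighting."""
    pixels = np.asarray(pixels)
    if len(pixels) < 2:
        return 0.0
    c = field.step_cost[pixels[:, 0], pixels[:, 1]]
    steps = np.hypot(*np.diff(pixels, axis=0).T)
    return float(np.sum(steps * 0.5 * (c[:-1] + c[1:])))


# ---------------------------------------------------------------------------
# the medial axis path
# ---------------------------------------------------------------------------


@dataclass
class MedialAxisPath:
    """Compressed control-point polyline plus its full-rank pixel chain."""

    control_points: np.ndarray
    full_rank: np.ndarray
    source_scale: int = 1
    total_cost: float | None = None

    def as_roi(self) -> SegmentedLineRoi:
        return SegmentedLineRoi(self.control_points)

    def __len__(self) -> int:
        return len(self.full_rank)


def compress_path(full_rank: np.ndarray, tolerance: float = DEFAULT_TOLERANCE) -> np.ndarray:
    """Reduce a pixel chain to its major turning points (Douglas-Peucker).

    Linear interpolation of the returned control points deviates from the
    original chain by at most ``tolerance`` pixels; straight segments
    collapse to their endpoints.
    """
    from skimage.measure import approximate_polygon

    full_rank = np.asarray(full_rank, dtype=float)
    if len(full_rank) == 1:
        return full_rank.copy()
    return approximate_polygon(full_rank, tolerance)


def interpolate_path(control_points: np.ndarray) -> np.ndarray:
    """Rasterize a control-point polyline back into an 8-connected chain."""
    from skimage.draw import line as draw_line

    pts = np.rint(np.atleast_2d(np.asarray(control_points, float))).astype(int)
    if len(pts) < 2:
        raise ValueError("need at least 2 control points to interpolate")
    chain: list[np.ndarray] = []
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        rr, cc = draw_line(r0, c0, r1, c1)
        seg = np.column_stack([rr, cc])
        if chain:
            seg = seg[1:]  # joint shared with previous segment
        if len(seg):
            chain.append(seg)
    full = np.concatenate(chain) if chain else pts[:1]
    keep = np.ones(len(full), bool)
    keep[1:] = np.any(np.diff(full, axis=0) != 0, axis=1)
    return full[keep]


def _downsample_mask(admissible: np.ndarray, k: int) -> np.ndarray:
    """Block-mean pool then re-threshold at 0.5 occupancy."""
    h, w = admissible.shape
    ph, pw = (-h) % k, (-w) % k
    padded = np.pad(admissible.astype(float), ((0, ph), (0, pw)))
    blocks = padded.reshape((h + ph) // k, k, (w + pw) // k, k).mean(axis=(1, 3))
    return blocks >= 0.5


def shortest_path(
    field: CostField,
    start: tuple[int, int],
    end: tuple[int, int],
    tolerance: float = DEFAULT_TOLERANCE,
    max_dim: int = DOWNSAMPLE_TRIGGER,
    allow_downsample: bool = True,
) -> MedialAxisPath:
    """Trace the medial axis between two endpoints.

    Endpoints falling off the admissible region are snapped to the
    nearest admissible pixel (within 10 px).  If either image dimension
    exceeds ``max_dim`` the search first runs on an integer-factor
    downsampled field and is then refined at full resolution inside a
    corridor around the coarse solution, so the returned path always
    lies on full-resolution admissible pixels.
    """
    h, w = field.admissible.shape
    start = snap_to_admissible(start, field.admissible)
    end = snap_to_admissible(end, field.admissible)

    if start == end:
        full = np.array([start])
        return MedialAxisPath(
            control_points=np.asarray(full, float),
            full_rank=full,
            source_scale=1,
            total_cost=0.0,
        )

    scale = 1
    search_field = field
    if allow_downsample and max(h, w) > max_dim:
        scale = int(np.ceil(max(h, w) / max_dim))
        coarse_mask = _downsample_mask(field.admissible, scale)
        coarse_field = build_cost_field(coarse_mask)
        cs = snap_to_admissible((start[0] // scale, start[1] // scale), coarse_mask)
        ce = snap_to_admissible((end[0] // scale, end[1] // scale), coarse_mask)
        coarse_pixels, _ = _run_dijkstra(coarse_field, cs, ce)
        # refine at full resolution inside a corridor around the coarse path
        up = coarse_pixels * scale + scale // 2
        up = np.clip(up, 0, [h - 1, w - 1])
        spine = np.zeros((h, w), bool)
        chain = interpolate_path(np.vstack([[start], up, [end]]))
        spine[chain[:, 0], chain[:, 1]] = True
        corridor = ndi.distance_transform_edt(~spine) <= 2 * scale + 1
        restricted = field.admissible & corridor
        restricted[start] = restricted[end] = True
        step = np.where(restricted, field.step_cost, np.inf)
        step[~np.isfinite(field.step_cost) & restricted] = 1.0
        search_field = CostField(
            admissible=restricted,
            boundary_distance=field.boundary_distance,
            step_cost=step,
        )

    pixels, cost = _run_dijkstra(search_field, start, end)
    control = compress_path(pixels, tolerance)
    return MedialAxisPath(
        control_points=control, full_rank=pixels, source_scale=scale, total_cost=cost
    )


def trace_dendrite(
    image: np.ndarray,
    start: tuple[int, int],
    end: tuple[int, int],
    filter_size: int = 7,
    threshold: float | str = "mean",
    tolerance: float = DEFAULT_TOLERANCE,
) -> tuple[MedialAxisPath, BinaryMask, CostField]:
    """Convenience wrapper: binarize, build the cost field, trace."""
    bm = binarize(image, filter_size=filter_size, threshold=threshold)
    field = build_cost_field(bm)
    path = shortest_path(field, start, end, tolerance=tolerance)
    return path, bm, field
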