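"""ROI-scoped fluorescent puncta detection (smFISH-style spot counting).

Spots are found with scale-normalized Laplacian-of-Gaussian blob
detection, restricted to the interior of the parent ROI.  Each ROI gets
its own adaptive threshold tR(t, c) = max(R(t, c, j, k)) * gamma / 100,
where gamma is the percent slider for the ROI kind (dendrite versus
synapse/soma); ROIs whose peak intensity sits below the background noise
floor are skipped outright.  Dendrites are scanned through consecutive
local rectangles spanning the cross-section along the medial axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import blob_log

from .dendrite_geometry import WidthProfile
from .image_io import RoiPolygon
from .medial_axis import MedialAxisPath


@dataclass
class ThresholdPolicy:
    """Detection thresholds and scale limits for puncta detection."""

    gamma_dendrite: float = 30.0  # percent, dendrite ROIs
    gamma_synapse: float = 30.0  # percent, spine/soma ROIs
    min_sigma: float = 1.0
    max_sigma: float = 5.0
    noise_floor: float | None = None  # intensity level; None = no gating

    def __post_init__(self) -> None:
        if not 0 <= self.gamma_dendrite <= 100 or not 0 <= self.gamma_synapse <= 100:
            raise ValueError("gamma must lie in [0, 100]")
        if not 0 < self.min_sigma <= self.max_sigma:
            raise ValueError("need 0 < min_sigma <= max_sigma")


@dataclass
class Punctum:
    location: tuple[float, float]  # (row, col), subpixel
    scale_sigma: float
    min_intensity: float
    max_intensity: float
    mean_intensity: float
    parent_roi: str = ""
    t: int = 0
    c: int = 0
    arclength: float | None = None

    @property
    def radius(self) -> float:
        """Effective spot radius, sigma * sqrt(2), in pixels."""
        return self.scale_sigma * np.sqrt(2.0)


def roi_threshold(roi_pixels: np.ndarray, gamma: float) -> float:
    """Adaptive LoG threshold tR = max(roi pixels) * gamma / 100."""
    roi_pixels = np.asarray(roi_pixels)
    if roi_pixels.size == 0:
        raise ValueError("empty ROI has no threshold")
    if not 0 <= gamma <= 100:
        raise ValueError("gamma must lie in [0, 100]")
    return float(roi_pixels.max()) * gamma / 100.0


def estimate_noise_floor(image: np.ndarray, occupied: np.ndarray) -> float:
    """Background noise level: mean + 2 SD of pixels outside all ROIs."""
    bg = np.asarray(image, float)[~np.asarray(occupied, bool)]
    if bg.size == 0:
        return 0.0
    return float(bg.mean() + 2.0 * bg.std())


def _blob_stats(image: np.ndarray, r: float, c: float, sigma: float) -> tuple[float, float, float]:
    h, w = image.shape
    rad = max(1, int(round(sigma * np.sqrt(2.0))))
    rr, cc = np.ogrid[:h, :w]
    disc = (rr - r) ** 2 + (cc - c) ** 2 <= rad**2
    vals = image[disc]
    if vals.size == 0:
        v = float(image[int(round(r)) % h, int(round(c)) % w])
        return v, v, v
    return float(vals.min()), float(vals.max()), float(vals.mean())


def detect_in_polygon(
    image: np.ndarray,
    roi: RoiPolygon,
    policy: ThresholdPolicy,
    gamma: float | None = None,
    roi_id: str = "",
    t: int = 0,
    c: int = 0,
) -> list[Punctum]:
    """LoG blob detection confined to one polygon ROI.

    The detector runs on the ROI's bounding box; candidates whose
    centres fall outside the polygon are discarded (border centres count
    as inside).  The whole ROI short-circuits when its maximum intensity
    does not exceed the noise floor.
    """
    image = np.asarray(image, float)
    shape = image.shape
    mask = roi.clamp(shape).rasterize(shape)
    if not mask.any():
        return []
    roi_pixels = image[mask]
    if policy.noise_floor is not None and roi_pixels.max() <= policy.noise_floor:
        return []
    g = policy.gamma_synapse if gamma is None else gamma
    thr = roi_threshold(roi_pixels, g)

    v = roi.vertices
    pad = int(np.ceil(policy.max_sigma * 2))
    r0 = max(0, int(np.floor(v[:, 0].min())) - pad)
    r1 = min(shape[0], int(np.ceil(v[:, 0].max())) + pad + 1)
    c0 = max(0, int(np.floor(v[:, 1].min())) - pad)
    c1 = min(shape[1], int(np.ceil(v[:, 1].max())) + pad + 1)
    crop = image[r0:r1, c0:c1]
    if crop.size == 0 or np.ptp(crop) == 0:
        return []
    blobs = blob_log(
        crop,
        min_sigma=policy.min_sigma,
        max_sigma=policy.max_sigma,
        num_sigma=10,
        threshold=max(thr, 1e-12),
    )
    out: list[Punctum] = []
    for br, bc, sigma in blobs:
        # a maximum on the boundary of the scale grid is not a certified
        # scale-space maximum: the spot's true size lies outside the band
        if policy.max_sigma > policy.min_sigma and (
            sigma >= policy.max_sigma - 1e-9 or sigma <= policy.min_sigma + 1e-9
        ):
            continue
        rr, cc = br + r0, bc + c0
        if not roi.contains((rr, cc)):
            continue
        mn, mx, mean = _blob_stats(image, rr, cc, sigma)
        out.append(
            Punctum(
                location=(float(rr), float(cc)),
                scale_sigma=float(sigma),
                min_intensity=mn,
                max_intensity=mx,
                mean_intensity=mean,
                parent_roi=roi_id,
                t=t,
                c=c,
            )
        )
    return out


# ---------------------------------------------------------------------------
# dendrite scoping: local rectangles along the medial axis
# ---------------------------------------------------------------------------


def dendrite_rectangles(
    path: MedialAxisPath, profile: WidthProfile
) -> list[RoiPolygon]:
    """Partition the dendrite band into quadrilaterals, one per segment.

    Corners use normals averaged between adjacent segments (mitred), so
    consecutive quads share an edge exactly: no gaps, no double cover.
    """
    control = np.asarray(path.control_points, float)
    full = np.asarray(path.full_rank, float)
    if len(control) < 2:
        raise ValueError("need at least two control points")
    # representative cross-section per segment: median half-widths over the
    # full-rank points the segment spans (robust to endpoint dropouts)
    idx = [int(np.argmin(np.linalg.norm(full - cp, axis=1))) for cp in control]
    seg_half = []
    for i in range(len(control) - 1):
        lo, hi = sorted((idx[i], idx[i + 1]))
        span = profile.half_widths[lo : hi + 1]
        seg_half.append(np.median(span, axis=0))
    # width at a control point: mean of its adjacent segments, so
    # consecutive quads share their edge exactly
    half = np.empty((len(control), 2))
    half[0] = seg_half[0]
    half[-1] = seg_half[-1]
    for j in range(1, len(control) - 1):
        half[j] = 0.5 * (np.asarray(seg_half[j - 1]) + np.asarray(seg_half[j]))

    seg_dirs = np.diff(control, axis=0)
    seg_dirs /= np.maximum(np.linalg.norm(seg_dirs, axis=1, keepdims=True), 1e-9)
    # mitred normal at each control point
    normals = []
    for i in range(len(control)):
        if i == 0:
            t = seg_dirs[0]
        elif i == len(control) - 1:
            t = seg_dirs[-1]
        else:
            t = seg_dirs[i - 1] + seg_dirs[i]
            n = np.linalg.norm(t)
            t = t / n if n > 1e-9 else seg_dirs[i]
        normals.append(np.array([-t[1], t[0]]))
    quads = []
    for i in range(len(control) - 1):
        a, b = control[i], control[i + 1]
        na, nb = normals[i], normals[i + 1]
        (la, ra), (lb, rb) = half[i], half[i + 1]
        verts = np.array(
            [a + la * na, b + lb * nb, b - rb * nb, a - ra * na]
        )
        try:
            quads.append(RoiPolygon(verts))
        except ValueError:
            continue  # degenerate sliver (zero width on both sides)
    return quads


def detect_in_dendrite(
    image: np.ndarray,
    path: MedialAxisPath,
    profile: WidthProfile,
    policy: ThresholdPolicy,
    roi_id: str = "dendrite",
    t: int = 0,
    c: int = 0,
) -> list[Punctum]:
    """Detect puncta inside the dendrite's local rectangles.

    Each quad is scanned with ``gamma_dendrite``; duplicates straddling a
    shared edge are merged (keep the brighter of any pair closer than
    max(sigma_i, sigma_j)), and every punctum is annotated with its
    arclength position along the medial axis.
    """
    quads = dendrite_rectangles(path, profile)
    found: list[Punctum] = []
    for qi, quad in enumerate(quads):
        found.extend(
            detect_in_polygon(
                image,
                quad,
                policy,
                gamma=policy.gamma_dendrite,
                roi_id=f"{roi_id}/seg{qi}",
                t=t,
                c=c,
            )
        )
    # deduplicate across shared edges
    found.sort(key=lambda p: -p.mean_intensity)
    kept: list[Punctum] = []
    for p in found:
        dup = False
        for q in kept:
            dist = np.hypot(
                p.location[0] - q.location[0], p.location[1] - q.location[1]
            )
            if dist < max(p.scale_sigma, q.scale_sigma):
                dup = True
                break
        if not dup:
            kept.append(p)

    full = np.asarray(path.full_rank, float)
    seglen = np.hypot(*np.diff(full, axis=0).T) if len(full) > 1 else np.array([0.0])
    arc = np.concatenate([[0.0], np.cumsum(seglen)])
    for p in kept:
        i = int(np.argmin(np.linalg.norm(full - np.array(p.location), axis=1)))
        p.arclength = float(arc[i])
        p.parent_roi = roi_id
    kept.sort(key=lambda p: p.arclength)
    return kept


def localization_fractions(
    puncta: list[Punctum], compartment_of: dict[str, str]
) -> dict:
    """Per-(channel, compartment) puncta counts and fractions.

    Fractions are normalized per channel and sum to 1; a channel with no
    puncta reports ``None`` fractions rather than 0/0.
    """
    counts: dict[int, dict[str, int]] = {}
    for p in puncta:
        if p.parent_roi not in compartment_of:
            raise KeyError(f"ROI {p.parent_roi!r} has no compartment mapping")
        comp = compartment_of[p.parent_roi]
        counts.setdefault(p.c, {}).setdefault(comp, 0)
        counts[p.c][comp] += 1
    out: dict = {"counts": counts, "fractions": {}}
    for ch, by_comp in counts.items():
        total = sum(by_comp.values())
        out["fractions"][ch] = {
            comp: (n / total if total else None) for comp, n in by_comp.items()
        }
    if not counts:
        out["fractions"] = None
    return out


def puncta_rows(puncta: list[Punctum]) -> list[dict]:
    """Flatten puncta into write_tables-compatible records."""
    return [
        {
            "id": p.parent_roi,
            "t": p.t,
            "c": p.c,
            "row": p.location[0],
            "col": p.location[1],
            "sigma": p.scale_sigma,
            "radius": p.radius,
            "min_intensity": p.min_intensity,
            "mean_intensity": p.mean_intensity,
            "max_intensity": p.max_intensity,
            "arclength": p.arclength,
        }
        for p in puncta
    ]
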