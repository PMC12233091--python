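"""Reading, writing and the internal image/ROI data model.

Everything downstream works on a single canonical representation: a
four-axis intensity array ``I(t, c, x, y)`` (time, channel, row, column),
with optional physical pixel size in micrometres per pixel.  Coordinates
are ``(row, col)``, 0-based, pixel centres at integer coordinates; the
ImageJ ``.roi`` dialect conversion happens only at the file boundary.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class LayoutError(ValueError):
    """Declared axis layout inconsistent with the file contents."""


class RoiFormatError(ValueError):
    """A .roi / array dump does not contain the expected ROI type."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ImageStack:
    """The 4-axis intensity record ``I(t, c, x, y)``.

    Parameters
    ----------
    data:
        Array indexed ``(t, c, row, col)``; finite and non-negative.
    pixel_size:
        Micrometres per pixel, if known.
    channel_names:
        Optional labels, one per channel.
    """

    data: np.ndarray
    pixel_size: float | None = None
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4 axes (t, c, x, y), got {self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")
        if self.pixel_size is not None and not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if self.channel_names is not None and len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names must match the channel axis")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[2:]

    def frame(self, t: int = 0, c: int = 0) -> np.ndarray:
        return self.data[t, c]

    @classmethod
    def from_array(
        cls,
        arr: np.ndarray,
        axis_order: str = "xy",
        pixel_size: float | None = None,
        channel_names: list[str] | None = None,
    ) -> "ImageStack":
        """Normalize an array with a declared layout into (t, c, x, y).

        ``axis_order`` is a permutation-free subset of ``"tcxy"`` naming the
        axes actually present, e.g. ``"xy"`` for a single frame, ``"txy"``
        for a single-channel series, ``"ctxy"`` if channel varies slowest.
        Missing axes are inserted as singletons; no silent guessing.
        """
        arr = np.asarray(arr)
        order = axis_order.lower()
        if sorted(order) != sorted(set(order)) or not set(order) <= set("tcxy"):
            raise LayoutError(f"invalid axis_order {axis_order!r}")
        if "x" not in order or "y" not in order:
            raise LayoutError("axis_order must contain both spatial axes 'x' and 'y'")
        if arr.ndim != len(order):
            raise LayoutError(
                f"axis_order {axis_order!r} declares {len(order)} axes, "
                f"array has {arr.ndim}"
            )
        # move declared axes into canonical t, c, x, y order
        canonical = [a for a in "tcxy" if a in order]
        arr = np.moveaxis(arr, [order.index(a) for a in canonical], range(len(canonical)))
        for pos, a in enumerate("tc"):
            if a not in order:
                arr = np.expand_dims(arr, pos)
        return cls(arr, pixel_size=pixel_size, channel_names=channel_names)


def _simple(vertices: np.ndarray) -> bool:
    from shapely.geometry import Polygon

    return Polygon(np.asarray(vertices, float)).is_valid


@dataclass
class RoiPolygon:
    """Closed polygon ROI; vertices are ordered (row, col) points."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.atleast_2d(np.asarray(self.vertices, dtype=float))
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array of (row, col)")
        if len(self.vertices) < 3:
            raise ValueError("a polygon needs at least 3 vertices")
        if not _simple(self.vertices):
            raise ValueError("polygon is self-intersecting")

    def clamp(self, shape: tuple[int, int]) -> "RoiPolygon":
        v = self.vertices.copy()
        v[:, 0] = np.clip(v[:, 0], 0, shape[0] - 1)
        v[:, 1] = np.clip(v[:, 1], 0, shape[1] - 1)
        return RoiPolygon(v)

    def translated(self, drow: float, dcol: float) -> "RoiPolygon":
        return RoiPolygon(self.vertices + np.array([drow, dcol]))

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        from skimage.draw import polygon as draw_polygon

        rr, cc = draw_polygon(self.vertices[:, 0], self.vertices[:, 1], shape)
        mask = np.zeros(shape, dtype=bool)
        mask[rr, cc] = True
        return mask

    def area(self) -> float:
        """Shoelace area in square pixels."""
        r, c = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * abs(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1)))

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def circumradius(self) -> float:
        return float(np.linalg.norm(self.vertices - self.centroid(), axis=1).max())

    def contains(self, point: tuple[float, float]) -> bool:
        """Even-odd membership; border points count as inside."""
        from shapely.geometry import Point, Polygon

        poly = Polygon(self.vertices)
        p = Point(point)
        return bool(poly.contains(p) or poly.touches(p))


@dataclass
class SegmentedLineRoi:
    """Open polyline ROI with optional per-point half widths."""

    points: np.ndarray
    widths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array of (row, col)")
        if len(self.points) < 2:
            raise ValueError("a polyline needs at least 2 points")
        if self.widths is not None:
            self.widths = np.asarray(self.widths, dtype=float)
            if len(self.widths) != len(self.points):
                raise ValueError("widths must match point count")
            if np.any(self.widths < 0):
                raise ValueError("widths must be >= 0")

    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


# ---------------------------------------------------------------------------
# stack reading
# ---------------------------------------------------------------------------


def read_stack(
    path: str | Path,
    axis_order: str = "xy",
    pixel_size: float | None = None,
    channel_names: list[str] | None = None,
) -> ImageStack:
    """Read a TIFF (single- or multi-page) or .npy dump into an ImageStack.

    The source layout must be declared via ``axis_order``; a mismatch
    between declaration and page count raises :class:`LayoutError`.
    """
    path = Path(path)
    try:
        if path.suffix.lower() in {".npy"}:
            arr = np.load(path)
        else:
            import tifffile

            arr = tifffile.imread(path)
    except LayoutError:
        raise
    except Exception as exc:  # noqa: BLE001 - normalize to IO error
        raise OSError(f"could not read image file {path}: {exc}") from exc
    if arr.size == 0:
        raise OSError(f"empty or truncated image file {path}")
    return ImageStack.from_array(
        arr, axis_order=axis_order, pixel_size=pixel_size, channel_names=channel_names
    )


def write_stack(stack: ImageStack, path: str | Path, squeeze: bool = False) -> None:
    """Write an ImageStack as a TIFF preserving dtype."""
    import tifffile

    data = stack.data
    if squeeze:
        data = np.squeeze(data)
    tifffile.imwrite(Path(path), data, photometric="minisblack")


# ---------------------------------------------------------------------------
# ImageJ .roi codec
#
# Minimal encoder/decoder for the ImageJ ROI binary dialect (big-endian,
# 64-byte header, then x then y vertex shorts relative to the bounding box).
# Only the polygon (type 0) and polyline (type 5) records are produced.
# ---------------------------------------------------------------------------

_ROI_MAGIC = b"Iout"
_ROI_VERSION = 226
_TYPE_POLYGON = 0
_TYPE_POLYLINE = 5


def _write_imagej_roi(path: Path, points: np.ndarray, roi_type: int) -> None:
    pts = np.rint(np.asarray(points, float)).astype(int)
    x = pts[:, 1]  # ImageJ x is the column
    y = pts[:, 0]
    left, top = int(x.min()), int(y.min())
    right, bottom = int(x.max()), int(y.max())
    n = len(pts)
    header = bytearray(64)
    header[0:4] = _ROI_MAGIC
    struct.pack_into(">h", header, 4, _ROI_VERSION)
    header[6] = roi_type
    struct.pack_into(">hhhh", header, 8, top, left, bottom, right)
    struct.pack_into(">h", header, 16, n)
    body = struct.pack(f">{n}h", *(x - left)) + struct.pack(f">{n}h", *(y - top))
    try:
        path.write_bytes(bytes(header) + body)
    except OSError as exc:
        raise OSError(f"could not write ROI file {path}: {exc}") from exc


def _read_imagej_roi(path: Path) -> tuple[int, np.ndarray]:
    blob = Path(path).read_bytes()
    if blob[0:4] != _ROI_MAGIC:
        raise RoiFormatError(f"{path} is not an ImageJ .roi file")
    roi_type = blob[6]
    top, left = struct.unpack_from(">hh", blob, 8)
    n = struct.unpack_from(">h", blob, 16)[0]
    x = np.array(struct.unpack_from(f">{n}h", blob, 64)) + left
    y = np.array(struct.unpack_from(f">{n}h", blob, 64 + 2 * n)) + top
    return roi_type, np.column_stack([y, x]).astype(float)


def export_roi(roi: RoiPolygon | SegmentedLineRoi, path: str | Path) -> None:
    """Write an ImageJ-dialect .roi file (polygon or polyline type)."""
    path = Path(path)
    if isinstance(roi, RoiPolygon):
        _write_imagej_roi(path, roi.vertices, _TYPE_POLYGON)
    elif isinstance(roi, SegmentedLineRoi):
        _write_imagej_roi(path, roi.points, _TYPE_POLYLINE)
    else:
        raise TypeError(f"cannot export {type(roi).__name__} as .roi")


def import_path(path: str | Path) -> SegmentedLineRoi:
    """Import a medial-axis polyline from a .npy dump or a polyline .roi."""
    path = Path(path)
    if path.suffix.lower() == ".npy":
        arr = np.load(path)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise RoiFormatError(
                f"{path}: expected an (n, 2) array of (row, col) points, got {arr.shape}"
            )
        return SegmentedLineRoi(arr)
    roi_type, pts = _read_imagej_roi(path)
    if roi_type != _TYPE_POLYLINE:
        raise RoiFormatError(
            f"{path}: expected a polyline ROI (type {_TYPE_POLYLINE}), got type {roi_type}"
        )
    return SegmentedLineRoi(pts)


def import_polygon(path: str | Path) -> RoiPolygon:
    roi_type, pts = _read_imagej_roi(Path(path))
    if roi_type != _TYPE_POLYGON:
        raise RoiFormatError(f"{path}: expected a polygon ROI, got type {roi_type}")
    return RoiPolygon(pts)


# ---------------------------------------------------------------------------
# stats tables and mask images
# ---------------------------------------------------------------------------


def write_tables(records: list[dict], basepath: str | Path) -> None:
    """Write statistics both as a flat .csv and as a nested .json.

    Each record is a flat dict carrying an ``"id"`` key (the entity) plus
    per-timepoint/per-channel fields; the CSV holds one row per record,
    the JSON nests the same rows under each entity id.  Numeric content is
    identical between the two files.
    """
    basepath = Path(basepath)
    basepath.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame.from_records(records)
    csv_path = basepath.with_suffix(".csv")
    json_path = basepath.with_suffix(".json")
    try:
        df.to_csv(csv_path, index=False)
        nested: dict[str, list[dict]] = {}
        for rec in records:
            entity = str(rec.get("id", ""))
            row = {k: _jsonable(v) for k, v in rec.items() if k != "id"}
            nested.setdefault(entity, []).append(row)
        json_path.write_text(json.dumps(nested, indent=1))
    except OSError as exc:
        raise OSError(f"could not write tables at {basepath}: {exc}") from exc


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    return v


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as an 8-bit PNG (foreground = 255)."""
    import imageio.v3 as iio

    iio.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))
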