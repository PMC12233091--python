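"""Global and local (per-spine) drift correction via phase cross-correlation.

Global correction estimates one whole-frame translation per timepoint
against a reference frame (on a user-designated structural channel) and
resamples the pixels.  Local correction then estimates the residual
shift of a small window around each spine and moves only the spine's
ROI — never the pixels — so genuine spine motility remains visible and
is recorded per timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.registration import phase_cross_correlation

from .image_io import ImageStack
from .spine_analysis import SpineRecord


@dataclass
class ShiftRecord:
    """Bookkeeping of all translations applied across a time-series."""

    reference_t: int = 0
    global_shift: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    local_shifts: dict[int, np.ndarray] = field(default_factory=dict)

    def rows(self) -> list[dict]:
        out = []
        for t, (dr, dc) in enumerate(self.global_shift):
            out.append({"id": "global", "t": t, "drow": float(dr), "dcol": float(dc)})
        for spine_id, shifts in self.local_shifts.items():
            for t, (dr, dc) in enumerate(shifts):
                out.append(
                    {"id": f"spine_{spine_id}", "t": t, "drow": float(dr), "dcol": float(dc)}
                )
        return out


def estimate_shift(
    reference: np.ndarray,
    moving: np.ndarray,
    upsample: int = 1,
    prefilter_sigma: float = 1.5,
) -> tuple[float, float]:
    """Translation (drow, dcol) of ``moving`` relative to ``reference``.

    Positive values mean the content of ``moving`` sits that far down/right
    of where it sits in ``reference``.  Subpixel precision is 1/upsample.

    The correlation runs in the frequency domain on lightly smoothed
    frames (``prefilter_sigma``) and uses the plain cross-power spectrum
    rather than the whitened (phase-normalized) one: whitening amplifies
    high-frequency noise and loses integer shifts already at moderate
    noise levels, while the unnormalized spectrum stays exact.
    """
    reference = np.asarray(reference, float)
    moving = np.asarray(moving, float)
    if reference.shape != moving.shape:
        raise ValueError("frames must share a shape")
    if np.ptp(reference) == 0 or np.ptp(moving) == 0:
        raise ValueError("cannot estimate a shift from a constant image")
    if prefilter_sigma > 0:
        reference = ndi.gaussian_filter(reference, prefilter_sigma)
        moving = ndi.gaussian_filter(moving, prefilter_sigma)
    shift, _, _ = phase_cross_correlation(
        reference, moving, upsample_factor=int(upsample), normalization=None
    )
    # skimage returns the shift that registers `moving` onto `reference`
    return (-float(shift[0]), -float(shift[1]))


def correct_global(
    stack: ImageStack,
    reference_t: int = 0,
    channel: int = 0,
    upsample: int = 1,
    subpixel: bool = False,
) -> tuple[ImageStack, ShiftRecord]:
    """Undo whole-frame drift; all channels share the channel-estimated shift.

    Frames are translated by the negated estimated shift with zero fill
    for out-of-frame regions.  Integer rounding is the default; enable
    ``subpixel`` for interpolated resampling.
    """
    record = ShiftRecord(reference_t=reference_t)
    T = stack.n_timepoints
    record.global_shift = np.zeros((T, 2))
    if T < 2:
        return stack, record
    ref = stack.data[reference_t, channel]
    corrected = stack.data.astype(float).copy()
    for t in range(T):
        if t == reference_t:
            continue
        d = np.array(estimate_shift(ref, stack.data[t, channel], upsample=upsample))
        if not subpixel:
            d = np.round(d)
        record.global_shift[t] = d
        for c in range(stack.n_channels):
            corrected[t, c] = ndi.shift(
                stack.data[t, c].astype(float),
                -d,
                order=0 if not subpixel else 1,
                cval=0.0,
            )
    out = ImageStack(
        corrected, pixel_size=stack.pixel_size, channel_names=stack.channel_names
    )
    return out, record


def correct_local(
    stack: ImageStack,
    spine: SpineRecord,
    window: int | None = None,
    reference_t: int = 0,
    channel: int = 0,
    upsample: int = 10,
    dendrite_mask: np.ndarray | None = None,
) -> SpineRecord:
    """Track residual per-spine motion by shifting only the ROI.

    A square window (default side 3x the head-ROI circumradius) around
    the spine centre is compared per timepoint against the reference
    crop; the estimated shift moves the ROI, the pixel data stays
    untouched, and the shifts are recorded on the spine for the final
    analysis tables.  Pixels on the dendrite shaft (``dendrite_mask``)
    are flattened to the crop median first: the shaft's edge is
    translation-invariant along its own axis but not across it, and would
    otherwise anchor the transverse component of the spine's motion.
    """
    T = stack.n_timepoints
    shifts = np.zeros((T, 2))
    if T >= 2:
        if window is None:
            window = int(round(3 * max(spine.head_rois[0].circumradius(), 2.0)))
        half = max(window // 2, 4)
        r, c = (int(round(x)) for x in spine.center.s0)
        h, w = stack.frame_shape
        r0, r1 = max(0, r - half), min(h, r + half + 1)
        c0, c1 = max(0, c - half), min(w, c + half + 1)
        excl = None
        if dendrite_mask is not None:
            excl = ndi.binary_dilation(dendrite_mask, iterations=2)[r0:r1, c0:c1]
            if excl.all():
                excl = None

        def crop_at(t: int) -> np.ndarray:
            out = stack.data[t, channel, r0:r1, c0:c1].astype(float)
            if excl is not None:
                out = out.copy()
                out[excl] = np.median(out[~excl])
            return out

        ref = crop_at(reference_t)
        for t in range(T):
            if t == reference_t:
                continue
            try:
                shifts[t] = estimate_shift(ref, crop_at(t), upsample=upsample)
            except ValueError:
                shifts[t] = 0.0
    spine.local_shifts = shifts
    return spine


def load_compensatory(path, n_timepoints: int) -> np.ndarray:
    """Read per-timepoint (t, drow, dcol) compensatory offsets from CSV."""
    import pandas as pd

    df = pd.read_csv(path)
    out = np.zeros((n_timepoints, 2))
    for _, row in df.iterrows():
        t = int(row["t"])
        if 0 <= t < n_timepoints:
            out[t] = (float(row["drow"]), float(row["dcol"]))
    return out
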