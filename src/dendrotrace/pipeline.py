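"""End-to-end workflow: dendrite -> spines -> motion -> puncta -> export.

A single :class:`AnalysisConfig` carries every tunable of every stage
plus the input paths; the resolved config is always written next to the
outputs so a run is reproducible and its parameters transferable to the
next dataset (the one-image-optimized protocol).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import dendrite_geometry, image_io, medial_axis, motion_correction, puncta, spine_analysis
from .image_io import ImageStack

log = logging.getLogger("dendrotrace")


@dataclass
class AnalysisConfig:
    """All stage parameters, input paths and seed for one analysis run."""

    # inputs
    input_path: str | None = None
    axis_order: str = "xy"
    pixel_size: float | None = None
    dendrite_endpoints: list[list[list[float]]] = field(default_factory=list)
    spine_centers: list[list[float]] = field(default_factory=list)  # (row, col[, conf])
    # medial axis / binarization
    filter_size: int = 7
    threshold: float | str = "mean"
    tolerance: float = 2.0
    # dendrite geometry
    gaussian_sigma: float = 2.0
    width_multiplier: float = 1.0
    smoothing_strength: float = 0.5
    semi_minor: float = 2.0
    max_semi_major: float = 30.0
    # spines
    drop_factor: float = 0.4
    n_rule: int = 2
    max_extent: int = 30
    min_confidence: float = 0.0
    mode: str = "luminosity"  # or "area"
    # motion
    reference_frame: int = 0
    register_channel: int = 0
    upsample: int = 10
    local_correction: bool = True
    compensatory_path: str | None = None
    # puncta
    gamma_dendrite: float = 30.0
    gamma_synapse: float = 30.0
    sigma_min: float = 1.0
    sigma_max: float = 5.0
    noise_floor: float | None = None
    puncta_channel: int = 0
    # misc
    structural_channel: int = 0
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        return cls(**json.loads(Path(path).read_text()))


def transfer_parameters(source: AnalysisConfig, **new_inputs) -> AnalysisConfig:
    """Copy analysis parameters onto new inputs (the slider-transfer workflow).

    Everything except the input fields is carried over unchanged; a
    pixel-size mismatch between source and target emits a warning since
    physical-unit statistics will differ in meaning.
    """
    cfg = dataclasses.replace(source)
    for k, v in new_inputs.items():
        if not hasattr(cfg, k):
            raise AttributeError(f"unknown config field {k!r}")
        setattr(cfg, k, v)
    if (
        "pixel_size" in new_inputs
        and source.pixel_size is not None
        and new_inputs["pixel_size"] is not None
        and new_inputs["pixel_size"] != source.pixel_size
    ):
        warnings.warn(
            f"pixel_size differs between source ({source.pixel_size}) and "
            f"target ({new_inputs['pixel_size']})",
            UserWarning,
        )
    return cfg


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(
    config: AnalysisConfig,
    outdir: str | Path,
    stack: ImageStack | None = None,
) -> dict:
    """Execute the full workflow and write the result bundle to ``outdir``.

    Stages run in order: global motion correction, medial axis +
    segmentation per dendrite, spine ROI generation + neck + class +
    local correction + background, puncta in dendrite and spine ROIs,
    then table/mask/ROI export and a resolved-config copy.  A failed
    neck trace is logged, not fatal.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    if stack is None:
        if config.input_path is None:
            raise StageFailure("load", ValueError("no input path or stack"))
        stack = image_io.read_stack(
            config.input_path, axis_order=config.axis_order, pixel_size=config.pixel_size
        )
    log.info("loaded stack %s", stack.shape)
    results: dict = {"config": config, "stack_shape": stack.shape}

    # ---- motion: global ---------------------------------------------------
    if stack.n_timepoints > 1:
        stack, shift_record = motion_correction.correct_global(
            stack,
            reference_t=config.reference_frame,
            channel=config.register_channel,
            upsample=config.upsample,
        )
    else:
        shift_record = motion_correction.ShiftRecord(
            reference_t=0, global_shift=np.zeros((1, 2))
        )
    results["shifts"] = shift_record

    frame = stack.data[config.reference_frame, config.structural_channel]

    # ---- dendrites --------------------------------------------------------
    if not config.dendrite_endpoints:
        raise StageFailure("dendrite", ValueError("no dendrite endpoints provided"))
    segmentations = []
    for di, pair in enumerate(config.dendrite_endpoints):
        if len(pair) != 2:
            raise StageFailure(
                "dendrite", ValueError(f"dendrite {di}: need a start and an end point")
            )
        t0 = time.time()
        try:
            path, bm, fld = medial_axis.trace_dendrite(
                frame,
                tuple(pair[0]),
                tuple(pair[1]),
                filter_size=config.filter_size,
                threshold=config.threshold,
                tolerance=config.tolerance,
            )
            edges = dendrite_geometry.detect_edges(
                frame,
                gaussian_sigma=config.gaussian_sigma,
                filter_size=config.filter_size,
                threshold=config.threshold,
            )
            profile = dendrite_geometry.compute_profile(
                path,
                edges,
                semi_minor=config.semi_minor,
                width_multiplier=config.width_multiplier,
                smoothing_strength=config.smoothing_strength,
                max_semi_major=config.max_semi_major,
            )
            seg = dendrite_geometry.build_mask(
                path, profile, frame.shape, stack=stack
            )
        except Exception as exc:  # noqa: BLE001
            raise StageFailure(f"dendrite[{di}]", exc) from exc
        segmentations.append(seg)
        log.info(
            "dendrite %d: %d path px, mean width %.2f px (%.2fs)",
            di,
            len(path.full_rank),
            float(profile.widths.mean()),
            time.time() - t0,
        )
        image_io.write_mask_png(seg.mask, outdir / f"dendrite_{di}_mask.png")
        image_io.export_roi(path.as_roi(), outdir / f"dendrite_{di}_axis.roi")
        np.save(outdir / f"dendrite_{di}_axis.npy", path.control_points)
    results["dendrites"] = segmentations
    dendrite_mask = np.zeros(frame.shape, bool)
    for seg in segmentations:
        dendrite_mask |= seg.mask

    dend_rows = []
    for di, seg in enumerate(segmentations):
        widths = seg.profile.widths
        for t in range(stack.n_timepoints):
            for c in range(stack.n_channels):
                row = {
                    "id": f"dendrite_{di}",
                    "t": t,
                    "c": c,
                    "mean_width_px": float(widths.mean()),
                    "mask_luminosity": float(seg.stats["mask_luminosity"][t, c]),
                    "mean_axis_luminosity": float(
                        seg.stats["axis_luminosity"][t, c].mean()
                    ),
                }
                if stack.pixel_size is not None:
                    row["mean_width_um"] = float(widths.mean() * stack.pixel_size)
                dend_rows.append(row)
    image_io.write_tables(dend_rows, outdir / "dendrite_stats")

    # ---- spines -----------------------------------------------------------
    centers = [
        spine_analysis.SpineCenter(
            s0=(float(sc[0]), float(sc[1])),
            confidence=float(sc[2]) if len(sc) > 2 else 1.0,
        )
        for sc in config.spine_centers
    ]
    centers = spine_analysis.filter_detections(centers, config.min_confidence)
    params = spine_analysis.RuleParams(
        drop_factor=config.drop_factor, n=config.n_rule, max_extent=config.max_extent
    )
    records = []
    occupied = dendrite_mask.copy()
    compensatory = None
    if config.compensatory_path:
        compensatory = motion_correction.load_compensatory(
            config.compensatory_path, stack.n_timepoints
        )
    for si, center in enumerate(centers):
        try:
            rec = spine_analysis.build_spine_record(
                stack,
                center,
                all_centers=centers,
                dendrite_mask=dendrite_mask,
                params=params,
                mode=config.mode,
                channel=config.structural_channel,
            )
        except ValueError as exc:
            log.warning("spine %d skipped: %s", si, exc)
            continue
        if rec.neck is None:
            log.info("spine %d: neck generation not successful", si)
        if stack.n_timepoints > 1 and config.local_correction:
            motion_correction.correct_local(
                stack,
                rec,
                reference_t=config.reference_frame,
                channel=config.structural_channel,
                upsample=config.upsample,
                dendrite_mask=dendrite_mask,
            )
            shift_record.local_shifts[si] = rec.local_shifts
        if compensatory is not None:
            rec.compensatory = compensatory
        occupied |= rec.head_rois[0].rasterize(frame.shape)
        records.append((si, rec))
    for si, rec in records:
        try:
            rec.background_roi = spine_analysis.place_background(
                rec.head_rois[0], occupied, frame.shape
            )
            occupied |= rec.background_roi.rasterize(frame.shape)
        except ValueError:
            log.warning("spine %d: no background position found", si)
    spine_rows = []
    for si, rec in records:
        for row in spine_analysis.spine_stats(rec, stack):
            spine_rows.append({"id": f"spine_{si}", **row})
        image_io.export_roi(rec.head_rois[0].clamp(frame.shape), outdir / f"spine_{si}.roi")
        if rec.neck is not None:
            image_io.export_roi(rec.neck.path, outdir / f"spine_{si}_neck.roi")
    image_io.write_tables(spine_rows, outdir / "spine_stats")
    image_io.write_tables(shift_record.rows(), outdir / "shifts")
    results["spines"] = [rec for _, rec in records]

    # ---- puncta -----------------------------------------------------------
    policy = puncta.ThresholdPolicy(
        gamma_dendrite=config.gamma_dendrite,
        gamma_synapse=config.gamma_synapse,
        min_sigma=config.sigma_min,
        max_sigma=config.sigma_max,
        noise_floor=config.noise_floor,
    )
    all_puncta = []
    pc = min(config.puncta_channel, stack.n_channels - 1)
    for t in range(stack.n_timepoints):
        img = stack.data[t, pc]
        for di, seg in enumerate(segmentations):
            all_puncta.extend(
                puncta.detect_in_dendrite(
                    img, seg.path, seg.profile, policy,
                    roi_id=f"dendrite_{di}", t=t, c=pc,
                )
            )
        for si, rec in records:
            all_puncta.extend(
                puncta.detect_in_polygon(
                    img, rec.head_roi_at(t).clamp(frame.shape), policy,
                    roi_id=f"spine_{si}", t=t, c=pc,
                )
            )
    image_io.write_tables(puncta.puncta_rows(all_puncta), outdir / "puncta")
    results["puncta"] = all_puncta

    config.to_json(outdir / "resolved_config.json")
    log.info("pipeline finished in %.2fs", time.time() - t_start)
    return results
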