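"""Ground-truthed synthetic fixtures for every pipeline stage.

Renders tube-like dendrites of known centreline and width, plateau
spine heads with rectangular necks, fluorescent puncta, rigid per-frame
drift and per-spine wander, then additive Gaussian plus salt-and-pepper
noise.  Plateau intensities (rather than smooth profiles) keep the
ground-truth masks unambiguous.  The SNR knob fixes the noise standard
deviation as (structure amplitude) / SNR; a dark pedestal of at most
0.12x the amplitude emulates the detector offset while leaving the
luminosity drop-off rule meaningful.  Identical spec + seed renders
bit-identical stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import ndimage as ndi

from .image_io import ImageStack
from .medial_axis import interpolate_path
from .spine_analysis import classify_spine


@dataclass
class DendriteSpec:
    control_points: list[tuple[int, int]]
    width: float = 10.0
    intensity_scale: float = 1.0


@dataclass
class SpineSpec:
    center: tuple[int, int]  # head centre
    head_radius: float = 5.0
    neck_length: float = 0.0  # 0 = flush with the dendrite (stubby)
    neck_width: float = 0.0
    intensity_scale: float = 1.0

    def implied_class(self) -> str:
        nw = self.neck_width if self.neck_length > 0 else 0.0
        return classify_spine(nw, 2.0 * self.head_radius)


@dataclass
class PunctumSpec:
    position: tuple[float, float]
    sigma: float = 2.0
    amplitude: float = 100.0
    channel: int = 0
    profile: str = "disc"  # 'disc' (radius sigma*sqrt(2)) or 'gauss'
    compartment: str = "soma"


@dataclass
class FixtureSpec:
    shape: tuple[int, int] = (128, 128)
    n_timepoints: int = 1
    n_channels: int = 1
    pixel_size: float = 0.2  # um / px
    amplitude: float = 100.0
    dendrite: DendriteSpec | None = None
    spines: list[SpineSpec] = field(default_factory=list)
    puncta: list[PunctumSpec] = field(default_factory=list)
    snr: float | None = None  # None = noiseless
    salt_pepper: float = 0.0  # fraction of corrupted pixels
    drift: np.ndarray | None = None  # (T, 2) global shift per frame
    wander: dict[int, np.ndarray] | None = None  # spine idx -> (T, 2)
    seed: int = 0

    @property
    def noise_sd(self) -> float:
        return 0.0 if self.snr is None else self.amplitude / self.snr

    @property
    def background(self) -> float:
        """Dark pedestal: detector offset, kept well below the structures.

        Fluorescence images have near-dark backgrounds; the pedestal is
        2 noise SD where that is small, capped at 0.12x the structure
        amplitude so that background always falls below the luminosity
        drop-off level of the spine rules.
        """
        return min(0.12 * self.amplitude, 2.0 * self.noise_sd)


@dataclass
class GroundTruth:
    dendrite_mask: np.ndarray | None
    centreline: np.ndarray | None
    widths: np.ndarray | None
    spine_masks: list[np.ndarray]
    spine_centers: list[tuple[int, int]]
    spine_classes: list[str]
    neck_masks: list[np.ndarray]
    puncta: list[dict]
    global_drift: np.ndarray
    wander: dict[int, np.ndarray]
    background: float
    noise_sd: float

    def structure_mask(self) -> np.ndarray:
        masks = list(self.spine_masks) + list(self.neck_masks)
        if self.dendrite_mask is not None:
            masks.append(self.dendrite_mask)
        if not masks:
            raise ValueError("fixture has no structures")
        out = np.zeros_like(masks[0], dtype=bool)
        for m in masks:
            out |= m
        return out


class Fixture(NamedTuple):
    spec: FixtureSpec
    stack: ImageStack
    truth: GroundTruth


# ---------------------------------------------------------------------------
# rasterization helpers
# ---------------------------------------------------------------------------


def _tube_mask(
    shape: tuple[int, int], control: np.ndarray, width: float
) -> tuple[np.ndarray, np.ndarray]:
    """Mask of a tube of the given full width, plus its centreline chain."""
    chain = interpolate_path(np.asarray(control))
    chain = chain[
        (chain[:, 0] >= 0)
        & (chain[:, 0] < shape[0])
        & (chain[:, 1] >= 0)
        & (chain[:, 1] < shape[1])
    ]
    line = np.zeros(shape, bool)
    line[chain[:, 0], chain[:, 1]] = True
    mask = ndi.distance_transform_edt(~line) <= width / 2.0
    return mask, chain


def _disc_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _segment_mask(
    shape: tuple[int, int],
    a: np.ndarray,
    b: np.ndarray,
    width: float,
) -> np.ndarray:
    """Pixels within width/2 of the segment a-b."""
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    p = np.stack([rr, cc], axis=-1).astype(float)
    ab = b - a
    denom = float(ab @ ab)
    if denom < 1e-12:
        return _disc_mask(shape, tuple(a), width / 2.0)
    t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
    closest = a + t[..., None] * ab
    return np.linalg.norm(p - closest, axis=-1) <= width / 2.0


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _render_structure_frame(
    spec: FixtureSpec,
    offset: np.ndarray,
    spine_offsets: dict[int, np.ndarray],
) -> tuple[np.ndarray, dict]:
    """Noiseless structural image for one frame, plus its truth masks."""
    shape = spec.shape
    img = np.zeros(shape)
    truth: dict = {
        "dendrite_mask": None,
        "centreline": None,
        "spine_masks": [],
        "neck_masks": [],
    }
    A = spec.amplitude
    dend_mask = None
    chain = None
    if spec.dendrite is not None:
        control = np.asarray(spec.dendrite.control_points, float) + offset
        dend_mask, chain = _tube_mask(shape, control, spec.dendrite.width)
        img[dend_mask] = np.maximum(
            img[dend_mask], A * spec.dendrite.intensity_scale
        )
        truth["dendrite_mask"] = dend_mask
        truth["centreline"] = chain
    for si, sp in enumerate(spec.spines):
        extra = spine_offsets.get(si, np.zeros(2))
        hc = np.asarray(sp.center, float) + offset + extra
        head = _disc_mask(shape, tuple(hc), sp.head_radius)
        img[head] = np.maximum(img[head], A * sp.intensity_scale)
        neck = np.zeros(shape, bool)
        if sp.neck_length > 0 and sp.neck_width > 0 and chain is not None:
            q = chain[np.argmin(np.linalg.norm(chain - hc, axis=1))].astype(float)
            neck = _segment_mask(shape, hc, q, sp.neck_width)
            neck &= ~head
            if dend_mask is not None:
                neck &= ~dend_mask
            # necks image dim: thin sub-resolution stalks
            img[neck] = np.maximum(img[neck], 0.30 * A * sp.intensity_scale)
        truth["spine_masks"].append(head)
        truth["neck_masks"].append(neck)
    return img, truth


def _add_puncta(img: np.ndarray, spec: FixtureSpec, channel: int, offset: np.ndarray) -> None:
    rr, cc = np.mgrid[: img.shape[0], : img.shape[1]]
    for p in spec.puncta:
        if p.channel != channel:
            continue
        pr, pc = np.asarray(p.position, float) + offset
        d2 = (rr - pr) ** 2 + (cc - pc) ** 2
        if p.profile == "gauss":
            img += p.amplitude * np.exp(-d2 / (2.0 * p.sigma**2))
        else:
            img[d2 <= 2.0 * p.sigma**2] += p.amplitude


def render_fixture(spec: FixtureSpec) -> tuple[ImageStack, GroundTruth]:
    """Render a fixture spec into an image stack and its ground truth.

    Per frame: structures are drawn at their drifted (and, per spine,
    wandered) positions, puncta added, then the dark offset, Gaussian
    noise and salt-and-pepper corruption.  Ground-truth masks refer to
    frame 0; shift histories are recorded separately.
    """
    T, C = spec.n_timepoints, spec.n_channels
    h, w = spec.shape
    drift = (
        np.zeros((T, 2)) if spec.drift is None else np.asarray(spec.drift, float)
    )
    if drift.shape != (T, 2):
        raise ValueError("drift must be (n_timepoints, 2)")
    wander = {k: np.asarray(v, float) for k, v in (spec.wander or {}).items()}
    rng = np.random.default_rng(spec.seed)
    data = np.zeros((T, C, h, w))
    truth0: dict = {}
    for t in range(T):
        spine_offsets = {k: v[t] for k, v in wander.items()}
        frame, truth = _render_structure_frame(spec, drift[t], spine_offsets)
        if t == 0:
            truth0 = truth
        for c in range(C):
            img = frame.copy()
            _add_puncta(img, spec, c, drift[t])
            img += spec.background
            if spec.noise_sd > 0:
                img += rng.normal(0.0, spec.noise_sd, size=img.shape)
            if spec.salt_pepper > 0:
                n_bad = int(spec.salt_pepper * img.size)
                idx = rng.choice(img.size, size=n_bad, replace=False)
                vals = np.where(
                    rng.random(n_bad) < 0.5, 0.0, spec.background + 1.5 * spec.amplitude
                )
                img.flat[idx] = vals
            data[t, c] = np.clip(img, 0.0, None)

    # structures must stay in bounds in frame 0
    for sp in spec.spines:
        r, c = sp.center
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"spine centre {sp.center} out of bounds")
    stack = ImageStack(data, pixel_size=spec.pixel_size)
    widths = None
    if spec.dendrite is not None and truth0["centreline"] is not None:
        # a tube of nominal width w rendered as dist <= w/2 around a
        # pixel-centred line spans 2*floor(w/2)+1 pixels; record that
        effective = 2 * np.floor(spec.dendrite.width / 2.0) + 1.0
        widths = np.full(len(truth0["centreline"]), effective)
    gt = GroundTruth(
        dendrite_mask=truth0.get("dendrite_mask"),
        centreline=truth0.get("centreline"),
        widths=widths,
        spine_masks=truth0.get("spine_masks", []),
        spine_centers=[tuple(sp.center) for sp in spec.spines],
        spine_classes=[sp.implied_class() for sp in spec.spines],
        neck_masks=truth0.get("neck_masks", []),
        puncta=[
            {
                "position": p.position,
                "sigma": p.sigma,
                "channel": p.channel,
                "compartment": p.compartment,
            }
            for p in spec.puncta
        ],
        global_drift=drift,
        wander=wander,
        background=spec.background,
        noise_sd=spec.noise_sd,
    )
    return stack, gt


def measure_snr(stack: ImageStack, truth: GroundTruth, t: int = 0, c: int = 0) -> float:
    """Empirical (structure - background) / noise SD of a rendered frame.

    Quantile-based: level difference as median(foreground) -
    median(background); noise SD as the background's 84th-minus-50th
    percentile spread.  Both are insensitive to the floor clipping at
    zero intensity that heavy noise produces.
    """
    frame = stack.data[t, c]
    struct = truth.structure_mask()
    fg = ndi.binary_erosion(struct, iterations=1)
    if not fg.any():
        fg = struct
    bg = frame[~ndi.binary_dilation(struct, iterations=3)]
    spread = np.quantile(bg, 0.8413) - np.median(bg)
    return float((np.median(frame[fg]) - np.median(bg)) / spread)


# ---------------------------------------------------------------------------
# the canonical gallery
# ---------------------------------------------------------------------------

SNR_LADDER = (0.5, 1.0, 2.0, 3.0, 5.0)


def registration_scene_spec(seed: int = 0) -> FixtureSpec:
    """Curved spiny dendrite used for drift-recovery validation.

    A straight tube is nearly translation-invariant along its own axis;
    the curved path plus three spines pins both shift components.
    """
    return FixtureSpec(
        shape=(128, 128),
        dendrite=DendriteSpec(
            [(100, 10), (72, 36), (52, 64), (72, 92), (100, 118)], width=10.0
        ),
        spines=[
            SpineSpec((60, 30), 5.0, 7, 3),
            SpineSpec((30, 64), 5.0, 7, 3),
            SpineSpec((60, 100), 5.0, 7, 3),
        ],
        snr=None,
        seed=seed,
    )


def puncta_grid_spec(
    n: int,
    shape: tuple[int, int] = (220, 220),
    sigma: float = 2.0,
    amplitude: float = 100.0,
    snr: float = 20.0,
    seed: int = 0,
) -> FixtureSpec:
    """A field of ``n`` well-separated disc puncta on a dark background.

    Spot positions sit on a jittered grid with pairwise spacing well above
    the spot diameter, so every punctum is an isolated blob of known
    position and scale (the smFISH counting regime).
    """
    rng = np.random.default_rng(seed)
    k = int(np.ceil(np.sqrt(n)))
    pitch = (min(shape) - 30) / k
    if pitch < 6 * sigma:
        raise ValueError("too many puncta for the field size")
    pts = []
    for i in range(k):
        for j in range(k):
            if len(pts) < n:
                jit = rng.uniform(-pitch / 6, pitch / 6, size=2)
                pts.append((15 + (i + 0.5) * pitch + jit[0], 15 + (j + 0.5) * pitch + jit[1]))
    return FixtureSpec(
        shape=shape,
        amplitude=amplitude,
        puncta=[PunctumSpec(p, sigma=sigma, amplitude=amplitude) for p in pts],
        snr=snr,
        seed=seed,
    )


def _spiny_tube_spec(snr: float | None, seed: int, shape=(128, 128)) -> FixtureSpec:
    """Straight tube with four spines: the workhorse validation scene."""
    row = shape[0] // 2
    return FixtureSpec(
        shape=shape,
        dendrite=DendriteSpec([(row, 8), (row, shape[1] - 8)], width=10.0),
        spines=[
            SpineSpec((row - 19, 30), head_radius=6.0, neck_length=8.0, neck_width=2.0),
            SpineSpec((row + 17, 55), head_radius=5.0, neck_length=7.0, neck_width=6.0),
            SpineSpec((row - 9, 80), head_radius=5.0, neck_length=0.0),
            SpineSpec((row + 18, 102), head_radius=6.0, neck_length=7.0, neck_width=3.0),
        ],
        snr=snr,
        seed=seed,
    )


def fixture_gallery(seed: int = 0) -> dict[str, Fixture]:
    """The canonical named test scenes, rendered with ground truth.

    Contains a straight tube, a curved tube, a six-spine scene spanning
    all four morphology classes, a crowded spine pair 6 px apart, a
    puncta field with a soma and a dendrite, a drifting 5-frame series,
    and an SNR ladder at 0.5 / 1 / 2 / 3 / 5.
    """
    g: dict[str, Fixture] = {}

    def add(name: str, spec: FixtureSpec) -> None:
        stack, truth = render_fixture(spec)
        g[name] = Fixture(spec, stack, truth)

    add(
        "straight_tube",
        FixtureSpec(
            shape=(128, 128),
            dendrite=DendriteSpec([(64, 8), (64, 120)], width=10.0),
            snr=4.0,
            salt_pepper=0.002,
            seed=seed + 1,
        ),
    )
    add(
        "curved_tube",
        FixtureSpec(
            shape=(128, 128),
            dendrite=DendriteSpec(
                [(100, 10), (72, 36), (52, 64), (72, 92), (100, 118)], width=10.0
            ),
            snr=4.0,
            seed=seed + 2,
        ),
    )
    add(
        "four_class_spines",
        FixtureSpec(
            shape=(160, 160),
            dendrite=DendriteSpec([(80, 8), (80, 152)], width=10.0),
            spines=[
                SpineSpec((71, 20), head_radius=5.0, neck_length=0.0),  # stubby
                SpineSpec((61, 45), head_radius=6.0, neck_length=8.0, neck_width=2.0),  # mushroom
                SpineSpec((99, 70), head_radius=5.0, neck_length=8.0, neck_width=3.0),  # mushroom
                SpineSpec((62, 95), head_radius=4.0, neck_length=9.0, neck_width=6.0),  # thin
                SpineSpec((98, 120), head_radius=4.0, neck_length=8.0, neck_width=7.0),  # thin
                SpineSpec((64, 140), head_radius=3.0, neck_length=10.0, neck_width=8.0),  # outlier
            ],
            snr=4.0,
            seed=seed + 3,
        ),
    )
    add(
        "crowded_pair",
        FixtureSpec(
            shape=(96, 96),
            dendrite=DendriteSpec([(70, 4), (70, 92)], width=8.0),
            spines=[
                SpineSpec((40, 45), head_radius=4.0, neck_length=0.0),
                SpineSpec((40, 51), head_radius=4.0, neck_length=0.0),
            ],
            snr=5.0,
            seed=seed + 4,
        ),
    )
    soma_center = (48, 48)
    dend_points = [(72, 66), (110, 100), (140, 146)]
    # well-separated spots (pairwise > 9 px) so amplitudes never stack
    soma_spots = [(34, 40), (38, 54), (46, 30), (48, 62), (58, 40), (62, 54), (68, 44), (45, 46)]
    chain = interpolate_path(np.asarray(dend_points, float))
    neurite_spots = [tuple(chain[25]), tuple(chain[70])]  # on the centreline
    puncta = [
        PunctumSpec(p, sigma=2.0, amplitude=120.0, compartment="soma") for p in soma_spots
    ] + [
        PunctumSpec(p, sigma=2.0, amplitude=120.0, compartment="neurite")
        for p in neurite_spots
    ]
    add(
        "puncta_field",
        FixtureSpec(
            shape=(160, 160),
            amplitude=30.0,  # dim structural plateau under bright puncta
            dendrite=DendriteSpec(dend_points, width=9.0),
            spines=[SpineSpec(soma_center, head_radius=28.0, neck_length=0.0)],
            puncta=puncta,
            snr=10.0,
            seed=seed + 5,
        ),
    )
    T = 5
    add(
        "drifting_series",
        FixtureSpec(
            shape=(128, 128),
            n_timepoints=T,
            dendrite=DendriteSpec([(64, 8), (64, 120)], width=10.0),
            spines=[
                SpineSpec((45, 40), head_radius=5.0, neck_length=9.0, neck_width=3.0),
                SpineSpec((84, 85), head_radius=5.0, neck_length=9.0, neck_width=3.0),
            ],
            drift=np.array([(t, t) for t in range(T)], float),
            wander={0: np.array([(0, 0), (1, 0), (2, 1), (2, 1), (3, 2)], float)},
            snr=6.0,
            seed=seed + 6,
        ),
    )
    for snr in SNR_LADDER:
        add(f"snr_{snr:g}", _spiny_tube_spec(snr, seed=seed + 7 + int(snr * 2)))
    return g
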