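"""Synthetic apical four-chamber echo phantoms with analytically known LA strain.

A phantom scene mimics a 2-D echo sector scan: a fan-shaped bright speckle
sector on a black background containing two dark blood pools — an LV-like
chamber near the probe (top of the image) and the left atrium below it.  The
LA cavity is a truncated superellipse whose contour is scaled isotropically
about a fixed centre by a per-frame factor ``s(t)``, so the cavity contour
length is exactly ``s(t)`` times the base length and the reservoir strain
``s(t) - 1`` is known in closed form.  The module also constructs degenerate
fixtures, one per image-quality exclusion criterion, used to exercise the QC
checks.

Labels: 0 = background, 1 = LA cavity, 2 = LA wall.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Sequence

import numpy as np
from PIL import Image
from scipy import ndimage
import tifffile

__all__ = [
    "EchoSequence",
    "LabelMaskSequence",
    "PhantomTruth",
    "PhantomParams",
    "FixtureKind",
    "make_phantom",
    "make_fixture",
    "raised_cosine_scale",
    "write_sequence_png",
    "write_masks_png",
    "write_sequence_tiff",
    "write_truth_json",
    "read_sequence_png",
    "read_masks_png",
]

BACKGROUND, CAVITY, WALL = 0, 1, 2


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class EchoSequence:
    """A T-frame grayscale image stack (intensities in [0, 1])."""

    frames: list[np.ndarray]
    r_peak_index: int | None = None
    pixel_spacing: float | None = None  # mm / pixel
    id: str = ""

    def __post_init__(self):
        if len(self.frames) < 1:
            raise ValueError("sequence needs at least one frame")
        h, w = self.frames[0].shape
        for f in self.frames:
            if f.shape != (h, w):
                raise ValueError("all frames must share one height/width")
        if self.r_peak_index is not None and not (
            0 <= self.r_peak_index < len(self.frames)
        ):
            raise ValueError("r_peak_index out of range")

    @property
    def frame_count(self) -> int:
        return len(self.frames)

    @property
    def height(self) -> int:
        return self.frames[0].shape[0]

    @property
    def width(self) -> int:
        return self.frames[0].shape[1]


@dataclass
class LabelMaskSequence:
    """Per-frame label images aligned 1:1 with an EchoSequence."""

    masks: list[np.ndarray]

    def __post_init__(self):
        for m in self.masks:
            labels = np.unique(m)
            if not np.isin(labels, [BACKGROUND, CAVITY, WALL]).all():
                raise ValueError("mask labels must be in {0, 1, 2}")

    def __len__(self) -> int:
        return len(self.masks)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.masks[i]


@dataclass
class PhantomTruth:
    """Analytic ground truth of a phantom: base contour and scale function."""

    base_contour: np.ndarray          # (N, 2) closed polyline, (row, col), sub-pixel
    scale_values: np.ndarray          # s(t) per frame; s(base) == 1
    r_peak_index: int
    wall_thickness: int
    sector: dict                      # apex, span_deg, radius

    @property
    def true_strain(self) -> np.ndarray:
        return self.scale_values - 1.0

    def scale(self, t: int) -> float:
        return float(self.scale_values[t])


class FixtureKind(str, Enum):
    """The five constructed image-quality defects."""

    single_chamber = "a"
    truncated_bottom = "b"
    beyond_sector = "c"
    blurred_boundary = "d"
    black_region = "e"


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

def raised_cosine_scale(t: np.ndarray, s_max: float, T: int) -> np.ndarray:
    """Reservoir scale curve: s=1 at frame 0 (the R peak), peaking mid-sequence."""
    if T == 1:
        return np.ones(1)
    phase = np.sin(np.pi * t / (T - 1)) ** 2
    phase = phase / phase.max()  # peak scale hit exactly at some frame
    return 1.0 + (s_max - 1.0) * phase


@dataclass
class PhantomParams:
    """Geometry, noise and cardiac-cycle settings of a synthetic sequence.

    All geometric defaults are expressed for a 224-pixel image and scale
    linearly with ``size``.
    """

    size: int = 224
    frames: int = 40
    wall_thickness: int = 4
    s_max: float = 1.25
    scale_fn: Callable[[np.ndarray, int], np.ndarray] | None = None
    superellipse_p: float = 2.5
    la_center: tuple[float, float] | None = None      # (row, col)
    la_semiaxes: tuple[float, float] | None = None    # (row, col) semi-axes
    truncation: float = 0.62       # chord position, fraction of the row semi-axis
    tissue_level: float = 0.55
    wall_level: float = 0.85
    cavity_level: float = 0.15
    cavity_noise_sd: float = 0.03
    blur_sigma: float = 0.6
    sector_apex: tuple[float, float] | None = None
    sector_span_deg: float = 78.0
    sector_radius: float | None = None
    include_lv: bool = True
    contour_points: int = 400

    def validate(self):
        if self.size <= 0 or self.frames < 1:
            raise ValueError("image size and frame count must be positive")
        if self.wall_thickness < 1:
            raise ValueError("wall thickness must be at least 1 pixel")
        if self.scale_fn is None and self.s_max <= 1.0:
            raise ValueError("peak scale s_max must exceed 1")

    # resolved geometry, in pixels of the requested image size
    def _geom(self) -> dict:
        u = self.size / 224.0
        return {
            "la_center": self.la_center or (150.0 * u, 112.0 * u),
            "la_semiaxes": self.la_semiaxes or (38.0 * u, 45.0 * u),
            "apex": self.sector_apex or (8.0 * u, 112.0 * u),
            "radius": self.sector_radius or 210.0 * u,
            "lv_center": (62.0 * u, 112.0 * u),
            "lv_semiaxes": (40.0 * u, 34.0 * u),
            "lv_wall": max(2, int(round(self.wall_thickness * u / max(u, 1e-9)))),
        }


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _superellipse_contour(center, semiaxes, p, truncation, n) -> np.ndarray:
    """Closed (row, col) polyline of a superellipse with a flat top chord."""
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    cr, cc = center
    br, bc = semiaxes
    dy = br * np.sign(np.sin(theta)) * np.abs(np.sin(theta)) ** (2.0 / p)
    dx = bc * np.sign(np.cos(theta)) * np.abs(np.cos(theta)) ** (2.0 / p)
    # rows grow downward; the chamber "top" (annulus plane) is at negative dy
    dy = np.maximum(dy, -truncation * br)
    return np.column_stack([cr + dy, cc + dx])


def _fill_polygon(poly: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    from skimage.draw import polygon

    rr, cc = polygon(poly[:, 0], poly[:, 1], shape=shape)
    out = np.zeros(shape, dtype=bool)
    out[rr, cc] = True
    return out


def _sector_mask(shape, apex, span_deg, radius) -> np.ndarray:
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
    dr = rows - apex[0]
    dc = cols - apex[1]
    dist = np.hypot(dr, dc)
    ang = np.degrees(np.arctan2(dc, dr))  # 0 deg points straight down
    return (dist <= radius) & (np.abs(ang) <= span_deg / 2.0) & (dr >= 0)


def _disk(radius: int) -> np.ndarray:
    r = int(radius)
    y, x = np.ogrid[-r:r + 1, -r:r + 1]
    return x * x + y * y <= r * r


def _render_frame(cavity: np.ndarray, params: PhantomParams, geom: dict,
                  sector: np.ndarray, rng: np.random.Generator,
                  include_lv: bool) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize one frame: returns (image, label mask)."""
    shape = cavity.shape
    wall = ndimage.binary_dilation(cavity, structure=_disk(params.wall_thickness))
    wall &= ~cavity

    mask = np.zeros(shape, dtype=np.uint8)
    mask[cavity] = CAVITY
    mask[wall] = WALL

    img = np.zeros(shape)
    tissue = sector & ~cavity & ~wall
    # multiplicative exponential speckle on tissue and wall
    img[tissue] = params.tissue_level * rng.exponential(1.0, int(tissue.sum()))
    img[wall] = params.wall_level * rng.exponential(1.0, int(wall.sum()))
    img[cavity] = params.cavity_level + rng.normal(
        0.0, params.cavity_noise_sd, int(cavity.sum())
    )

    if include_lv:
        lv = _ellipse_mask(shape, geom["lv_center"], geom["lv_semiaxes"])
        lv &= sector & ~cavity & ~wall
        lv_wall = ndimage.binary_dilation(lv, structure=_disk(2)) & ~lv
        lv_wall &= sector & ~cavity & ~wall
        img[lv] = params.cavity_level + rng.normal(0.0, params.cavity_noise_sd,
                                                   int(lv.sum()))
        img[lv_wall] = params.wall_level * rng.exponential(1.0, int(lv_wall.sum()))

    img[~sector] = 0.0
    if params.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, params.blur_sigma)
        img[~sector] = 0.0
    return np.clip(img, 0.0, 1.0), mask


def _ellipse_mask(shape, center, semiaxes) -> np.ndarray:
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
    return ((rows - center[0]) / semiaxes[0]) ** 2 + (
        (cols - center[1]) / semiaxes[1]
    ) ** 2 <= 1.0


def make_phantom(params: PhantomParams | None = None, seed: int = 0,
                 ) -> tuple[EchoSequence, LabelMaskSequence, PhantomTruth]:
    """Generate one synthetic 4CH sequence with analytically known strain.

    The LA cavity polygon at frame ``t`` is the base contour scaled by
    ``s(t)`` about the LA centre, so its true contour length is
    ``s(t) * L_0`` exactly and the true strain is ``s(t) - 1``.
    """
    params = params or PhantomParams()
    params.validate()
    rng = np.random.default_rng(seed)
    geom = params._geom()
    shape = (params.size, params.size)

    base = _superellipse_contour(
        geom["la_center"], geom["la_semiaxes"], params.superellipse_p,
        params.truncation, params.contour_points,
    )
    t = np.arange(params.frames, dtype=float)
    if params.scale_fn is not None:
        scale = np.asarray(params.scale_fn(t, params.frames), dtype=float)
    else:
        scale = raised_cosine_scale(t, params.s_max, params.frames)
    if np.any(scale <= 0):
        raise ValueError("scale function must be positive")

    sector = _sector_mask(shape, geom["apex"], params.sector_span_deg,
                          geom["radius"])
    center = np.asarray(geom["la_center"])

    frames, masks = [], []
    for s in scale:
        poly = center + s * (base - center)
        cavity = _fill_polygon(poly, shape)
        img, mask = _render_frame(cavity, params, geom, sector, rng,
                                  params.include_lv)
        frames.append(img)
        masks.append(mask)

    base_index = int(np.argmin(np.abs(scale - 1.0)))
    truth = PhantomTruth(
        base_contour=base,
        scale_values=scale,
        r_peak_index=base_index,
        wall_thickness=params.wall_thickness,
        sector={"apex": list(geom["apex"]), "span_deg": params.sector_span_deg,
                "radius": geom["radius"]},
    )
    seq = EchoSequence(frames=frames, r_peak_index=base_index,
                       id=f"phantom-{seed}")
    return seq, LabelMaskSequence(masks=masks), truth


# ---------------------------------------------------------------------------
# Degenerate fixtures (one per exclusion criterion)
# ---------------------------------------------------------------------------

def make_fixture(kind: FixtureKind | str, seed: int = 0, size: int = 224,
                 ) -> tuple[EchoSequence, LabelMaskSequence]:
    """Construct a single-frame sequence violating exactly one QC criterion.

    a: only one chamber (no LV) -- b: mask truncated flat at the bottom image
    row -- c: part of the mask lies beyond the scan sector -- d: LA boundary
    blurred -- e: a large dark blob inside the mask.
    """
    kind = FixtureKind(kind)
    u = size / 224.0
    base_kwargs = dict(size=size, frames=1, scale_fn=lambda t, T: np.ones_like(t))

    if kind is FixtureKind.single_chamber:
        params = PhantomParams(include_lv=False, **base_kwargs)
        seq, masks, _ = make_phantom(params, seed)
    elif kind is FixtureKind.truncated_bottom:
        # push the LA into the bottom image edge; enlarge the sector so the
        # image boundary, not the sector, does the clipping
        params = PhantomParams(
            la_center=(214.0 * u, 112.0 * u), sector_radius=300.0 * u,
            **base_kwargs,
        )
        seq, masks, _ = make_phantom(params, seed)
    elif kind is FixtureKind.beyond_sector:
        # shrink the sector so the lower mask rim pokes past the arc
        params = PhantomParams(sector_radius=178.0 * u, **base_kwargs)
        seq, masks, _ = make_phantom(params, seed)
    elif kind is FixtureKind.blurred_boundary:
        params = PhantomParams(**base_kwargs)
        seq, masks, _ = make_phantom(params, seed)
        blurred = ndimage.gaussian_filter(seq.frames[0], 6.0 * u)
        seq = EchoSequence(frames=[blurred], r_peak_index=0, id=seq.id + "-d")
    elif kind is FixtureKind.black_region:
        params = PhantomParams(**base_kwargs)
        seq, masks, _ = make_phantom(params, seed)
        img = seq.frames[0].copy()
        cavity = masks[0] == CAVITY
        area = cavity.sum()
        r = int(np.ceil(np.sqrt(0.14 * area / np.pi)))
        cr, cc = ndimage.center_of_mass(cavity)
        rows, cols = np.mgrid[0:size, 0:size]
        blob = (rows - cr) ** 2 + (cols - cc) ** 2 <= r * r
        img[blob & cavity] = 0.01
        seq = EchoSequence(frames=[img], r_peak_index=0, id=seq.id + "-e")
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unknown fixture kind {kind!r}")

    seq.id = f"fixture-{kind.value}-{seed}"
    return seq, masks


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_PALETTE = [0, 0, 0, 0, 200, 0, 200, 0, 0]  # background, cavity, wall


def write_sequence_png(seq: EchoSequence, out_dir: str):
    os.makedirs(out_dir, exist_ok=True)
    for i, frame in enumerate(seq.frames):
        arr = (np.clip(frame, 0, 1) * 255).round().astype(np.uint8)
        Image.fromarray(arr, mode="L").save(
            os.path.join(out_dir, f"frame_{i:03d}.png")
        )


def write_masks_png(masks: LabelMaskSequence, out_dir: str):
    os.makedirs(out_dir, exist_ok=True)
    for i, mask in enumerate(masks.masks):
        im = Image.fromarray(mask.astype(np.uint8), mode="P")
        im.putpalette(_PALETTE + [0] * (768 - len(_PALETTE)))
        im.save(os.path.join(out_dir, f"mask_{i:03d}.png"))


def write_sequence_tiff(seq: EchoSequence, path: str):
    stack = np.stack([(np.clip(f, 0, 1) * 255).round().astype(np.uint8)
                      for f in seq.frames])
    tifffile.imwrite(path, stack, photometric="minisblack")


def write_truth_json(truth: PhantomTruth, path: str):
    payload = {
        "scale_values": truth.scale_values.tolist(),
        "base_contour": truth.base_contour.tolist(),
        "r_peak_index": truth.r_peak_index,
        "wall_thickness": truth.wall_thickness,
        "sector": truth.sector,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_sequence_png(in_dir: str, r_peak_index: int | None = None,
                      ) -> EchoSequence:
    names = sorted(n for n in os.listdir(in_dir)
                   if n.startswith("frame_") and n.endswith(".png"))
    if not names:
        raise FileNotFoundError(f"no frame_*.png in {in_dir}")
    frames = [np.asarray(Image.open(os.path.join(in_dir, n)).convert("L"),
                         dtype=float) / 255.0 for n in names]
    meta = os.path.join(in_dir, "meta.json")
    if r_peak_index is None and os.path.exists(meta):
        with open(meta) as fh:
            r_peak_index = json.load(fh).get("r_peak_index")
    return EchoSequence(frames=frames, r_peak_index=r_peak_index,
                        id=os.path.basename(in_dir))


def read_masks_png(in_dir: str) -> LabelMaskSequence:
    names = sorted(n for n in os.listdir(in_dir)
                   if n.startswith("mask_") and n.endswith(".png"))
    if not names:
        raise FileNotFoundError(f"no mask_*.png in {in_dir}")
    masks = [np.asarray(Image.open(os.path.join(in_dir, n)), dtype=np.uint8)
             for n in names]
    return LabelMaskSequence(masks=masks)
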