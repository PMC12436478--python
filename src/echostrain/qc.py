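"""Automated clean-subset exclusion criteria for segmentation training data.

Five per-image checks mirror the visual exclusion criteria used when curating
echo frames for segmentation training: (a) only a single chamber visible,
(b) the ground-truth mask truncated flat against the bottom image row,
(c) the mask extending beyond the scan sector, (d) a blurred LA boundary,
and (e) a significant black region inside the mask.  Each check is a
measurable proxy with a configurable threshold; ``apply_exclusions`` filters
a dataset and writes a per-image report.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .phantom import BACKGROUND, CAVITY, WALL
from .strain import extract_contour, EmptyCavityError

__all__ = [
    "QCReport",
    "QCThresholds",
    "check_single_chamber",
    "check_truncated_bottom",
    "check_beyond_sector",
    "check_blurred_boundary",
    "check_black_region",
    "qc_image",
    "apply_exclusions",
    "boundary_gradient",
]


@dataclass
class QCThresholds:
    """Proxy thresholds for the five exclusion criteria."""

    second_chamber_area_frac: float = 0.25   # of cavity area (flag a)
    dark_chamber_level: float = 0.35         # intensity below = chamber-dark
    bottom_run_pixels: int = 20              # consecutive mask pixels (flag b)
    sector_support_level: float = 0.02       # intensity support (flag c)
    beyond_sector_frac: float = 0.02         # of mask pixels (flag c)
    blur_gradient_frac: float = 0.5          # of reference gradient (flag d)
    black_level: float = 0.05                # "black" intensity (flag e)
    black_blob_frac: float = 0.10            # of cavity area (flag e)


@dataclass
class QCReport:
    """Flags and diagnostics for one image; excluded = any flag raised."""

    image_id: str
    flag_a: bool
    flag_b: bool
    flag_c: bool
    flag_d: bool
    flag_e: bool
    diagnostics: dict = field(default_factory=dict)

    @property
    def excluded(self) -> bool:
        return self.flag_a or self.flag_b or self.flag_c or self.flag_d or self.flag_e


def _sector_support(image: np.ndarray, level: float) -> np.ndarray:
    """Estimate the scan-sector footprint: bright support, closed and filled
    so enclosed dark blood pools count as inside."""
    support = np.pad(image > level, 1, mode="edge")
    support = ndimage.binary_closing(support, structure=np.ones((3, 3)))
    return ndimage.binary_fill_holes(support)[1:-1, 1:-1]


def check_single_chamber(image: np.ndarray, mask: np.ndarray,
                         thresholds: QCThresholds | None = None) -> bool:
    """Flag a: no second dark-chamber candidate besides the LA."""
    th = thresholds or QCThresholds()
    la = np.asarray(mask) > 0
    if not la.any():
        raise ValueError("empty mask")
    cavity_area = int((np.asarray(mask) == CAVITY).sum())
    sector = _sector_support(image, th.sector_support_level)
    dark = (image < th.dark_chamber_level) & sector
    dark &= ~ndimage.binary_dilation(la, iterations=3)
    labeled, n = ndimage.label(dark)
    if n == 0:
        return True
    sizes = ndimage.sum_labels(dark, labeled, index=np.arange(1, n + 1))
    return bool(sizes.max() < th.second_chamber_area_frac * cavity_area)


def check_truncated_bottom(mask: np.ndarray,
                           thresholds: QCThresholds | None = None) -> bool:
    """Flag b: a long flat run of mask pixels on the last image row."""
    th = thresholds or QCThresholds()
    bottom = np.asarray(mask)[-1] > 0
    if not bottom.any():
        return False
    # longest run of consecutive True values
    padded = np.concatenate([[0], bottom.astype(int), [0]])
    edges = np.flatnonzero(np.diff(padded))
    runs = edges[1::2] - edges[0::2]
    return bool(runs.max() >= th.bottom_run_pixels)


def check_beyond_sector(image: np.ndarray, mask: np.ndarray,
                        thresholds: QCThresholds | None = None) -> bool:
    """Flag c: the mask extends beyond the echocardiographic sector."""
    th = thresholds or QCThresholds()
    if image.size == 0:
        raise ValueError("empty image")
    m = np.asarray(mask) > 0
    if not m.any():
        return False
    sector = _sector_support(image, th.sector_support_level)
    outside = m & ~sector
    return bool(outside.sum() / m.sum() >= th.beyond_sector_frac)


def boundary_gradient(image: np.ndarray, mask: np.ndarray) -> float:
    """Mean image-gradient magnitude sampled along the cavity contour."""
    poly = extract_contour(mask)
    gy, gx = np.gradient(np.asarray(image, dtype=float))
    gmag = np.hypot(gy, gx)
    rr = np.clip(np.round(poly[:, 0]).astype(int), 0, image.shape[0] - 1)
    cc = np.clip(np.round(poly[:, 1]).astype(int), 0, image.shape[1] - 1)
    return float(gmag[rr, cc].mean())


def check_blurred_boundary(image: np.ndarray, mask: np.ndarray,
                           reference_gradient: float,
                           thresholds: QCThresholds | None = None) -> bool:
    """Flag d: boundary gradient below a fraction of the dataset reference
    (typically the dataset median boundary gradient)."""
    th = thresholds or QCThresholds()
    g = boundary_gradient(image, mask)
    return bool(g < th.blur_gradient_frac * reference_gradient)


def check_black_region(image: np.ndarray, mask: np.ndarray,
                       thresholds: QCThresholds | None = None) -> bool:
    """Flag e: a connected black blob inside the mask covering a significant
    fraction of the cavity.  Scattered dark speckle pixels do not trigger it;
    the normal dark blood pool is not 'black' at the 0.05 level."""
    th = thresholds or QCThresholds()
    m = np.asarray(mask) > 0
    if not m.any():
        return False
    cavity_area = max(int((np.asarray(mask) == CAVITY).sum()), 1)
    dark = (np.asarray(image) < th.black_level) & m
    if not dark.any():
        return False
    labeled, n = ndimage.label(dark)
    sizes = ndimage.sum_labels(dark, labeled, index=np.arange(1, n + 1))
    return bool(sizes.max() >= th.black_blob_frac * cavity_area)


def qc_image(image: np.ndarray, mask: np.ndarray, reference_gradient: float,
             image_id: str = "", thresholds: QCThresholds | None = None,
             ) -> QCReport:
    """Run all five checks on one (image, mask) pair."""
    th = thresholds or QCThresholds()
    try:
        grad = boundary_gradient(image, mask)
    except EmptyCavityError:
        grad = 0.0
    return QCReport(
        image_id=image_id,
        flag_a=check_single_chamber(image, mask, th),
        flag_b=check_truncated_bottom(mask, th),
        flag_c=check_beyond_sector(image, mask, th),
        flag_d=grad < th.blur_gradient_frac * reference_gradient,
        flag_e=check_black_region(image, mask, th),
        diagnostics={"boundary_gradient": grad,
                     "reference_gradient": reference_gradient},
    )


def apply_exclusions(dataset: list[tuple[np.ndarray, np.ndarray]],
                     ids: list[str] | None = None,
                     thresholds: QCThresholds | None = None,
                     ) -> tuple[list[tuple[np.ndarray, np.ndarray]], list[QCReport]]:
    """Filter a dataset of (image, mask) pairs; returns (clean subset, reports).

    The blur reference is the median boundary gradient over the dataset, so
    the check adapts to the dataset's overall sharpness.  The input dataset
    is not modified.
    """
    if not dataset:
        raise ValueError("empty dataset")
    th = thresholds or QCThresholds()
    ids = ids or [f"img_{i:04d}" for i in range(len(dataset))]
    grads = []
    for image, mask in dataset:
        try:
            grads.append(boundary_gradient(image, mask))
        except EmptyCavityError:
            grads.append(np.nan)
    reference = float(np.nanmedian(grads))
    reports = [qc_image(img, msk, reference, image_id=i, thresholds=th)
               for (img, msk), i in zip(dataset, ids)]
    clean = [pair for pair, rep in zip(dataset, reports) if not rep.excluded]
    return clean, reports


def reports_to_frame(reports: list[QCReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        row = {"image_id": r.image_id, "flag_a": r.flag_a, "flag_b": r.flag_b,
               "flag_c": r.flag_c, "flag_d": r.flag_d, "flag_e": r.flag_e,
               "excluded": r.excluded}
        row.update(r.diagnostics)
        rows.append(row)
    return pd.DataFrame(rows)
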