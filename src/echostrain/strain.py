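"""Left-atrial reservoir strain from segmentation masks.

The LA endocardial border is recovered per frame as the sub-pixel 0.5
iso-contour of the (lightly smoothed) binary cavity field, its perimeter is
the contour length ``L_t``, and the strain at frame ``t`` is

    strain_t = (L_t - L_0) / L_0

with ``L_0`` the length at the base frame — the ECG R-peak frame when one is
recorded, otherwise the frame of minimum contour length (the LA is smallest
at LV end-diastole).  Curves are resampled to 30 equidistant frames for the
downstream classifier; peak strain is the curve maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .phantom import CAVITY, LabelMaskSequence

__all__ = [
    "ContourSeries",
    "StrainCurve",
    "EmptyCavityError",
    "InsufficientFramesError",
    "extract_contour",
    "contour_length",
    "select_base_frame",
    "strain_curve",
    "resample_equidistant",
    "peak_strain",
    "sequence_to_strain",
    "RESAMPLED_LENGTH",
]

RESAMPLED_LENGTH = 30


class EmptyCavityError(ValueError):
    """Raised when a mask frame contains no cavity pixels."""


class InsufficientFramesError(ValueError):
    """Raised when a sequence has fewer frames than the resampling length."""


@dataclass
class ContourSeries:
    """Per-frame endocardial contours and their lengths (pixels)."""

    contours: list[np.ndarray]       # each (N, 2) closed polyline, (row, col)
    lengths: np.ndarray              # L_t per frame
    base_index: int

    @property
    def base_length(self) -> float:
        return float(self.lengths[self.base_index])


@dataclass
class StrainCurve:
    """Fractional LA strain per frame; 30 values when resampled."""

    values: np.ndarray
    base_index: int
    is_resampled: bool = False

    @property
    def peak(self) -> float:
        return float(np.max(self.values))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.is_resampled and len(self.values) != RESAMPLED_LENGTH:
            raise ValueError(
                f"resampled curve must have {RESAMPLED_LENGTH} values"
            )


def extract_contour(mask_frame: np.ndarray, smooth_sigma: float = 1.0,
                    ) -> np.ndarray:
    """Sub-pixel closed contour of the largest cavity component.

    The binary cavity field is smoothed with a small Gaussian before
    iso-contouring at 0.5: marching squares on the raw binary field follows
    the pixel staircase and overestimates perimeter, while the smoothed field
    crosses 0.5 at sub-pixel positions close to the true border.
    """
    cavity = np.asarray(mask_frame) == CAVITY
    if not cavity.any():
        raise EmptyCavityError("empty cavity: no pixels with the cavity label")
    labeled, n = ndimage.label(cavity)
    if n > 1:
        sizes = ndimage.sum_labels(cavity, labeled, index=np.arange(1, n + 1))
        cavity = labeled == (int(np.argmax(sizes)) + 1)
    # pad so a component touching the border still yields a closed contour
    f = ndimage.gaussian_filter(np.pad(cavity, 2).astype(float), smooth_sigma)
    contours = measure.find_contours(f, 0.5)
    if not contours:
        raise EmptyCavityError("cavity vanished during contour extraction")
    poly = max(contours, key=_poly_length) - 2.0  # undo the padding offset
    return poly


def _poly_length(poly: np.ndarray) -> float:
    d = np.diff(poly, axis=0)
    return float(np.sqrt((d * d).sum(axis=1)).sum())


def contour_length(polyline: np.ndarray) -> float:
    """Perimeter of a closed polyline: consecutive vertex distances plus the
    closing segment."""
    poly = np.asarray(polyline, dtype=float)
    if np.allclose(poly[0], poly[-1]) and len(poly) > 1:
        poly = poly[:-1]
    if len(poly) < 3:
        raise ValueError("a closed contour needs at least 3 distinct vertices")
    d = np.diff(np.vstack([poly, poly[:1]]), axis=0)
    return float(np.sqrt((d * d).sum(axis=1)).sum())


def select_base_frame(lengths: np.ndarray, r_peak_index: int | None = None,
                      ) -> int:
    """Base frame: the R peak if recorded, else the minimum-length frame."""
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size < 1:
        raise ValueError("at least one frame required")
    if r_peak_index is not None:
        if not 0 <= r_peak_index < lengths.size:
            raise ValueError("r_peak_index out of range")
        return int(r_peak_index)
    return int(np.argmin(lengths))  # argmin ties break to the smallest index


def strain_curve(lengths: np.ndarray, base_index: int) -> StrainCurve:
    """strain_t = (L_t - L_0) / L_0; exactly zero at the base frame."""
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("contour lengths must be positive")
    l0 = lengths[base_index]
    values = (lengths - l0) / l0
    values[base_index] = 0.0
    return StrainCurve(values=values, base_index=base_index)


def resample_equidistant(curve: StrainCurve, m: int = RESAMPLED_LENGTH,
                         ) -> StrainCurve:
    """Pick m equidistant frames (first and last always included)."""
    T = len(curve.values)
    if T < m:
        raise InsufficientFramesError(
            f"insufficient frames: {T} < {m} required for equidistant sampling"
        )
    idx = np.round(np.arange(m) * (T - 1) / (m - 1)).astype(int)
    new_base = int(np.argmin(np.abs(idx - curve.base_index)))
    return StrainCurve(values=curve.values[idx], base_index=new_base,
                       is_resampled=(m == RESAMPLED_LENGTH))


def peak_strain(curve: StrainCurve | np.ndarray) -> float:
    """Maximum strain across all timestamps."""
    values = curve.values if isinstance(curve, StrainCurve) else np.asarray(curve)
    if values.size == 0:
        raise ValueError("empty strain curve")
    return float(np.max(values))


def contour_series(masks: LabelMaskSequence, r_peak_index: int | None = None,
                   smooth_sigma: float = 1.0,
                   median_filter: bool = False) -> ContourSeries:
    """Contours and lengths for every frame of a mask sequence."""
    contours, lengths = [], []
    for i, mask in enumerate(masks.masks):
        try:
            poly = extract_contour(mask, smooth_sigma=smooth_sigma)
        except EmptyCavityError as exc:
            raise EmptyCavityError(f"frame {i}: {exc}") from exc
        contours.append(poly)
        lengths.append(contour_length(poly))
    lengths = np.asarray(lengths)
    if median_filter and len(lengths) >= 3:
        lengths = ndimage.median_filter(lengths, size=3, mode="nearest")
    base = select_base_frame(lengths, r_peak_index)
    return ContourSeries(contours=contours, lengths=lengths, base_index=base)


def sequence_to_strain(masks: LabelMaskSequence,
                       r_peak_index: int | None = None,
                       resample: bool = True,
                       smooth_sigma: float = 1.0,
                       median_filter: bool = False) -> StrainCurve:
    """Masks -> contours -> lengths -> strain curve (-> 30-point resampling)."""
    series = contour_series(masks, r_peak_index, smooth_sigma, median_filter)
    curve = strain_curve(series.lengths, series.base_index)
    if resample:
        curve = resample_equidistant(curve)
    return curve
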