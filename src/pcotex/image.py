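"""Image loading, calibrated grayscale conversion, and analysis masks.

The scoring region of a retroillumination photograph is the central disc of
the intraocular-lens optic (clinically, the central 4.0 mm).  Bright Purkinje
reflexes from the axial illumination saturate pixels and destroy the texture
there, so saturated regions are detected and excluded from every downstream
computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
from scipy import ndimage

from .errors import EmptyMaskError, ImageFormatError

#: Rec. 601 luminance weights, the conventional RGB -> gray reduction.
DEFAULT_LUMINANCE_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class GrayImage:
    """A 2-D grayscale raster with intensities in [0, 1].

    Parameters
    ----------
    pixels : ndarray of float, shape (H, W)
        Intensities in the closed unit interval.
    mm_per_pixel : float, optional
        Physical pixel pitch; used only to convert millimetre ROI diameters
        to pixels.
    """

    pixels: np.ndarray
    mm_per_pixel: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.size == 0:
            raise ImageFormatError("pixels must be a non-empty 2-D array")
        if not np.all(np.isfinite(px)):
            raise ImageFormatError("pixels contain non-finite values")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ImageFormatError("intensities must lie in [0, 1]")
        if self.mm_per_pixel is not None and not self.mm_per_pixel > 0:
            raise ValueError("mm_per_pixel must be positive")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class AnalysisMask:
    """Boolean raster of pixels that take part in classification and scoring."""

    inside: np.ndarray
    n_valid: int = field(init=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.inside, dtype=bool)
        if m.ndim != 2 or m.size == 0:
            raise ValueError("mask must be a non-empty 2-D boolean array")
        self.inside = m
        self.n_valid = int(m.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.inside.shape  # type: ignore[return-value]


def _scale_to_unit(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    if np.issubdtype(arr.dtype, np.floating):
        out = arr.astype(np.float64)
        if out.size and (out.min() < 0.0 or out.max() > 1.0):
            raise ImageFormatError(
                "floating-point images must already be scaled to [0, 1]"
            )
        return out
    raise ImageFormatError(f"unsupported pixel dtype {arr.dtype}")


def load_image(
    path: str | Path,
    luminance_weights: tuple[float, float, float] = DEFAULT_LUMINANCE_WEIGHTS,
    mm_per_pixel: float | None = None,
) -> GrayImage:
    """Read an 8/16-bit PNG or TIFF, gray or RGB, as a unit-scaled GrayImage.

    RGB images are reduced with the weighted channel sum
    ``w_r R + w_g G + w_b B``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise ImageFormatError(f"could not read {path}: {exc}") from exc

    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    if arr.ndim == 2:
        gray = _scale_to_unit(arr)
    elif arr.ndim == 3 and arr.shape[-1] == 3:
        w = np.asarray(luminance_weights, dtype=np.float64)
        if w.shape != (3,):
            raise ValueError("luminance_weights must have length 3")
        gray = _scale_to_unit(arr) @ w
        # the weighted sum of unit channels can overshoot 1 by float error
        gray = np.clip(gray, 0.0, 1.0)
    else:
        raise ImageFormatError(
            f"unsupported channel layout {arr.shape}; expected gray or RGB"
        )
    return GrayImage(gray, mm_per_pixel=mm_per_pixel)


def roi_diameter_px(mm_diameter: float, mm_per_pixel: float) -> float:
    """Convert a physical ROI diameter (e.g. the 4.0 mm optic disc) to pixels."""
    if mm_diameter <= 0 or mm_per_pixel <= 0:
        raise ValueError("diameter and pixel pitch must be positive")
    return mm_diameter / mm_per_pixel


def make_roi_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    diameter: float,
) -> AnalysisMask:
    """Circular region-of-interest mask.

    A pixel belongs to the ROI iff its center lies *strictly* inside the open
    disc of the given diameter; pixels exactly on the boundary are excluded.

    Parameters
    ----------
    shape : (H, W)
    center : (row, col) of the circle center, in pixel coordinates.
    diameter : circle diameter in pixels.
    """
    h, w = shape
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    cr, cc = center
    if not (0 <= cr <= h - 1 and 0 <= cc <= w - 1):
        raise ValueError("center must lie inside the grid")
    rows = np.arange(h, dtype=np.float64)[:, None] - cr
    cols = np.arange(w, dtype=np.float64)[None, :] - cc
    inside = rows**2 + cols**2 < (diameter / 2.0) ** 2
    if not inside.any():
        raise EmptyMaskError("ROI circle contains no pixel centers")
    return AnalysisMask(inside)


def detect_reflex_mask(
    img: GrayImage,
    saturation_threshold: float = 0.98,
    dilation_radius: int = 2,
) -> np.ndarray:
    """Mask of saturated Purkinje-reflex pixels, grown by a square dilation.

    Returns a boolean array that is True where intensity >= threshold,
    morphologically dilated by a (2r+1) x (2r+1) square.  An all-False
    result is valid (no reflexes present).
    """
    if not 0 < saturation_threshold <= 1:
        raise ValueError("saturation_threshold must be in (0, 1]")
    if dilation_radius < 0:
        raise ValueError("dilation_radius must be non-negative")
    sat = img.pixels >= saturation_threshold
    if dilation_radius == 0 or not sat.any():
        return sat
    size = 2 * dilation_radius + 1
    return ndimage.binary_dilation(sat, structure=np.ones((size, size), bool))


def combine_masks(roi: AnalysisMask, reflex: np.ndarray) -> AnalysisMask:
    """Valid-pixel mask: inside the ROI and not on a reflex."""
    reflex = np.asarray(reflex, dtype=bool)
    if reflex.shape != roi.shape:
        raise ValueError("mask shapes differ")
    inside = roi.inside & ~reflex
    if not inside.any():
        raise EmptyMaskError("no valid pixels remain after reflex exclusion")
    return AnalysisMask(inside)


def save_mask_png(mask: AnalysisMask, path: str | Path) -> None:
    """Export a mask as an 8-bit PNG (0 outside, 255 inside)."""
    iio.imwrite(Path(path), (mask.inside.astype(np.uint8) * 255))
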