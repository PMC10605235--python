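"""Calibrated micrograph container, file I/O, and uniform preprocessing.

A :class:`Micrograph` holds a single-channel intensity array normalized to
[0, 1] plus the nm-per-pixel calibration and optional nucleus/exclusion masks.
The brightness/contrast adjustment reproduces common image-editor semantics:
a linear gain for brightness followed by a midpoint-pivot stretch for
contrast, applied uniformly to every pixel and clipped to [0, 1].
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import tifffile
from skimage.draw import polygon2mask

from .errors import ValidationError

# Rec. 601 luma weights for collapsing pseudo-colored RGB overlays.
_REC601 = np.array([0.299, 0.587, 0.114])


@dataclass
class Micrograph:
    """A calibrated 2-D grayscale electron micrograph.

    Parameters
    ----------
    pixels:
        2-D float array, finite, within [0, 1].
    scale_nm_per_px:
        Physical pixel pitch in nanometers; must be positive.
    exclusion_mask:
        Optional boolean array (same shape); True marks pixels to ignore
        (artifacts, nucleolus, non-relevant areas).
    nucleus_mask:
        Optional boolean array; True marks pixels inside the nuclear section.
        Absent means the whole frame is nucleus.
    """

    pixels: np.ndarray
    scale_nm_per_px: float
    exclusion_mask: Optional[np.ndarray] = None
    nucleus_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValidationError("pixels must be a 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("pixels must be finite")
        if self.pixels.size and (self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9):
            raise ValidationError("pixels must lie in [0, 1] after normalization")
        if not (np.isscalar(self.scale_nm_per_px) and self.scale_nm_per_px > 0):
            raise ValidationError("scale_nm_per_px must be a positive scalar")
        self.scale_nm_per_px = float(self.scale_nm_per_px)
        for name in ("exclusion_mask", "nucleus_mask"):
            m = getattr(self, name)
            if m is not None:
                m = np.asarray(m, dtype=bool)
                if m.shape != self.pixels.shape:
                    raise ValidationError(f"{name} shape {m.shape} != image shape {self.pixels.shape}")
                setattr(self, name, m)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def analysis_mask(self) -> np.ndarray:
        """Boolean mask of pixels that enter the analysis (nucleus minus exclusions)."""
        mask = np.ones(self.pixels.shape, dtype=bool) if self.nucleus_mask is None else self.nucleus_mask.copy()
        if self.exclusion_mask is not None:
            mask &= ~self.exclusion_mask
        return mask

    def with_pixels(self, pixels: np.ndarray) -> "Micrograph":
        """Return a copy with new pixel data, carrying calibration and masks through."""
        return replace(self, pixels=pixels)


def read_micrograph(path: str | Path, scale_nm_per_px: float) -> Micrograph:
    """Read a TIFF/PNG raster into a normalized :class:`Micrograph`.

    8- and 16-bit integer images are mapped linearly onto [0, 1]; float images
    must already lie in [0, 1]. RGB(A) inputs are collapsed by Rec. 601
    luminance.
    """
    if not (np.isscalar(scale_nm_per_px) and scale_nm_per_px > 0):
        raise ValidationError("scale_nm_per_px must be positive")
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such image: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise IOError(f"could not decode image {path}: {exc}") from exc
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        arr = (arr.astype(float) - info.min) / (info.max - info.min)
    else:
        arr = arr.astype(float)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _REC601
    if arr.ndim != 2:
        raise IOError(f"expected a 2-D image, got shape {arr.shape}")
    pixels = arr
    return Micrograph(pixels=np.clip(pixels, 0.0, 1.0), scale_nm_per_px=float(scale_nm_per_px))


def write_micrograph(img: Micrograph, path: str | Path) -> Path:
    """Write pixels as a 16-bit grayscale TIFF or PNG (lossless to 1/65535)."""
    path = Path(path)
    data = np.round(np.clip(img.pixels, 0, 1) * 65535).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)
    return path


def adjust_brightness_contrast(
    img: Micrograph, brightness_pct: float = 50.0, contrast_pct: float = 80.0
) -> Micrograph:
    """Uniform brightness/contrast adjustment.

    ``v1 = v * (1 + brightness_pct/100)`` then
    ``v2 = (v1 - 0.5) * (1 + contrast_pct/100) + 0.5``, clipped to [0, 1].
    The transform is monotone non-decreasing in input intensity before
    clipping (for percentages > -100) and leaves shape, calibration and masks
    untouched. Defaults are the uniform 50%/80% adjustment applied to every
    micrograph before automatic annotation.
    """
    if brightness_pct < -100 or contrast_pct < -100:
        raise ValidationError("brightness/contrast percentages must be >= -100")
    v1 = img.pixels * (1.0 + brightness_pct / 100.0)
    v2 = (v1 - 0.5) * (1.0 + contrast_pct / 100.0) + 0.5
    return img.with_pixels(np.clip(v2, 0.0, 1.0))


def apply_exclusion(img: Micrograph, regions: Sequence[np.ndarray]) -> Micrograph:
    """Mark polygonal regions as excluded (union with any existing mask).

    ``regions`` is a sequence of (N, 2) vertex arrays in (row, col) pixel
    coordinates; each polygon needs at least 3 vertices. Pixels whose centers
    fall inside a polygon are excluded from all downstream analysis.
    """
    mask = (
        np.zeros(img.pixels.shape, dtype=bool)
        if img.exclusion_mask is None
        else img.exclusion_mask.copy()
    )
    for poly in regions:
        poly = np.asarray(poly, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
            raise ValidationError("each exclusion polygon needs >= 3 (row, col) vertices")
        mask |= polygon2mask(img.pixels.shape, poly)
    return replace(img, exclusion_mask=mask)
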