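"""Neck-photograph preprocessing.

The screening pipeline reduces a raw neck photograph to a clean grayscale
patch of the lower anterior neck in four steps:

1. crop to the region of interest (jawline to sternal notch), given
   explicitly as a :class:`CropSpec` — cropping is a manual/semantic step,
   so no automatic landmark detection is attempted;
2. keep the bottom half of the crop (the clavicular region, where loss of
   muscle mass shows as recesses and wrinkles);
3. convert to grayscale (ITU-R BT.601 luma weights by default);
4. apply a 5x5 median filter to remove speckling noise.

Images are plain numpy arrays with intensities in [0, 1]: 2-D ``(H, W)``
for grayscale, 3-D ``(H, W, 3)`` for RGB.  All coordinates are 0-based,
row-major, with half-open ``[top, bottom) x [left, right)`` intervals.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "BT601_WEIGHTS",
    "AVERAGE_WEIGHTS",
    "CropSpec",
    "load_image",
    "save_image",
    "crop",
    "lower_half",
    "to_grayscale",
    "median_filter",
    "preprocess",
]

#: ITU-R BT.601 luma weights, the common still-image grayscale convention.
BT601_WEIGHTS = (0.299, 0.587, 0.114)

#: Plain channel average, offered as an alternative grayscale convention.
AVERAGE_WEIGHTS = (1 / 3, 1 / 3, 1 / 3)


@dataclass(frozen=True)
class CropSpec:
    """Rectangular crop, 0-based half-open: rows [top, bottom), cols [left, right)."""

    top: int
    bottom: int
    left: int
    right: int

    def __post_init__(self) -> None:
        if not (self.top < self.bottom and self.left < self.right):
            raise ValueError(f"degenerate crop spec: {self}")
        if min(self.top, self.left) < 0:
            raise ValueError(f"negative crop indices: {self}")

    def validate(self, height: int, width: int) -> None:
        if self.bottom > height or self.right > width:
            raise ValueError(
                f"crop spec {self} exceeds image bounds {height}x{width}"
            )

    def compose(self, inner: "CropSpec") -> "CropSpec":
        """Spec equivalent to cropping with ``self`` then ``inner``."""
        return CropSpec(
            top=self.top + inner.top,
            bottom=self.top + inner.bottom,
            left=self.left + inner.left,
            right=self.left + inner.right,
        )

    @classmethod
    def parse(cls, text: str) -> "CropSpec":
        """Parse the ``top:bottom:left:right`` command-line form."""
        parts = text.split(":")
        if len(parts) != 4:
            raise ValueError(f"expected top:bottom:left:right, got {text!r}")
        return cls(*(int(p) for p in parts))


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim not in (2, 3):
        raise ValueError(f"expected 2-D or 3-D image array, got shape {image.shape}")
    if image.ndim == 3 and image.shape[2] != 3:
        raise ValueError(f"RGB image must have 3 channels, got {image.shape[2]}")
    return image


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Read an 8-bit PNG/TIFF as a float array in [0, 1].

    Grayscale files load as 2-D arrays; colour files as ``(H, W, 3)`` RGB
    (alpha channels are dropped).
    """
    try:
        with Image.open(path) as im:
            if im.mode in ("L", "I;16", "I"):
                im = im.convert("L")
                arr = np.asarray(im, dtype=float)
            else:
                im = im.convert("RGB")
                arr = np.asarray(im, dtype=float)
    except (OSError, Image.UnidentifiedImageError) as exc:
        raise OSError(f"cannot read image file {path!r}: {exc}") from exc
    return arr / 255.0


def save_image(image: np.ndarray, path: str | os.PathLike) -> None:
    """Write a [0, 1] float image as 8-bit PNG/TIFF (values are rounded)."""
    image = _check_image(image)
    arr = np.rint(np.clip(image, 0.0, 1.0) * 255.0).astype(np.uint8)
    Image.fromarray(arr).save(path)


def crop(image: np.ndarray, spec: CropSpec) -> np.ndarray:
    """Extract the sub-grid defined by ``spec`` (grayscale or RGB)."""
    image = _check_image(image)
    spec.validate(image.shape[0], image.shape[1])
    return image[spec.top : spec.bottom, spec.left : spec.right].copy()


def lower_half(image: np.ndarray) -> np.ndarray:
    """Rows ``[floor(H/2), H)`` — the bottom half; odd heights keep the larger half."""
    image = _check_image(image)
    height = image.shape[0]
    if height < 2:
        raise ValueError(f"image height {height} too small to halve")
    return image[height // 2 :].copy()


def to_grayscale(
    image: np.ndarray, weights: tuple[float, float, float] = BT601_WEIGHTS
) -> np.ndarray:
    """Weighted channel sum; BT.601 luma by default. 2-D inputs pass through."""
    image = _check_image(image)
    if image.ndim == 2:
        return image.copy()
    w = np.asarray(weights, dtype=float)
    if w.shape != (3,):
        raise ValueError("weights must be a length-3 sequence")
    return image @ w


def median_filter(image: np.ndarray, kernel: int = 5) -> np.ndarray:
    """Median filter with a ``kernel x kernel`` window, edge replication at borders.

    The window median is an order statistic, so output values are always
    drawn from the input's value set and the [0, 1] range is preserved.
    """
    image = _check_image(image)
    if image.ndim != 2:
        raise ValueError("median_filter expects a grayscale image")
    if kernel % 2 == 0 or kernel < 3:
        raise ValueError(f"kernel size must be odd and >= 3, got {kernel}")
    if min(image.shape) < kernel:
        raise ValueError(
            f"image {image.shape} smaller than kernel {kernel}x{kernel}"
        )
    # mode="nearest" replicates the edge row/column outward.
    return ndimage.median_filter(image, size=kernel, mode="nearest")


def preprocess(
    image: np.ndarray,
    crop_spec: CropSpec | None = None,
    kernel: int = 5,
    weights: tuple[float, float, float] = BT601_WEIGHTS,
) -> np.ndarray:
    """Full chain: crop -> lower half -> grayscale -> median filter."""
    image = _check_image(image)
    if crop_spec is not None:
        image = crop(image, crop_spec)
    image = lower_half(image)
    image = to_grayscale(image, weights=weights)
    return median_filter(image, kernel=kernel)
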