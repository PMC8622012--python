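"""Image features for the neck-appearance screening test.

Three per-image features summarise the preprocessed (grayscale, median
filtered) lower-neck patch:

* ``median_pixel`` — median brightness over all pixels (1 = white, 0 = black);
* ``iqr_pixel`` — interquartile range of pixel brightness, a contrast measure;
* ``fast_density`` — FAST corner detections per pixel.  Recessed areas around
  a protruding clavicle and wrinkles from muscle loss create local intensity
  corners, so a higher density indicates more visible texture.

The FAST (Features from Accelerated Segment Test) detector declares a pixel
a corner when a contiguous arc of pixels on the 16-pixel Bresenham circle of
radius 3 around it is uniformly brighter, or uniformly darker, than the
centre by more than a threshold.  The threshold is expressed on the 0-255
intensity scale (the convention of the classical implementations) while
pixel statistics use the [0, 1] scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "FAST_CIRCLE_OFFSETS",
    "FASTConfig",
    "FeatureVector",
    "KDECurve",
    "pixel_median_iqr",
    "fast_corners",
    "fast_density",
    "kde_curve",
    "extract_features",
]

#: The 16 (row, col) offsets of the radius-3 Bresenham circle, clockwise
#: from the pixel directly above the centre.
FAST_CIRCLE_OFFSETS: tuple[tuple[int, int], ...] = (
    (-3, 0), (-3, 1), (-2, 2), (-1, 3),
    (0, 3), (1, 3), (2, 2), (3, 1),
    (3, 0), (3, -1), (2, -2), (1, -3),
    (0, -3), (-1, -3), (-2, -2), (-3, -1),
)


@dataclass(frozen=True)
class FASTConfig:
    """Segment-test parameters.

    radius
        Circle radius in pixels; only the classical radius-3 / 16-pixel
        circle is supported.
    threshold
        Brightness threshold on the 0-255 intensity scale.
    arc_length
        Number of contiguous circle pixels that must all exceed the centre
        (FAST-9 by default).
    nms
        Apply non-maximum suppression over 8-neighbourhoods of candidates.
    """

    radius: int = 3
    threshold: float = 2.5
    arc_length: int = 9
    nms: bool = True

    def __post_init__(self) -> None:
        if self.radius != 3:
            raise ValueError("only radius=3 (16-pixel circle) is supported")
        if not self.threshold > 0:
            raise ValueError(f"threshold must be positive, got {self.threshold}")
        if not 1 <= self.arc_length <= 16:
            raise ValueError(f"arc_length must be in [1, 16], got {self.arc_length}")


@dataclass(frozen=True)
class FeatureVector:
    """The three image features of one subject."""

    median_pixel: float
    iqr_pixel: float
    fast_density: float

    def as_dict(self) -> dict[str, float]:
        return {
            "median_pixel": self.median_pixel,
            "iqr_pixel": self.iqr_pixel,
            "fast_density": self.fast_density,
        }


@dataclass(frozen=True)
class KDECurve:
    """Gaussian-kernel density estimate evaluated on an even grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float


def pixel_median_iqr(image: np.ndarray) -> tuple[float, float]:
    """Median and Q3 - Q1 of all pixel values (type-7 linear-interpolation quantiles)."""
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("cannot compute pixel statistics of an empty image")
    q1, med, q3 = np.percentile(image, [25.0, 50.0, 75.0])
    return float(med), float(q3 - q1)


def _segment_test(
    image255: np.ndarray, cfg: FASTConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised segment test on the full image.

    Returns ``(candidate, score)`` arrays of the image's shape; border pixels
    (within ``radius`` of any edge) are never candidates.  The corner score
    is the maximum, over qualifying arcs, of the arc sum of
    ``|I_circle - I_p| - threshold``; non-candidates score ``-inf``.
    """
    h, w = image255.shape
    r = cfg.radius
    center = image255[r : h - r, r : w - r]
    circle = np.stack(
        [image255[r + dr : h - r + dr, r + dc : w - r + dc] for dr, dc in FAST_CIRCLE_OFFSETS]
    )  # (16, h-2r, w-2r)
    brighter = circle > center + cfg.threshold
    darker = circle < center - cfg.threshold
    excess = np.abs(circle - center) - cfg.threshold

    cand_in = np.zeros(center.shape, dtype=bool)
    score_in = np.full(center.shape, -np.inf)
    idx = np.arange(16)
    for start in range(16):
        arc = (idx + start) % 16
        arc = arc[: cfg.arc_length]
        ok = brighter[arc].all(axis=0) | darker[arc].all(axis=0)
        if not ok.any():
            continue
        arc_sum = excess[arc].sum(axis=0)
        cand_in |= ok
        score_in = np.where(ok, np.maximum(score_in, arc_sum), score_in)

    candidate = np.zeros((h, w), dtype=bool)
    score = np.full((h, w), -np.inf)
    candidate[r : h - r, r : w - r] = cand_in
    score[r : h - r, r : w - r] = score_in
    return candidate, score


def _nms(candidate: np.ndarray, score: np.ndarray) -> np.ndarray:
    """Suppress candidates not strictly maximal among candidate 8-neighbours.

    A score tie keeps only the lexicographically smallest (row, col) of the
    tied pair.
    """
    h, w = candidate.shape
    keep = candidate.copy()
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            n_cand = np.zeros_like(candidate)
            n_score = np.full_like(score, -np.inf)
            src_r = slice(max(dr, 0), h + min(dr, 0))
            dst_r = slice(max(-dr, 0), h + min(-dr, 0))
            src_c = slice(max(dc, 0), w + min(dc, 0))
            dst_c = slice(max(-dc, 0), w + min(-dc, 0))
            n_cand[dst_r, dst_c] = candidate[src_r, src_c]
            n_score[dst_r, dst_c] = score[src_r, src_c]
            # the neighbour at (r+dr, c+dc) is lexicographically larger than
            # (r, c) iff dr > 0 or (dr == 0 and dc > 0); ties survive then.
            tie_ok = dr > 0 or (dr == 0 and dc > 0)
            beats = score > n_score
            if tie_ok:
                beats |= score == n_score
            keep &= ~n_cand | beats
    return keep


def fast_corners(image: np.ndarray, cfg: FASTConfig = FASTConfig()) -> np.ndarray:
    """Detect FAST corners; returns an ``(k, 2)`` array of (row, col), sorted.

    Intensities are scaled by 255 before thresholding, so ``cfg.threshold``
    is on the classical 0-255 scale.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("fast_corners expects a grayscale image")
    need = 2 * cfg.radius + 1
    if image.shape[0] < need or image.shape[1] < need:
        raise ValueError(
            f"image {image.shape} smaller than the {need}x{need} minimum for radius {cfg.radius}"
        )
    candidate, score = _segment_test(image * 255.0, cfg)
    if cfg.nms:
        candidate = _nms(candidate, score)
    rows, cols = np.nonzero(candidate)
    return np.column_stack([rows, cols])


def fast_density(
    image: np.ndarray, cfg: FASTConfig = FASTConfig(), scale: float = 1.0
) -> float:
    """FAST corners per pixel: ``count / (H * W) * scale``.

    The raw per-pixel density is bounded by 1; the scale constant lets a
    calibration express densities in other units.
    """
    if not scale > 0:
        raise ValueError(f"scale must be positive, got {scale}")
    image = np.asarray(image, dtype=float)
    corners = fast_corners(image, cfg)
    return len(corners) / image.size * scale


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule of thumb: ``0.9 * min(sd, IQR/1.349) * n**(-1/5)``."""
    values = np.asarray(values, dtype=float)
    n = values.size
    sd = values.std(ddof=1)
    iqr = np.subtract(*np.percentile(values, [75.0, 25.0]))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    return 0.9 * spread * n ** (-0.2)


def kde_curve(
    values,
    bandwidth: float | str = "auto",
    grid_size: int = 512,
) -> KDECurve:
    """Gaussian-kernel density on an even grid spanning [min - 3 bw, max + 3 bw]."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2:
        raise ValueError("kde_curve needs at least 2 values")
    if bandwidth == "auto":
        bandwidth = silverman_bandwidth(values)
        if not bandwidth > 0:
            raise ValueError("auto bandwidth failed: values have zero spread")
    bandwidth = float(bandwidth)
    if not bandwidth > 0:
        raise ValueError(f"bandwidth must be positive, got {bandwidth}")
    grid = np.linspace(values.min() - 3 * bandwidth, values.max() + 3 * bandwidth, grid_size)
    density = stats.norm.pdf(grid[:, None], loc=values[None, :], scale=bandwidth).mean(axis=1)
    return KDECurve(grid=grid, density=density, bandwidth=bandwidth)


def extract_features(
    image: np.ndarray, cfg: FASTConfig = FASTConfig(), scale: float = 1.0
) -> FeatureVector:
    """Bundle the three image features of a preprocessed image."""
    med, iqr = pixel_median_iqr(image)
    dens = fast_density(image, cfg, scale=scale)
    return FeatureVector(median_pixel=med, iqr_pixel=iqr, fast_density=dens)
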