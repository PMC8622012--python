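"""Shared independent oracles for the test suite.

These deliberately use the slowest, most literal formulation of each
operation (per-pixel loops, exhaustive scans, pair counting) so they stay
independent of the vectorised implementations they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from neckscreen.features import FAST_CIRCLE_OFFSETS


def brute_force_fast(image: np.ndarray, cfg) -> set[tuple[int, int]]:
    """Exhaustive segment test: every interior pixel, all 16 arc starts."""
    intensity = image * 255.0
    h, w = intensity.shape
    r = cfg.radius
    detections = set()
    for row in range(r, h - r):
        for col in range(r, w - r):
            center = intensity[row, col]
            circle = [intensity[row + dr, col + dc] for dr, dc in FAST_CIRCLE_OFFSETS]
            for start in range(16):
                arc = [circle[(start + k) % 16] for k in range(cfg.arc_length)]
                if all(v > center + cfg.threshold for v in arc) or all(
                    v < center - cfg.threshold for v in arc
                ):
                    detections.add((row, col))
                    break
    return detections


def naive_median_filter(image: np.ndarray, kernel: int) -> np.ndarray:
    """Per-pixel sorted-window median with edge replication."""
    h, w = image.shape
    half = kernel // 2
    padded = np.pad(image, half, mode="edge")
    out = np.empty_like(image)
    for i in range(h):
        for j in range(w):
            window = sorted(padded[i : i + kernel, j : j + kernel].ravel())
            out[i, j] = window[len(window) // 2]
    return out


def pair_counting_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney statistic: fraction of positive-negative pairs correctly
    ordered, ties counted one half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def exhaustive_youden(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Best J and the lowest threshold attaining it, by scanning every
    midpoint candidate (plus +/- inf) directly."""
    distinct = np.unique(scores)
    candidates = [-np.inf, *((distinct[:-1] + distinct[1:]) / 2.0), np.inf]
    n_pos = (labels == 1).sum()
    n_neg = (labels == 0).sum()
    best_j, best_thr = -np.inf, None
    for thr in candidates:
        pred = scores >= thr
        se = (pred & (labels == 1)).sum() / n_pos
        sp = (~pred & (labels == 0)).sum() / n_neg
        j = se + sp - 1.0
        if j > best_j:
            best_j, best_thr = j, thr
    return best_j, best_thr


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
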