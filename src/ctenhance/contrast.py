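"""Global histogram equalization over 256 gray levels.

The classic chain: histogram h(r_k) = n_k, probability P(r_k) = n_k / N,
cumulative distribution s_k = sum_{j<=k} P(r_j), and the lookup table
lut[k] = round(s_k * (L - 1)) with L = 256.  The cumulative sum is taken
over integer counts and divided by N once, so s_255 is exactly 1 and the
highest occupied level always maps to 255.  Rounding is the shared
half-up rule.

Equalization is defined on 8-bit images; the enhancement pipeline min-max
normalizes the diffused HU slice first.  All pixels participate in the
histogram — the global path is deliberately global, with no air exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ctenhance._rounding import to_byte
from ctenhance.errors import ValidationError

__all__ = [
    "GrayHistogram",
    "EqualizationMap",
    "gray_histogram",
    "cumulative_distribution",
    "equalization_map",
    "equalize",
]

_LEVELS = 256


@dataclass(frozen=True)
class GrayHistogram:
    """Per-level pixel counts (length 256) and the total pixel count."""

    counts: np.ndarray
    total: int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (_LEVELS,) or c.min() < 0 or int(c.sum()) != self.total:
            raise ValidationError("histogram counts must be 256 non-negative ints summing to total")


@dataclass(frozen=True)
class EqualizationMap:
    """Monotone 256-entry lookup table into [0, 255]."""

    lut: np.ndarray

    def __post_init__(self) -> None:
        lut = np.asarray(self.lut)
        if lut.shape != (_LEVELS,) or lut.min() < 0 or lut.max() > 255:
            raise ValidationError("lut must be 256 values in [0, 255]")
        if np.any(np.diff(lut) < 0):
            raise ValidationError("lut must be monotone non-decreasing")


def gray_histogram(img: np.ndarray) -> GrayHistogram:
    arr = np.asarray(img)
    if arr.size == 0:
        raise ValidationError("cannot histogram an empty image")
    counts = np.bincount(arr.ravel().astype(np.int64), minlength=_LEVELS)
    return GrayHistogram(counts=counts, total=int(arr.size))


def cumulative_distribution(hist: GrayHistogram) -> np.ndarray:
    """s_k = cumulative counts / total; s_255 == 1.0 exactly."""
    if hist.total == 0:
        raise ValidationError("empty image: histogram total is 0")
    return np.cumsum(np.asarray(hist.counts, dtype=np.int64)) / float(hist.total)


def equalization_map(s: np.ndarray) -> EqualizationMap:
    """lut[k] = round-half-up(s_k * 255)."""
    s = np.asarray(s, dtype=np.float64)
    if s.shape != (_LEVELS,):
        raise ValidationError(f"expected a length-{_LEVELS} cumulative vector, got {s.shape}")
    return EqualizationMap(lut=to_byte(s * 255.0))


def equalize(img: np.ndarray) -> np.ndarray:
    """Histogram-equalize an 8-bit image through its cumulative distribution."""
    arr = np.asarray(img)
    emap = equalization_map(cumulative_distribution(gray_histogram(arr)))
    return emap.lut[arr.astype(np.int64)].astype(np.uint8)
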