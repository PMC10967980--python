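"""HU window level/width mapping to 8-bit — the local enhancement path.

A window is the HU interval [c - w/2, c + w/2] (c = level/center, w =
width) mapped linearly onto the 8-bit display range; HU below the window
saturate to 0, above to 255.  Inside the window the map is

    y = (g / w) * x + (w/2 - c) * (g / w),        g = 255,

so x = c - w/2 gives exactly 0, x = c gives g/2, and x = c + w/2 gives
exactly g.  Both window boundaries belong to the linear branch.  The
default window (center 60 HU, width 200 HU) is a conventional liver
window; narrower windows spend the gray range on a smaller HU interval and
therefore amplify contrast inside it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ctenhance._rounding import to_byte
from ctenhance.errors import ValidationError

__all__ = ["WindowSpec", "display_affine", "window_level"]


@dataclass(frozen=True)
class WindowSpec:
    """Window center and width in HU; ``out_max`` is the 8-bit display span."""

    center: float = 60.0
    width: float = 200.0
    out_max: int = 255

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValidationError(f"window width must be > 0, got {self.width}")
        if self.out_max != 255:
            raise ValidationError("out_max is fixed at 255 (8-bit display)")

    @property
    def low(self) -> float:
        return self.center - self.width / 2.0

    @property
    def high(self) -> float:
        return self.center + self.width / 2.0


def display_affine(spec: WindowSpec) -> tuple[float, float]:
    """Slope and intercept of the in-window linear map:
    slope = g/w, intercept = (w/2 - c) * g/w."""
    slope = spec.out_max / spec.width
    intercept = (spec.width / 2.0 - spec.center) * slope
    return slope, intercept


def window_level(img: np.ndarray, spec: WindowSpec) -> np.ndarray:
    """Apply the window map element-wise and quantize to uint8."""
    x = np.asarray(img, dtype=np.float64)
    slope, intercept = display_affine(spec)
    out = to_byte(slope * x + intercept)
    out[x < spec.low] = 0
    out[x > spec.high] = spec.out_max
    return out
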