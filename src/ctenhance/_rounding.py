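"""The single quantization rule used everywhere a real value becomes 8-bit.

Round half-up, then clamp to [0, 255].  numpy's ``round`` rounds half to
even, which would make 127.5 -> 128 in one module and 126.5 -> 126 in
another depending on parity; one explicit rule keeps every stage consistent.
"""

from __future__ import annotations

import numpy as np


def round_half_up(x: np.ndarray | float) -> np.ndarray:
    """Round to the nearest integer, ties away from minus infinity."""
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5)


def to_byte(x: np.ndarray | float) -> np.ndarray:
    """Quantize real values to uint8: round half-up then clamp to [0, 255]."""
    return np.clip(round_half_up(x), 0, 255).astype(np.uint8)
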