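"""Perona-Malik anisotropic diffusion for edge-preserving CT denoising.

One explicit (Jacobi) update reads

    I_{t+1} = I_t + lam * (cN*gN + cS*gS + cE*gE + cW*gW)

where gDir is the forward difference to the 4-neighbor in that direction and
cDir = exp(-(gDir/kappa)^2) is the conduction coefficient that shuts
diffusion down across strong gradients (edges).  Diffusion runs on the HU
slice before any 8-bit conversion, so ``kappa`` is in HU: gradients well
below kappa are treated as noise and smoothed, gradients well above kappa
as anatomy and preserved.

Borders are replicated (Neumann), so border-facing gradients are exactly
zero and total intensity is conserved: every interior flux appears twice
with opposite signs and identical conduction weights.  With ``lam <= 0.25``
and ``c <= 1`` each update is a convex combination of a pixel and its
neighbors, which gives the extremum principle (no new minima or maxima).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ctenhance.errors import ValidationError

__all__ = ["DiffusionParams", "directional_gradients", "conduction", "diffuse_step", "diffuse"]


@dataclass(frozen=True)
class DiffusionParams:
    """Perona-Malik settings: edge scale ``kappa`` (HU), step weight ``lam``,
    iteration count.  Defaults are conventional settings at CT scale."""

    kappa: float = 30.0
    lam: float = 0.25
    iterations: int = 15

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValidationError(f"kappa must be > 0, got {self.kappa}")
        if not 0 < self.lam <= 0.25:
            raise ValidationError(f"lam must be in (0, 0.25] for stability, got {self.lam}")
        if self.iterations < 1:
            raise ValidationError(f"iterations must be >= 1, got {self.iterations}")


def directional_gradients(img: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Four neighbor differences (north, south, east, west) at every pixel.

    gDir(p) = I(neighbor in Dir) - I(p); with replicate borders the
    difference facing outward at a border pixel is exactly 0.  North is
    row-1, south row+1, east col+1, west col-1.
    """
    img = np.asarray(img, dtype=np.float64)
    north = np.zeros_like(img)
    south = np.zeros_like(img)
    east = np.zeros_like(img)
    west = np.zeros_like(img)
    north[1:, :] = img[:-1, :] - img[1:, :]
    south[:-1, :] = img[1:, :] - img[:-1, :]
    east[:, :-1] = img[:, 1:] - img[:, :-1]
    west[:, 1:] = img[:, :-1] - img[:, 1:]
    return north, south, east, west


def conduction(grad: np.ndarray, kappa: float) -> np.ndarray:
    """Edge-stopping weight exp(-(g/kappa)^2), in (0, 1]."""
    if kappa <= 0:
        raise ValidationError(f"kappa must be > 0, got {kappa}")
    g = np.asarray(grad, dtype=np.float64)
    return np.exp(-np.square(g / kappa))


def diffuse_step(img: np.ndarray, params: DiffusionParams) -> np.ndarray:
    """One simultaneous (Jacobi) diffusion update of every pixel."""
    img = np.asarray(img, dtype=np.float64)
    north, south, east, west = directional_gradients(img)
    flux = (
        conduction(north, params.kappa) * north
        + conduction(south, params.kappa) * south
        + conduction(east, params.kappa) * east
        + conduction(west, params.kappa) * west
    )
    return img + params.lam * flux


def diffuse(img: np.ndarray, params: DiffusionParams) -> np.ndarray:
    """Apply ``params.iterations`` diffusion steps."""
    out = np.asarray(img, dtype=np.float64)
    for _ in range(params.iterations):
        out = diffuse_step(out, params)
    return out
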