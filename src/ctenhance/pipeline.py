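"""The dual-path enhancement scheme, composed end to end.

An HU slice is first denoised once by anisotropic diffusion, then split:

* global path: min-max normalize to 8-bit, histogram-equalize — reveals
  dark detail everywhere at the cost of tissue-specific contrast;
* local path: window level/width mapping — high contrast inside the target
  tissue window, everything else saturated.

The two 8-bit results are blended pixel-wise,
``alpha * local + (1 - alpha) * global``, rounded half-up.  ``alpha`` is
the weight on the local (window) path; 0.5 is the symmetric default and the
weight is a first-class knob since different downstream tasks want
different amounts of background detail.

Four variants are exposed so the scheme can be compared against its own
ablations: ``normalization`` (plain min-max, no diffusion — the baseline
conversion), ``histeq`` (global path only), ``window`` (local path only)
and ``proposed`` (the blend).  Nothing in the pipeline consumes
randomness, so every variant is bit-deterministic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ctenhance import image_io
from ctenhance._rounding import to_byte
from ctenhance.contrast import equalize
from ctenhance.diffusion import DiffusionParams, diffuse
from ctenhance.errors import ValidationError
from ctenhance.windowing import WindowSpec, window_level

__all__ = ["VARIANTS", "PipelineConfig", "blend", "enhance", "enhance_volume"]

logger = logging.getLogger(__name__)

VARIANTS = ("normalization", "histeq", "window", "proposed")


@dataclass(frozen=True)
class PipelineConfig:
    diffusion: DiffusionParams = field(default_factory=DiffusionParams)
    window: WindowSpec = field(default_factory=WindowSpec)
    alpha: float = 0.5
    variant: str = "proposed"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.variant not in VARIANTS:
            raise ValidationError(f"variant must be one of {VARIANTS}, got {self.variant!r}")


def blend(local: np.ndarray, global_img: np.ndarray, alpha: float) -> np.ndarray:
    """Weighted 8-bit blend: round-half-up(alpha*local + (1-alpha)*global)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError(f"alpha must be in [0, 1], got {alpha}")
    a = np.asarray(local)
    b = np.asarray(global_img)
    if a.shape != b.shape:
        raise ValidationError(f"shape mismatch: local {a.shape} vs global {b.shape}")
    if alpha == 1.0:  # keep the endpoint equivalences bit-exact
        return a.astype(np.uint8).copy()
    if alpha == 0.0:
        return b.astype(np.uint8).copy()
    return to_byte(alpha * a.astype(np.float64) + (1.0 - alpha) * b.astype(np.float64))


def enhance(img: np.ndarray, cfg: PipelineConfig) -> np.ndarray:
    """Enhance one HU slice into an 8-bit image per the configured variant."""
    if cfg.variant == "normalization":
        # baseline: the plain standardized conversion, no denoising
        return image_io.normalize_minmax(img)
    smoothed = diffuse(img, cfg.diffusion)
    if cfg.variant == "histeq":
        return equalize(image_io.normalize_minmax(smoothed))
    if cfg.variant == "window":
        return window_level(smoothed, cfg.window)
    local = window_level(smoothed, cfg.window)
    global_img = equalize(image_io.normalize_minmax(smoothed))
    return blend(local, global_img, cfg.alpha)


def enhance_volume(
    path_in: str | Path,
    path_out: str | Path,
    cfg: PipelineConfig,
    slice_index: int | None = None,
) -> dict:
    """Enhance a volume slice-by-slice to PNGs plus a JSON run manifest.

    Returns the manifest (also written to ``manifest.json``): config echo,
    per-slice output min/max, package version.
    """
    from ctenhance import __version__

    out_dir = Path(path_out)
    out_dir.mkdir(parents=True, exist_ok=True)
    probe = out_dir / ".write_probe"
    try:
        probe.write_bytes(b"")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc

    volume = image_io.read_volume(path_in)
    indices = range(volume.n_slices) if slice_index is None else [slice_index]
    width = max(3, len(str(volume.n_slices - 1)))
    entries = []
    for i in indices:
        out = enhance(image_io.to_hu(volume, i), cfg)
        name = f"slice_{i:0{width}d}.png"
        image_io.write_png(out, out_dir / name)
        entries.append({"index": i, "file": name, "min": int(out.min()), "max": int(out.max())})
        logger.info("slice %d/%d -> %s", i + 1, volume.n_slices, name)
    manifest = {
        "version": __version__,
        "input": str(path_in),
        "config": asdict(cfg),
        "slices": entries,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
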