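"""Seeded rotational and translational patch augmentation."""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

from ..preproc import Patch

MODES = ("both", "rotation_only", "translation_only", "none")


@dataclass(frozen=True)
class AugmentConfig:
    """Augmentation arms.

    ``rotations`` are base angles (degrees); each rotated copy adds a
    uniform jitter in [-jitter, +jitter] degrees.  Translations are
    uniform integer shifts up to ``max_translation`` of the patch side
    per axis, ``n_translations`` copies per patch.  Out-of-frame pixels
    are filled by edge replication.
    """

    rotations: tuple[float, ...] = (90.0, 180.0, 270.0)
    jitter: float = 15.0
    max_translation: float = 0.1
    n_translations: int = 3
    fill: str = "edge"
    seed: int = 0
    mode: str = "both"

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_translation <= 0.5:
            raise ValueError("max_translation must lie in [0, 0.5]")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


def rotate_patch(pixels: np.ndarray, angle: float) -> np.ndarray:
    """Rotate patch pixels; exact (bit-preserving) for multiples of 90."""
    if angle % 90.0 == 0.0:
        return np.rot90(pixels, k=int(angle // 90) % 4, axes=(0, 1)).copy()
    return ndi.rotate(
        pixels, angle, axes=(1, 0), reshape=False, order=1, mode="nearest"
    ).astype(pixels.dtype)


def translate_patch(pixels: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Integer shift with edge-replicated fill."""
    side = pixels.shape[0]
    dr = int(np.clip(dr, -side + 1, side - 1))
    dc = int(np.clip(dc, -side + 1, side - 1))
    pads = [(max(dr, 0), max(-dr, 0)), (max(dc, 0), max(-dc, 0))]
    if pixels.ndim == 3:
        pads.append((0, 0))
    padded = np.pad(pixels, pads, mode="edge")
    r0 = max(-dr, 0)
    c0 = max(-dc, 0)
    return padded[r0 : r0 + side, c0 : c0 + side].copy()


def _copy_with(patch: Patch, pixels: np.ndarray) -> Patch:
    return Patch(pixels=pixels, label=patch.label, source=patch.source, padded=patch.padded)


def augment(patches: Sequence[Patch], cfg: AugmentConfig) -> list[Patch]:
    """Emit each patch plus its augmented copies, per the configured mode.

    Deterministic for a fixed (patches, config): a fresh generator is
    seeded from ``cfg.seed``.  Labels are preserved.
    """
    if cfg.mode == "none":
        return list(patches)
    rng = np.random.default_rng(cfg.seed)
    out: list[Patch] = []
    for patch in patches:
        out.append(patch)
        side = patch.pixels.shape[0]
        if cfg.mode in ("both", "rotation_only"):
            for base in cfg.rotations:
                angle = base + (rng.uniform(-cfg.jitter, cfg.jitter) if cfg.jitter else 0.0)
                out.append(_copy_with(patch, rotate_patch(patch.pixels, angle)))
        if cfg.mode in ("both", "translation_only"):
            limit = cfg.max_translation * side
            for _ in range(cfg.n_translations):
                dr = int(round(rng.uniform(-limit, limit)))
                dc = int(round(rng.uniform(-limit, limit)))
                out.append(_copy_with(patch, translate_patch(patch.pixels, dr, dc)))
    return out
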