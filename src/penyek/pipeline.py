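"""Glue between the front end and the classifier: turn a raw patch into
the input image demanded by an image model (A-G)."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from . import bintrans, preproc
from .preproc import Patch


def transform_patch(
    patch: Patch,
    model: str,
    median_window: int = 3,
    morph_radius: int = 1,
    min_area: int = 9,
) -> Patch:
    """Apply the binarization chain and one image model to a patch.

    Models A-F run on the binary mask from the per-patch binarization
    chain (min_area defaults lower than the whole-scene default because
    patches are small); model G passes the RGB pixels through untouched.
    """
    if model == "G":
        if not patch.is_rgb:
            raise ValueError("image model G requires RGB patches")
        return patch
    gray = preproc.rgb_to_gray(patch.pixels) if patch.is_rgb else patch.pixels
    mask = preproc.segment_insects(
        gray,
        median_window=median_window,
        morph_radius=morph_radius,
        min_area=min_area,
    )
    if mask.all():  # EDM needs background; treat as no detection
        mask = np.zeros_like(mask)
    pixels = bintrans.apply_image_model(mask, None, model)
    return Patch(pixels=pixels, label=patch.label, source=patch.source, padded=patch.padded)


def transform_patches(patches: Sequence[Patch], model: str, **kwargs) -> list[Patch]:
    return [transform_patch(p, model, **kwargs) for p in patches]
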