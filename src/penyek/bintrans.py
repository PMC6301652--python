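"""Binary image models: outline, fill holes, skeletonize, watershed,
Voronoi and the Euclidean Distance Map, plus the raw-RGB passthrough.

Model ids follow a fixed A-G mapping (see ``IMAGE_MODELS``).  Every
transform here is deterministic; no RNG is used anywhere in the module.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage import measure as skmeasure
from skimage import morphology as skmorph
from skimage.segmentation import watershed as sk_watershed

#: model id -> human-readable filter name
IMAGE_MODELS = {
    "A": "outline",
    "B": "fill_holes",
    "C": "skeletonize",
    "D": "watershed",
    "E": "voronoi",
    "F": "edm",
    "G": "rgb",
}

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def outline(mask: np.ndarray) -> np.ndarray:
    """1-pixel-wide inner boundary: mask AND NOT erode(mask, 3x3 cross)."""
    mask = np.asarray(mask, dtype=bool)
    eroded = ndi.binary_erosion(mask, structure=_CROSS, border_value=0)
    return mask & ~eroded


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Turn background components not 4-connected to the border into foreground."""
    mask = np.asarray(mask, dtype=bool)
    return ndi.binary_fill_holes(mask, structure=_CROSS)


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Connectivity-preserving thinning to a maximally thin skeleton."""
    mask = np.asarray(mask, dtype=bool)
    return skmorph.skeletonize(mask)


def euclidean_distance_map(mask: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance of each foreground pixel to the nearest
    background pixel; background pixels carry 0.

    Raises
    ------
    ValueError
        On an all-foreground mask: there is no background pixel to
        measure against, and callers are expected to guarantee that
        background exists after binarization.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.all():
        raise ValueError("euclidean_distance_map: mask has no background pixel")
    return ndi.distance_transform_edt(mask)


def edm_to_gray(edm: np.ndarray) -> np.ndarray:
    """Linearly rescale a distance map to 8-bit: 0 -> 0, max -> 255.

    Rounding is half-up; an all-zero map stays all-zero.
    """
    edm = np.asarray(edm, dtype=np.float64)
    if np.any(edm < 0):
        raise ValueError("distance map must be non-negative")
    peak = edm.max()
    if peak == 0:
        return np.zeros(edm.shape, dtype=np.uint8)
    return np.floor(edm / peak * 255.0 + 0.5).clip(0, 255).astype(np.uint8)


def watershed_binary(mask: np.ndarray, merge_tolerance: float = 0.5) -> np.ndarray:
    """Split touching blobs by flooding the inverted EDM from its maxima.

    Local maxima of the foreground distance map are used as seeds, with
    maxima whose prominence is below ``merge_tolerance`` merged to avoid
    over-segmentation from plateau noise; ridge pixels between basins
    are set to background, so the output foreground is a subset of the
    input.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    edt = ndi.distance_transform_edt(mask)
    seeds_mask = skmorph.h_maxima(edt, merge_tolerance) & mask
    seeds, n_seeds = ndi.label(seeds_mask, structure=np.ones((3, 3), dtype=bool))
    if n_seeds == 0:
        return mask.copy()
    labels = sk_watershed(-edt, markers=seeds, mask=mask, watershed_line=True)
    return mask & (labels > 0)


def voronoi(mask: np.ndarray) -> np.ndarray:
    """Background ridge lines equidistant between nearest particles.

    Computes the watershed of the background's distance-from-particles
    map seeded by the particles themselves; the resulting watershed
    lines restricted to the background are the Voronoi tessellation
    boundaries of the connected components.  With fewer than two
    components the output is empty.
    """
    mask = np.asarray(mask, dtype=bool)
    lbl = skmeasure.label(mask, connectivity=2)
    if lbl.max() < 2:
        return np.zeros_like(mask)
    dist = ndi.distance_transform_edt(~mask)
    regions = sk_watershed(dist, markers=lbl, watershed_line=True)
    return (regions == 0) & ~mask


def apply_image_model(
    patch_mask: np.ndarray | None,
    patch_rgb: np.ndarray | None,
    model: str,
) -> np.ndarray:
    """Produce the classifier input for one of the models A-G.

    Binary models A-E are rendered as {0, 255} grayscale, model F as the
    8-bit rescaled distance map, model G as the untouched RGB patch.
    """
    if model not in IMAGE_MODELS:
        raise ValueError(f"unknown image model {model!r}; expected one of A..G")
    if model == "G":
        if patch_rgb is None:
            raise ValueError("model G requires an RGB patch")
        return np.asarray(patch_rgb).copy()
    if patch_mask is None:
        raise ValueError(f"model {model} requires a binary mask")
    mask = np.asarray(patch_mask, dtype=bool)
    if model == "F":
        return edm_to_gray(euclidean_distance_map(mask))
    transform = {
        "A": outline,
        "B": fill_holes,
        "C": skeletonize,
        "D": watershed_binary,
        "E": voronoi,
    }[model]
    return np.where(transform(mask), 255, 0).astype(np.uint8)
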