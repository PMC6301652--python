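"""Front-end image processing: grayscale conversion, median filtering,
iterative two-threshold binarization, morphological cleanup, size
filtering, patch extraction and Canny-based negative-patch mining.

All raster coordinates are 0-based, row-major, origin at the top-left
corner.  Grayscale and RGB rasters are ``uint8`` arrays in [0, 255];
binary masks are boolean arrays with ``True`` marking foreground.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from PIL import Image
from scipy import ndimage as ndi
from skimage import feature as skfeature
from skimage import measure as skmeasure

LABELS = ("BPH", "benign")

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThresholdResult:
    """Two optimal intensity thresholds splitting a histogram into 3 classes."""

    t_low: int
    t_high: int
    iterations: int
    converged: bool
    variance: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.t_low < self.t_high <= 255):
            raise ValueError(
                f"thresholds must satisfy 0 <= t_low < t_high <= 255, "
                f"got ({self.t_low}, {self.t_high})"
            )


@dataclass(frozen=True)
class PatchAnnotation:
    """A labelled bounding circle on a pad image."""

    image_id: str
    center_row: float
    center_col: float
    radius: float
    label: str

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("annotation radius must be > 0")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")


@dataclass
class Patch:
    """A square classifier-input patch cropped around an annotation."""

    pixels: np.ndarray  # S x S (gray) or S x S x 3 (RGB), uint8
    label: str
    source: tuple  # (image_id, annotation index or "mined")
    padded: bool = False

    def __post_init__(self) -> None:
        if self.pixels.ndim not in (2, 3):
            raise ValueError("patch pixels must be 2-D (gray) or 3-D (RGB)")
        if self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("patch must be square")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")

    @property
    def size(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def is_rgb(self) -> bool:
        return self.pixels.ndim == 3


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def rgb_to_gray(img: np.ndarray) -> np.ndarray:
    """Convert an RGB raster to grayscale with BT.601 luma weights.

    Per-pixel luma = 0.299 R + 0.587 G + 0.114 B, rounded half-up.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB image, got shape {img.shape}")
    luma = (
        0.299 * img[..., 0].astype(np.float64)
        + 0.587 * img[..., 1].astype(np.float64)
        + 0.114 * img[..., 2].astype(np.float64)
    )
    return np.floor(luma + 0.5).clip(0, 255).astype(np.uint8)


def median_filter(img: np.ndarray, window: int = 3) -> np.ndarray:
    """Square-window median filter with edge-replicated borders."""
    if window % 2 == 0 or window < 3:
        raise ValueError(f"median window must be odd and >= 3, got {window}")
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("median_filter expects a single-channel image")
    return ndi.median_filter(img, size=window, mode="nearest")


def _class_score(cum_w: np.ndarray, cum_s: np.ndarray, lo: int, hi: int) -> float:
    # sum_i s_i^2 / w_i term for the class of levels (lo, hi]; empty class -> 0
    w = cum_w[hi] - (cum_w[lo] if lo >= 0 else 0.0)
    if w <= 0:
        return 0.0
    s = cum_s[hi] - (cum_s[lo] if lo >= 0 else 0.0)
    return s * s / w


def three_class_variance(hist: np.ndarray, t_low: int, t_high: int) -> float:
    """Between-class variance of the 3-class split (<=t_low, (t_low,t_high], >t_high)."""
    p = hist.astype(np.float64)
    p = p / p.sum()
    levels = np.arange(p.size, dtype=np.float64)
    cum_w = np.cumsum(p)
    cum_s = np.cumsum(p * levels)
    mu = cum_s[-1]
    score = (
        _class_score(cum_w, cum_s, -1, t_low)
        + _class_score(cum_w, cum_s, t_low, t_high)
        + _class_score(cum_w, cum_s, t_high, p.size - 1)
    )
    return score - mu * mu


def iterative_multithreshold(
    img: np.ndarray, tol: int = 0, max_iter: int = 100
) -> ThresholdResult:
    """Two-threshold binarization by between-class-variance maximization.

    Coordinate ascent on the 3-class Otsu objective: each threshold is
    iteratively re-placed at the position maximizing the between-class
    variance with the other threshold held fixed, starting from the
    histogram's tercile boundaries, until neither threshold moves by
    more than ``tol`` or ``max_iter`` is reached.

    Returns
    -------
    ThresholdResult
        ``t_low`` and ``t_high`` partition intensities into the classes
        g <= t_low, t_low < g <= t_high and g > t_high.

    Raises
    ------
    ValueError
        If the image has fewer than 3 distinct intensity levels; use a
        single-threshold method (e.g. plain Otsu) as a fallback.
    """
    img = np.asarray(img)
    values = np.unique(img)
    if values.size < 3:
        raise ValueError(
            f"iterative_multithreshold needs >= 3 distinct intensity levels, "
            f"got {values.size}; fall back to a single-threshold method"
        )
    hist = np.bincount(img.ravel().astype(np.int64), minlength=256).astype(np.float64)
    p = hist / hist.sum()
    levels = np.arange(256, dtype=np.float64)
    cum_w = np.cumsum(p)
    cum_s = np.cumsum(p * levels)

    def seg(lo: np.ndarray | int, hi: np.ndarray | int) -> np.ndarray:
        # vectorized s^2/w for classes (lo, hi]; lo == -1 means from level 0
        w_lo = np.where(np.asarray(lo) >= 0, cum_w[np.maximum(lo, 0)], 0.0)
        s_lo = np.where(np.asarray(lo) >= 0, cum_s[np.maximum(lo, 0)], 0.0)
        w = cum_w[hi] - w_lo
        s = cum_s[hi] - s_lo
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(w > 0, s * s / np.where(w > 0, w, 1.0), 0.0)
        return out

    def objective(t1: int, t2: int) -> float:
        return float(seg(np.array([-1]), np.array([t1]))[0]
                     + seg(np.array([t1]), np.array([t2]))[0]
                     + seg(np.array([t2]), np.array([255]))[0])

    def ascend(t_low: int, t_high: int) -> tuple[int, int, int, bool]:
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            # optimal t_low given t_high
            cand = np.arange(0, t_high)
            obj = seg(np.full(cand.size, -1), cand) + seg(cand, t_high)
            new_low = int(cand[np.argmax(obj)])
            # optimal t_high given new t_low
            cand = np.arange(new_low + 1, 255)
            obj = seg(np.full(cand.size, new_low), cand) + seg(cand, 255)
            new_high = int(cand[np.argmax(obj)])
            moved = max(abs(new_low - t_low), abs(new_high - t_high))
            t_low, t_high = new_low, new_high
            if moved <= tol:
                converged = True
                break
        return t_low, t_high, it, converged

    # deterministic multi-start: the tercile boundaries plus the best cells
    # of a coarse strided scan of the objective; coordinate ascent alone
    # stalls in local optima on noisy histograms, and the best-of-starts
    # result is kept
    starts = [(int(np.searchsorted(cum_w, 1 / 3)),
               int(np.searchsorted(cum_w, 2 / 3)))]  # terciles first
    grid = np.arange(0, 255, 2)
    g1 = grid[:, None]
    g2 = grid[None, :]
    coarse = (seg(np.full_like(g1, -1), g1)
              + seg(np.broadcast_to(g1, (grid.size, grid.size)), g2)
              + seg(g2, np.full_like(g2, 255)))
    coarse = np.where(g1 < g2, coarse, -np.inf)
    top = np.argsort(coarse.ravel())[::-1][:5]
    for flat in top:
        i, j = np.unravel_index(flat, coarse.shape)
        starts.append((int(grid[i]), int(grid[j])))
    best: tuple[float, tuple[int, int, int, bool]] | None = None
    for s_low, s_high in starts:
        s_low = min(max(s_low, 0), 253)
        s_high = min(max(s_high, s_low + 1), 254)
        t_low, t_high, it, converged = ascend(s_low, s_high)
        value = objective(t_low, t_high)
        if best is None or value > best[0] + 1e-15:
            best = (value, (t_low, t_high, it, converged))
    t_low, t_high, it, converged = best[1]

    return ThresholdResult(
        t_low=t_low,
        t_high=t_high,
        iterations=it,
        converged=converged,
        variance=three_class_variance(hist, t_low, t_high),
    )


def binarize(
    img: np.ndarray, thr: ThresholdResult, foreground_rule: str = "darkest"
) -> np.ndarray:
    """Select one of the three intensity classes as the foreground mask.

    Rules: ``darkest`` -> g <= t_low (insects dark on a pale pad);
    ``middle`` -> t_low < g <= t_high; ``brightest`` -> g > t_high.
    """
    img = np.asarray(img)
    if foreground_rule == "darkest":
        return img <= thr.t_low
    if foreground_rule == "middle":
        return (img > thr.t_low) & (img <= thr.t_high)
    if foreground_rule == "brightest":
        return img > thr.t_high
    raise ValueError(f"unknown foreground rule {foreground_rule!r}")


def morph_close_open(mask: np.ndarray, radius: int = 1) -> np.ndarray:
    """Morphological closing then opening with a radius-r ball element.

    The ball is taken in the Chebyshev metric (a (2r+1)-square), so
    rectangular shapes are fixed points; a Euclidean disk would clip
    their corners.
    """
    if radius < 1:
        raise ValueError("structuring-element radius must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    selem = np.ones((2 * radius + 1, 2 * radius + 1), dtype=bool)
    closed = ndi.binary_closing(mask, structure=selem)
    return ndi.binary_opening(closed, structure=selem)


def size_filter(mask: np.ndarray, min_area: int = 30, connectivity: int = 8) -> np.ndarray:
    """Drop connected components smaller than ``min_area`` pixels."""
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(mask, dtype=bool)
    if min_area == 0:
        return mask.copy()
    lbl = skmeasure.label(mask, connectivity=1 if connectivity == 4 else 2)
    counts = np.bincount(lbl.ravel())
    keep = counts >= min_area
    keep[0] = False
    return keep[lbl]


def segment_insects(
    gray: np.ndarray,
    median_window: int = 3,
    morph_radius: int = 1,
    min_area: int = 30,
    foreground_rule: str = "darkest",
) -> np.ndarray:
    """Full binarization chain: median filter, iterative two-threshold
    binarization (plain Otsu fallback on degenerate histograms),
    closing/opening, size filter."""
    smoothed = median_filter(gray, median_window)
    try:
        thr = iterative_multithreshold(smoothed)
        mask = binarize(smoothed, thr, foreground_rule)
    except ValueError:
        from skimage.filters import threshold_otsu

        t = threshold_otsu(smoothed)
        mask = smoothed <= t if foreground_rule == "darkest" else smoothed > t
    mask = morph_close_open(mask, morph_radius)
    return size_filter(mask, min_area)


def extract_patch(img: np.ndarray, ann: PatchAnnotation, out_size: int) -> Patch:
    """Crop the 2r x 2r square around an annotation and resize bilinearly.

    A circle touching the image border is clamped: the crop is padded by
    edge replication and the patch is flagged ``padded``.  When the crop
    already has side ``out_size`` no resampling happens and pixels are
    preserved exactly.
    """
    img = np.asarray(img)
    if img.ndim not in (2, 3):
        raise ValueError("image must be gray (2-D) or RGB (3-D)")
    h, w = img.shape[:2]
    r = int(round(ann.radius))
    r0 = int(round(ann.center_row)) - r
    c0 = int(round(ann.center_col)) - r
    side = 2 * r
    r1, c1 = r0 + side, c0 + side
    pad_top = max(0, -r0)
    pad_left = max(0, -c0)
    pad_bottom = max(0, r1 - h)
    pad_right = max(0, c1 - w)
    padded = bool(pad_top or pad_left or pad_bottom or pad_right)
    crop = img[max(r0, 0) : min(r1, h), max(c0, 0) : min(c1, w)]
    if padded:
        pads = [(pad_top, pad_bottom), (pad_left, pad_right)]
        if img.ndim == 3:
            pads.append((0, 0))
        crop = np.pad(crop, pads, mode="edge")
    if crop.shape[0] != out_size:
        mode = "RGB" if img.ndim == 3 else "L"
        pil = Image.fromarray(crop.astype(np.uint8), mode=mode)
        crop = np.asarray(pil.resize((out_size, out_size), Image.BILINEAR))
    else:
        crop = crop.astype(np.uint8).copy()
    return Patch(pixels=crop, label=ann.label, source=(ann.image_id, "crop"), padded=padded)


def _circle_intersects_square(
    cr: float, cc: float, radius: float, r0: int, c0: int, side: int
) -> bool:
    nearest_r = min(max(cr, r0), r0 + side - 1)
    nearest_c = min(max(cc, c0), c0 + side - 1)
    return (nearest_r - cr) ** 2 + (nearest_c - cc) ** 2 <= radius**2


def mine_negative_patches(
    img: np.ndarray,
    annotations: Sequence[PatchAnnotation],
    canny_lo: float = 50.0,
    canny_hi: float = 150.0,
    patch_size: int = 49,
    max_patches: int = 100,
    min_edge_density: float = 0.02,
    seed: int = 0,
    image_id: str = "image",
) -> list[Patch]:
    """Mine benign patches via Canny edges, avoiding BPH circles.

    Windows of ``patch_size`` are slid over the Canny edge map with
    stride ``patch_size // 2``; windows whose edge-pixel fraction is at
    least ``min_edge_density`` and whose square does not intersect any
    BPH annotation circle are candidates, of which up to ``max_patches``
    are sampled with the given seed.  All returned patches are labelled
    benign.
    """
    if not canny_lo < canny_hi:
        raise ValueError("canny_lo must be < canny_hi")
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("mine_negative_patches expects a grayscale image")
    edges = skfeature.canny(
        img.astype(np.float64) / 255.0,
        low_threshold=canny_lo / 255.0,
        high_threshold=canny_hi / 255.0,
    )
    bph = [a for a in annotations if a.label == "BPH"]
    h, w = img.shape
    stride = max(1, patch_size // 2)
    candidates: list[tuple[int, int]] = []
    for r0 in range(0, max(h - patch_size + 1, 1), stride):
        for c0 in range(0, max(w - patch_size + 1, 1), stride):
            window = edges[r0 : r0 + patch_size, c0 : c0 + patch_size]
            if window.shape != (patch_size, patch_size):
                continue
            if window.mean() < min_edge_density:
                continue
            if any(
                _circle_intersects_square(
                    a.center_row, a.center_col, a.radius, r0, c0, patch_size
                )
                for a in bph
            ):
                continue
            candidates.append((r0, c0))
    rng = np.random.default_rng(seed)
    if len(candidates) > max_patches:
        idx = rng.choice(len(candidates), size=max_patches, replace=False)
        candidates = [candidates[i] for i in sorted(idx)]
    return [
        Patch(
            pixels=img[r0 : r0 + patch_size, c0 : c0 + patch_size].copy(),
            label="benign",
            source=(image_id, "mined"),
        )
        for r0, c0 in candidates
    ]
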