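"""Hand-crafted feature extractors + random forest comparison arms.

Six feature schemes — GLCM statistics, Gabor filter-bank responses,
uniform LBP histograms and gray/HSV/RGB intensity histograms — each fed
to a seeded random forest.  Feature extraction is fully deterministic;
only the forest uses (seeded) randomness.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from skimage.color import rgb2hsv
from skimage.feature import graycomatrix, graycoprops, local_binary_pattern
from skimage.filters import gabor
from sklearn.ensemble import RandomForestClassifier

from .preproc import Patch, rgb_to_gray

SCHEMES = ("GLCM", "Gabor", "LBP", "gray_hist", "HSV_hist", "RGB_hist")

DEFAULT_GLCM_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))
DEFAULT_GABOR_FREQUENCIES = (0.1, 0.2, 0.3, 0.4)
DEFAULT_GABOR_ORIENTATIONS = tuple(np.pi * i / 6 for i in range(6))


def glcm_matrices(
    img: np.ndarray,
    levels: int = 32,
    offsets: Sequence[tuple[int, int]] = DEFAULT_GLCM_OFFSETS,
) -> list[np.ndarray]:
    """Symmetrized, sum-normalized co-occurrence matrix per offset."""
    if levels < 2:
        raise ValueError("levels must be >= 2")
    img = np.asarray(img)
    quant = (img.astype(np.int64) * levels // 256).clip(0, levels - 1).astype(np.uint8)
    out = []
    for dr, dc in offsets:
        distance = max(abs(dr), abs(dc))
        angle = float(np.arctan2(-dr, dc))  # skimage angles are CCW from +x
        out.append(
            graycomatrix(
                quant, [distance], [angle], levels=levels, symmetric=True, normed=True
            )
        )
    return out


def glcm_features(
    img: np.ndarray,
    levels: int = 32,
    offsets: Sequence[tuple[int, int]] = DEFAULT_GLCM_OFFSETS,
) -> np.ndarray:
    """Contrast, correlation, energy and homogeneity of symmetrized,
    normalized co-occurrence matrices, concatenated across offsets."""
    feats = []
    for m in glcm_matrices(img, levels, offsets):
        for prop in ("contrast", "correlation", "energy", "homogeneity"):
            feats.append(float(graycoprops(m, prop)[0, 0]))
    return np.asarray(feats)


def gabor_features(
    img: np.ndarray,
    frequencies: Sequence[float] = DEFAULT_GABOR_FREQUENCIES,
    orientations: Sequence[float] = DEFAULT_GABOR_ORIENTATIONS,
) -> np.ndarray:
    """Mean and variance of Gabor response magnitude per (freq, theta)."""
    if not frequencies or not orientations:
        raise ValueError("frequency and orientation sets must be non-empty")
    img = np.asarray(img, dtype=np.float64) / 255.0
    feats = []
    for f in frequencies:
        for theta in orientations:
            real, imag = gabor(img, frequency=f, theta=theta)
            mag = np.hypot(real, imag)
            feats.extend([float(mag.mean()), float(mag.var())])
    return np.asarray(feats)


def lbp_histogram(img: np.ndarray, radius: int = 3, n_points: int = 24) -> np.ndarray:
    """Rotation-invariant uniform LBP histogram (n_points + 2 bins, sum 1)."""
    if n_points < 4:
        raise ValueError("n_points must be >= 4")
    img = np.asarray(img)
    if min(img.shape) <= 2 * radius:
        raise ValueError("image too small for the requested LBP radius")
    codes = local_binary_pattern(img, n_points, radius, method="uniform")
    codes = codes[radius:-radius, radius:-radius]  # border codes are ill-defined
    hist = np.bincount(codes.astype(np.int64).ravel(), minlength=n_points + 2)
    return hist / hist.sum()


def intensity_histograms(
    img: np.ndarray, colorspace: str = "gray", bins: int = 32
) -> np.ndarray:
    """Per-channel normalized intensity histograms, concatenated."""
    if bins < 2:
        raise ValueError("bins must be >= 2")
    img = np.asarray(img)
    if colorspace == "gray":
        if img.ndim == 3:
            img = rgb_to_gray(img)
        hist, _ = np.histogram(img, bins=bins, range=(0, 256))
        return hist / hist.sum()
    if colorspace not in ("RGB", "HSV"):
        raise ValueError(f"unknown colorspace {colorspace!r}")
    if img.ndim != 3:
        raise ValueError(f"{colorspace} histograms require an RGB input image")
    if colorspace == "HSV":
        img = rgb2hsv(img)  # floats in [0, 1]
        ranges = (0.0, 1.0)
    else:
        ranges = (0.0, 256.0)
    feats = []
    for ch in range(3):
        hist, _ = np.histogram(img[..., ch], bins=bins, range=ranges)
        feats.append(hist / hist.sum())
    return np.concatenate(feats)


def extract_features(patch: Patch, scheme: str) -> np.ndarray:
    """Dispatch one patch through the named feature scheme."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    px = patch.pixels
    if scheme == "GLCM":
        return glcm_features(px if px.ndim == 2 else rgb_to_gray(px))
    if scheme == "Gabor":
        return gabor_features(px if px.ndim == 2 else rgb_to_gray(px))
    if scheme == "LBP":
        return lbp_histogram(px if px.ndim == 2 else rgb_to_gray(px))
    colorspace = {"gray_hist": "gray", "HSV_hist": "HSV", "RGB_hist": "RGB"}[scheme]
    return intensity_histograms(px, colorspace=colorspace)


def train_rf(
    features: np.ndarray, labels: Sequence[str], n_trees: int = 200, seed: int = 0
) -> RandomForestClassifier:
    """Seeded random-forest fit; requires both classes to be present."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("training labels must contain at least 2 classes")
    clf = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1
    )
    clf.fit(np.asarray(features), labels)
    return clf


def classify(
    clf: RandomForestClassifier, features: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels plus P(BPH) scores (normalized tree votes)."""
    probs = clf.predict_proba(np.asarray(features))
    labels = clf.classes_[probs.argmax(axis=1)]
    bph_col = int(np.where(clf.classes_ == "BPH")[0][0])
    return labels, probs[:, bph_col]
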