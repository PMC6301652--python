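"""Seeded synthetic sticky-pad scenes and labelled patch datasets.

Generates procedural insect sprites of two morphologically distinct
classes on a cluttered pad (glue specks, multiplicative illumination
ramp, sensor noise), with ground-truth bounding circles, so every
downstream stage is testable without any external data.

Insects of the positive class ("BPH") are elongated — narrow head plus
two wing lobes — while benign insects are rounder with small
appendages; a ``distortion`` fraction removes a boundary sector of the
body and applies a random shear, emulating flattened or damaged
specimens.  Classes stay separable by simple shape statistics up to
distortion ~0.7.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage as ndi

from .preproc import LABELS, Patch, PatchAnnotation, extract_patch

_SPRITE_CANVAS = 48
# sprite gray values tint to brown-ish RGB on the pad
_TINT = np.array([1.15, 0.95, 0.65])
_PAD_RGB = np.array([214.0, 205.0, 188.0])
_SPECK_GRAY = 155.0


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic sticky-pad scene."""

    height: int = 512
    width: int = 512
    n_bph: int = 5
    n_benign: int = 5
    distortion: float = 0.5
    illum_gradient: float = 0.2
    speck_density: float = 50.0  # specks per megapixel
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("scene dimensions must be positive")
        if self.n_bph < 0 or self.n_benign < 0:
            raise ValueError("insect counts must be >= 0")
        if not 0.0 <= self.distortion <= 1.0:
            raise ValueError("distortion must lie in [0, 1]")
        if not 0.0 <= self.illum_gradient <= 1.0:
            raise ValueError("illum_gradient must lie in [0, 1]")
        if self.speck_density < 0 or self.noise_sd < 0:
            raise ValueError("speck_density and noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Annotations for a generated scene, plus per-insect debug masks."""

    annotations: list[PatchAnnotation] = field(default_factory=list)
    insect_masks: list[np.ndarray] | None = None


def moments_aspect(mask: np.ndarray) -> float:
    """Major/minor axis ratio from the second central moments of a mask.

    Rotation-invariant; returns 1.0 for degenerate (sub-2-pixel) masks.
    """
    coords = np.argwhere(mask)
    if coords.shape[0] < 2:
        return 1.0
    cov = np.cov(coords.T.astype(np.float64))
    eig = np.sort(np.linalg.eigvalsh(cov))
    if eig[0] <= 1e-12:
        return float("inf")
    return float(math.sqrt(eig[1] / eig[0]))


def render_insect(
    class_label: str, distortion: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Render one insect sprite.

    Returns ``(gray, alpha)``: a canvas of body intensities (uint8) and
    the boolean alpha mask.  ``distortion`` in [0, 1] removes a random
    boundary sector of roughly ``distortion * 30%`` of the body area and
    applies a random affine shear.
    """
    if class_label not in LABELS:
        raise ValueError(f"unknown class label {class_label!r}; expected one of {LABELS}")
    if not 0.0 <= distortion <= 1.0:
        raise ValueError("distortion must lie in [0, 1]")
    n = _SPRITE_CANVAS
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    yy -= (n - 1) / 2.0
    xx -= (n - 1) / 2.0
    theta = rng.uniform(0.0, math.pi)
    u = xx * math.cos(theta) + yy * math.sin(theta)  # along the body axis
    v = -xx * math.sin(theta) + yy * math.cos(theta)

    def ellipse(cu: float, cv: float, su: float, sv: float) -> np.ndarray:
        return ((u - cu) / su) ** 2 + ((v - cv) / sv) ** 2 <= 1.0

    if class_label == "BPH":
        a = rng.uniform(16.0, 19.0)
        b = a / rng.uniform(3.2, 3.8)
        mask = ellipse(0.0, 0.0, a, b)
        mask |= ellipse(a * 0.92, 0.0, b * 0.9, b * 0.75)  # narrow head
        for sign in (-1.0, 1.0):  # two wing lobes
            mask |= ellipse(-a * 0.25, sign * b * 0.75, a * 0.45, b * 0.6)
    else:
        a = rng.uniform(10.0, 13.0)
        b = a / rng.uniform(1.05, 1.3)
        mask = ellipse(0.0, 0.0, a, b)
        for _ in range(5):  # short appendage bumps around the body
            ang = rng.uniform(0.0, 2 * math.pi)
            cu, cv = a * 0.95 * math.cos(ang), b * 0.95 * math.sin(ang)
            r = rng.uniform(1.5, 3.0)
            mask |= ellipse(cu, cv, r, r)

    if distortion > 0 and mask.any():
        coords = np.argwhere(mask)
        cr, cc = coords.mean(axis=0)
        ang = np.arctan2(yy + (n - 1) / 2.0 - cr, xx + (n - 1) / 2.0 - cc)
        phi = rng.uniform(-math.pi, math.pi)
        half_width = distortion * 0.30 * math.pi  # sector area ~ distortion * 30%
        diff = np.angle(np.exp(1j * (ang - phi)))
        mask &= ~(np.abs(diff) <= half_width)
        shear = rng.uniform(-0.35, 0.35) * distortion
        mat = np.array([[1.0, shear], [0.0, 1.0]])
        center = np.array([(n - 1) / 2.0, (n - 1) / 2.0])
        offset = center - mat @ center
        mask = ndi.affine_transform(
            mask.astype(np.uint8), mat, offset=offset, order=0, mode="constant"
        ).astype(bool)

    base = rng.uniform(45.0, 68.0)
    texture = rng.normal(0.0, 6.0, size=(n, n))
    rim = np.hypot(u, v) / max(1.0, n / 2.0)
    gray = np.clip(base + 22.0 * rim + texture, 0.0, 120.0)
    gray = np.where(mask, gray, 0.0).astype(np.uint8)
    return gray, mask


def _sprite_circle(mask: np.ndarray) -> tuple[float, float, float]:
    """Center and radius (within the sprite canvas) covering the sprite.

    The radius is a fixed, class-independent value (large enough for any
    sprite): annotators draw circles of roughly constant size, and a
    class-dependent radius would leak the label through patch scale.
    """
    coords = np.argwhere(mask)
    cr, cc = coords.mean(axis=0)
    reach = float(np.sqrt(((coords - [cr, cc]) ** 2).sum(axis=1)).max())
    radius = max(_SPRITE_CANVAS / 2.0 + 4.0, reach + 2.0)
    return float(cr), float(cc), radius


def generate_scene(
    cfg: SceneConfig, image_id: str = "scene", max_retries: int = 200
) -> tuple[np.ndarray, GroundTruth]:
    """Render a scene and its ground truth.

    The scene contains exactly ``n_bph + n_benign`` non-overlapping
    insects plus glue specks, a multiplicative illumination ramp of a
    random direction and additive Gaussian noise.  Identical config
    (including seed) yields a byte-identical image.

    Raises
    ------
    RuntimeError
        If an insect cannot be placed without overlap within
        ``max_retries`` attempts; the message names how many insects
        were requested and how many fit.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.height, cfg.width
    pad = np.ones((h, w, 3), dtype=np.float64) * _PAD_RGB
    pad += rng.normal(0.0, 2.0, size=(h, w, 1))  # pad texture

    labels = ["BPH"] * cfg.n_bph + ["benign"] * cfg.n_benign
    placed: list[tuple[float, float, float]] = []
    gt = GroundTruth(annotations=[], insect_masks=[])
    for i, lab in enumerate(labels):
        gray, alpha = render_insect(lab, cfg.distortion, rng)
        scr, scc, radius = _sprite_circle(alpha)
        if 2 * radius >= min(h, w):
            raise RuntimeError(
                f"scene {h}x{w} too small for insect of radius {radius:.0f}"
            )
        for _ in range(max_retries):
            cr = rng.uniform(radius, h - radius)
            cc = rng.uniform(radius, w - radius)
            if all(
                (cr - pr) ** 2 + (cc - pc) ** 2 >= (radius + pradius) ** 2
                for pr, pc, pradius in placed
            ):
                break
        else:
            raise RuntimeError(
                f"could not place insect {i + 1} of {len(labels)} without "
                f"overlap after {max_retries} retries"
            )
        placed.append((cr, cc, radius))
        r0 = int(round(cr - scr))
        c0 = int(round(cc - scc))
        n = alpha.shape[0]
        # the sprite canvas may overhang the scene even though the circle
        # (and thus all foreground) fits; crop the paste region
        sr0, sc0 = max(0, -r0), max(0, -c0)
        sr1, sc1 = n - max(0, r0 + n - h), n - max(0, c0 + n - w)
        rs = slice(r0 + sr0, r0 + sr1)
        cs = slice(c0 + sc0, c0 + sc1)
        alpha_c = alpha[sr0:sr1, sc0:sc1]
        gray_c = gray[sr0:sr1, sc0:sc1]
        full = np.zeros((h, w), dtype=bool)
        full[rs, cs] = alpha_c
        gt.insect_masks.append(full)
        region = pad[rs, cs]
        region[alpha_c] = gray_c[alpha_c, None] * _TINT
        gt.annotations.append(
            PatchAnnotation(
                image_id=image_id,
                center_row=float(r0 + scr),
                center_col=float(c0 + scc),
                radius=radius,
                label=lab,
            )
        )

    n_specks = rng.poisson(cfg.speck_density * h * w / 1e6)
    for _ in range(n_specks):
        sr, sc = rng.uniform(0, h), rng.uniform(0, w)
        srad = rng.uniform(1.0, 2.5)
        rr, cc_ = np.mgrid[
            max(0, int(sr - 3)) : min(h, int(sr + 4)),
            max(0, int(sc - 3)) : min(w, int(sc + 4)),
        ]
        speck = (rr - sr) ** 2 + (cc_ - sc) ** 2 <= srad**2
        block = pad[max(0, int(sr - 3)) : min(h, int(sr + 4)),
                    max(0, int(sc - 3)) : min(w, int(sc + 4))]
        block[speck] = _SPECK_GRAY * _TINT

    # multiplicative illumination ramp with a random direction
    direction = rng.uniform(0.0, 2 * math.pi)
    rr, cc_ = np.mgrid[0:h, 0:w].astype(np.float64)
    proj = rr * math.sin(direction) + cc_ * math.cos(direction)
    proj = (proj - proj.min()) / max(float(np.ptp(proj)), 1e-9)
    ramp = 1.0 - cfg.illum_gradient * proj
    scene = pad * ramp[..., None]
    if cfg.noise_sd > 0:
        scene = scene + rng.normal(0.0, cfg.noise_sd, size=scene.shape)
    return np.clip(scene, 0, 255).astype(np.uint8), gt


def split_counts(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    """Largest-remainder apportionment of ``n`` items across 3 fractions."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    raw = [n * f for f in fractions]
    floors = [int(math.floor(x)) for x in raw]
    remainder = n - sum(floors)
    order = sorted(range(3), key=lambda i: raw[i] - floors[i], reverse=True)
    for i in order[:remainder]:
        floors[i] += 1
    return tuple(floors)  # type: ignore[return-value]


DEFAULT_SPLIT = (0.7, 0.1, 0.2)


def generate_dataset(
    n_bph: int,
    n_benign: int,
    split: tuple[float, float, float] = DEFAULT_SPLIT,
    patch_size: int = 49,
    cfg: SceneConfig | None = None,
    seed: int = 0,
) -> dict[str, list[Patch]]:
    """Generate a stratified train/val/test patch dataset.

    One single-insect mini-scene is rendered per patch, so splitting by
    scene and by patch coincide and no scene leaks across splits.  Per
    class the split sizes follow largest-remainder apportionment of the
    requested fractions (defaults ~70/10/20); scenes are shuffled with
    the given seed before assignment.  RGB patches are returned with
    their class label and source scene id.

    Raises
    ------
    ValueError
        If any split would receive 0 items of a class.
    """
    base = cfg or SceneConfig()
    sizes = {
        "BPH": split_counts(n_bph, split),
        "benign": split_counts(n_benign, split),
    }
    for lab, szs in sizes.items():
        if any(s == 0 for s in szs):
            raise ValueError(
                f"split {split} gives an empty subset for class {lab}: {szs}"
            )
    rng = np.random.default_rng(seed)
    scene_side = 2 * _SPRITE_CANVAS  # roomy enough for any sprite + circle
    out: dict[str, list[Patch]] = {"train": [], "val": [], "test": []}
    for lab in ("BPH", "benign"):
        total = sum(sizes[lab])
        order = rng.permutation(total)
        bounds = np.cumsum(sizes[lab])
        for rank, idx in enumerate(order):
            scene_seed = int(rng.integers(0, 2**31 - 1))
            scene_id = f"{lab}_{idx:05d}"
            scfg = replace(
                base,
                height=scene_side,
                width=scene_side,
                n_bph=1 if lab == "BPH" else 0,
                n_benign=0 if lab == "BPH" else 1,
                seed=scene_seed,
            )
            scene, gt = generate_scene(scfg, image_id=scene_id)
            patch = extract_patch(scene, gt.annotations[0], patch_size)
            patch.source = (scene_id, "crop")
            name = ("train", "val", "test")[int(np.searchsorted(bounds, rank, "right"))]
            out[name].append(patch)
    return out


# ---------------------------------------------------------------------------
# external interfaces: PNG scenes + annotation CSV
# ---------------------------------------------------------------------------

CSV_HEADER = ["image_id", "center_row", "center_col", "radius", "label"]


def save_scene(path: str | Path, scene: np.ndarray) -> None:
    Image.fromarray(scene, mode="RGB").save(Path(path), format="PNG")


def load_scene(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(Path(path)).convert("RGB"))


def save_annotations(path: str | Path, annotations: list[PatchAnnotation]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for a in annotations:
            writer.writerow([a.image_id, a.center_row, a.center_col, a.radius, a.label])


def load_annotations(path: str | Path) -> list[PatchAnnotation]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                PatchAnnotation(
                    image_id=row["image_id"],
                    center_row=float(row["center_row"]),
                    center_col=float(row["center_col"]),
                    radius=float(row["radius"]),
                    label=row["label"],
                )
            )
    return out
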