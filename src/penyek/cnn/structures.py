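"""CNN architecture presets and the VGG16-style fine-tuning contract."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .network import Conv2D, Dense, Flatten, Layer, MaxPool2D, Network, ReLU

# structure id -> (total layers, conv kernels, feature maps, pool kernels,
# fully-connected output widths). The final FC width is the classifier
# head; presets keep the printed 3-way head, which callers normally
# override to 2 classes (BPH / benign).
TABLE_PRESETS: dict[int, dict] = {
    1: dict(total_layers=6, conv_kernels=(3, 3), feature_maps=(16, 16),
            pool_kernels=(3, 3), fc_outputs=(128, 3)),
    2: dict(total_layers=6, conv_kernels=(7, 3), feature_maps=(16, 16),
            pool_kernels=(2, 2), fc_outputs=(156, 4)),
    3: dict(total_layers=7, conv_kernels=(9, 9), feature_maps=(16, 16),
            pool_kernels=(3, 3), fc_outputs=(128, 128, 3)),
    4: dict(total_layers=7, conv_kernels=(7, 5), feature_maps=(16, 16),
            pool_kernels=(2, 2), fc_outputs=(256, 128, 3)),
    5: dict(total_layers=9, conv_kernels=(7, 5, 3), feature_maps=(24, 16, 16),
            pool_kernels=(2, 2, 2), fc_outputs=(256, 128, 3)),
    6: dict(total_layers=10, conv_kernels=(9, 7, 5, 3),
            feature_maps=(32, 128, 128, 128), pool_kernels=(3, 3, 3),
            fc_outputs=(2048, 2048, 3)),
    7: dict(total_layers=11, conv_kernels=(11, 5, 3, 3, 3),
            feature_maps=(96, 256, 384, 384, 256), pool_kernels=(3, 3, 3),
            fc_outputs=(4096, 4096, 3)),
}

VGG_BLOCKS: tuple[tuple[int, ...], ...] = (
    (64, 64),
    (128, 128),
    (256, 256, 256),
    (512, 512, 512),
    (512, 512, 512),
)


@dataclass(frozen=True)
class FineTuneConfig:
    """Fine-tuning contract for the VGG16-style architecture.

    A reduced learning rate, a classification head truncated to
    ``head_classes`` outputs, and all conv blocks up to and including
    ``freeze_through_block`` (1-based; 0 = none) held non-trainable.
    """

    base_lr: float = 1e-4
    head_classes: int = 2
    freeze_through_block: int = 0
    pretrained_source: str | None = None

    def __post_init__(self) -> None:
        if self.head_classes < 2:
            raise ValueError("head_classes must be >= 2")
        if not 0 <= self.freeze_through_block <= 5:
            raise ValueError("freeze_through_block must lie in [0, 5]")


@dataclass(frozen=True)
class CNNStructure:
    """Declarative description of a classifier network."""

    structure_id: int | str
    conv_kernel_sizes: tuple[int, ...]
    feature_maps: tuple[int, ...]
    pool_kernel_sizes: tuple[int, ...]
    fc_outputs: tuple[int, ...]
    input_size: int
    input_channels: int
    activation: str = "relu"
    head: str = "softmax"
    vgg_blocks: tuple[tuple[int, ...], ...] | None = None
    freeze_through_block: int = 0
    pretrained_source: str | None = None

    def __post_init__(self) -> None:
        if len(self.conv_kernel_sizes) != len(self.feature_maps):
            raise ValueError("kernel list and feature-map list must align")
        if self.input_channels not in (1, 3):
            raise ValueError("input_channels must be 1 or 3")

    @property
    def head_classes(self) -> int:
        return self.fc_outputs[-1]


def build_structure(
    structure_id: int,
    input_size: int = 49,
    input_channels: int = 1,
    head_classes: int = 2,
) -> CNNStructure:
    """Return preset ``structure_id`` (1-7) with a configurable head.

    Conv layers use stride 1 with resolution-preserving padding and a
    rectifier activation; a max-pool with the row's window and stride 2
    follows each conv layer that has a pool entry; the final layer is a
    softmax over ``head_classes``.
    """
    if structure_id not in TABLE_PRESETS:
        raise ValueError(f"unknown structure id {structure_id!r}; expected 1..7")
    row = TABLE_PRESETS[structure_id]
    fc = tuple(row["fc_outputs"][:-1]) + (head_classes,)
    return CNNStructure(
        structure_id=structure_id,
        conv_kernel_sizes=tuple(row["conv_kernels"]),
        feature_maps=tuple(row["feature_maps"]),
        pool_kernel_sizes=tuple(row["pool_kernels"]),
        fc_outputs=fc,
        input_size=input_size,
        input_channels=input_channels,
    )


def build_vgg16(
    ft: FineTuneConfig, input_channels: int = 3, input_size: int = 224
) -> CNNStructure:
    """VGG16-style structure: 5 conv blocks of 3x3 kernels with widths
    (64,64),(128,128),(256x3),(512x3),(512x3), 2x2 max-pool stride 2
    between blocks, three fully-connected layers and a softmax head
    truncated to ``ft.head_classes``.

    Blocks up to ``ft.freeze_through_block`` are marked non-trainable.
    If ``ft.pretrained_source`` is set, the checkpoint must be readable
    when the network is instantiated (never a silent random init).
    """
    kernels = tuple(3 for blk in VGG_BLOCKS for _ in blk)
    maps = tuple(wd for blk in VGG_BLOCKS for wd in blk)
    return CNNStructure(
        structure_id="vgg16",
        conv_kernel_sizes=kernels,
        feature_maps=maps,
        pool_kernel_sizes=(2, 2, 2, 2, 2),
        fc_outputs=(4096, 4096, ft.head_classes),
        input_size=input_size,
        input_channels=input_channels,
        vgg_blocks=VGG_BLOCKS,
        freeze_through_block=ft.freeze_through_block,
        pretrained_source=ft.pretrained_source,
    )


def spatial_sizes(structure: CNNStructure) -> list[int]:
    """Spatial side length after each pooling stage (ending before FC)."""
    size = structure.input_size
    sizes = [size]
    if structure.vgg_blocks is not None:
        for _ in structure.vgg_blocks:
            size = (size - 2) // 2 + 1
            sizes.append(size)
    else:
        for k in structure.pool_kernel_sizes:
            size = (size - k) // 2 + 1
            sizes.append(size)
    return sizes


def _check_feasible(structure: CNNStructure) -> None:
    for s in spatial_sizes(structure):
        if s < 1:
            raise ValueError(
                f"input size {structure.input_size} is too small for "
                f"structure {structure.structure_id}: pooling exhausts the raster"
            )


def build_network(
    structure: CNNStructure, seed: int = 0, dtype: type = np.float32
) -> Network:
    """Instantiate a ``Network`` with seeded He-uniform initialization.

    ``dtype`` defaults to float32 for speed; pass float64 when doing
    numerical gradient checks.
    """
    _check_feasible(structure)
    rng = np.random.default_rng(seed)
    layers: list[Layer] = []
    size = structure.input_size
    in_ch = structure.input_channels
    if structure.vgg_blocks is not None:
        for bi, block in enumerate(structure.vgg_blocks, start=1):
            frozen = bi <= structure.freeze_through_block
            for width in block:
                layers.append(
                    Conv2D(
                        in_ch,
                        width,
                        3,
                        rng,
                        trainable=not frozen,
                        dtype=dtype,
                        needs_input_grad=bool(layers),
                    )
                )
                layers.append(ReLU())
                in_ch = width
            layers.append(MaxPool2D(2, 2))
            size = (size - 2) // 2 + 1
    else:
        pools = structure.pool_kernel_sizes
        for i, (k, width) in enumerate(
            zip(structure.conv_kernel_sizes, structure.feature_maps)
        ):
            layers.append(
                Conv2D(in_ch, width, k, rng, dtype=dtype, needs_input_grad=bool(layers))
            )
            layers.append(ReLU())
            in_ch = width
            if i < len(pools):
                layers.append(MaxPool2D(pools[i], 2))
                size = (size - pools[i]) // 2 + 1
    layers.append(Flatten())
    features = in_ch * size * size
    widths = structure.fc_outputs
    for i, width in enumerate(widths):
        layers.append(Dense(features, width, rng, dtype=dtype))
        if i < len(widths) - 1:
            layers.append(ReLU())
        features = width
    net = Network(layers)
    if structure.pretrained_source is not None:
        _load_pretrained(net, structure, rng)
    return net


def _load_pretrained(net: Network, structure: CNNStructure, rng: np.random.Generator) -> None:
    path = Path(structure.pretrained_source)
    try:
        archive = np.load(path)
    except (OSError, ValueError) as exc:
        raise ValueError(
            f"pretrained weights {path} could not be read: {exc}"
        ) from exc
    params = net.all_params()
    # match by position; head layers keep their fresh init when the
    # checkpoint shape disagrees (the truncated-head case)
    for i, p in enumerate(params):
        key = f"param_{i}"
        if key in archive and archive[key].shape == p.value.shape:
            p.value = archive[key].astype(np.float64)
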