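"""Training, inference, checkpointing and hard-negative bootstrapping."""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from ..preproc import Patch, rgb_to_gray
from .augment import AugmentConfig, augment
from .network import Network, OPTIMIZERS
from .structures import CNNStructure, build_network

CLASS_ORDER = ("benign", "BPH")  # column 1 of predicted probabilities = P(BPH)


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 30
    initial_lr: float = 1e-4
    epochs: int = 30
    optimizer: str = "sgd"  # sgd = SGD with momentum 0.9
    momentum: float = 0.9
    seed: int = 0
    augment: AugmentConfig | None = None

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class TrainResult:
    network: Network
    structure: CNNStructure
    config: TrainConfig
    loss_history: list[float]
    val_loss_history: list[float]
    norm_mean: float
    norm_std: float


def patches_to_arrays(
    patches: Sequence[Patch], structure: CNNStructure
) -> tuple[np.ndarray, np.ndarray]:
    """Stack patches into (N, C, S, S) float arrays in [0, 1] plus labels.

    Grayscale patches feed a 3-channel structure by channel replication;
    RGB patches feed a 1-channel structure through the luma transform.
    """
    xs = []
    ys = []
    s = structure.input_size
    for p in patches:
        px = p.pixels
        if px.shape[0] != s:
            raise ValueError(
                f"patch size {px.shape[0]} does not match structure input size {s}"
            )
        if structure.input_channels == 1:
            if px.ndim == 3:
                px = rgb_to_gray(px)
            arr = px[None, :, :]
        else:
            if px.ndim == 2:
                arr = np.repeat(px[None, :, :], 3, axis=0)
            else:
                arr = px.transpose(2, 0, 1)
        xs.append(arr.astype(np.float64) / 255.0)
        ys.append(CLASS_ORDER.index(p.label))
    return np.stack(xs), np.asarray(ys, dtype=np.int64)


def train(
    train_patches: Sequence[Patch],
    val_patches: Sequence[Patch],
    structure: CNNStructure,
    tc: TrainConfig,
) -> TrainResult:
    """Minimize cross-entropy by seeded mini-batch gradient descent.

    Deterministic given (data, structure, config): weight init, shuffle
    order and any augmentation all derive from ``tc.seed``.  Validation
    loss is recorded per epoch when a validation set is given.

    Raises
    ------
    ValueError
        If the training set contains a single class, or patch sizes do
        not match the structure's input size.
    """
    patches = list(train_patches)
    if tc.augment is not None:
        patches = augment(patches, replace(tc.augment, seed=tc.seed))
    x, y = patches_to_arrays(patches, structure)
    if np.unique(y).size < 2:
        raise ValueError("training set must contain both classes")
    mean = float(x.mean())
    std = float(x.std()) or 1.0
    x = (x - mean) / std
    xv = yv = None
    if val_patches:
        xv, yv = patches_to_arrays(val_patches, structure)
        xv = (xv - mean) / std

    net = build_network(structure, seed=tc.seed)
    opt_kwargs = {"momentum": tc.momentum} if tc.optimizer == "sgd" else {}
    optimizer = OPTIMIZERS[tc.optimizer](tc.initial_lr, **opt_kwargs)
    rng = np.random.default_rng(tc.seed + 1)
    n = x.shape[0]
    loss_history: list[float] = []
    val_history: list[float] = []
    for _ in range(tc.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, tc.batch_size):
            idx = order[start : start + tc.batch_size]
            loss = net.loss_and_backward(x[idx], y[idx])
            optimizer.step(net.trainable_params())
            epoch_losses.append(loss)
        loss_history.append(float(np.mean(epoch_losses)))
        if xv is not None:
            val_history.append(net.loss(xv, yv))
    return TrainResult(
        network=net,
        structure=structure,
        config=tc,
        loss_history=loss_history,
        val_loss_history=val_history,
        norm_mean=mean,
        norm_std=std,
    )


def predict(result: TrainResult, patches: Sequence[Patch]) -> np.ndarray:
    """Per-patch class probabilities, rows ordered (P(benign), P(BPH))."""
    x, _ = patches_to_arrays(patches, result.structure)
    x = (x - result.norm_mean) / result.norm_std
    # chunk to bound memory on large batches
    probs = [
        result.network.predict_proba(x[i : i + 64]) for i in range(0, x.shape[0], 64)
    ]
    return np.concatenate(probs, axis=0)


def bootstrap_hard_negatives(
    result: TrainResult,
    train_patches: Sequence[Patch],
    val_patches: Sequence[Patch],
    candidate_negatives: Sequence[Patch],
    threshold: float = 0.5,
    rounds: int = 1,
) -> tuple[list[Patch], TrainResult, list[int]]:
    """Iteratively fold confidently-misclassified negatives into training.

    Per round: score the remaining candidates with the current model,
    move those with P(BPH) >= threshold into the training set (labelled
    benign), retrain.  Ends early when a round yields no hard negatives.

    Returns the final training set, the final model and the per-round
    counts of added negatives.
    """
    if any(p.label != "benign" for p in candidate_negatives):
        raise ValueError("candidate negatives must all be labelled benign")
    train_set = list(train_patches)
    remaining = list(candidate_negatives)
    counts: list[int] = []
    current = result
    for _ in range(rounds):
        if not remaining:
            break
        probs = predict(current, remaining)
        hard = probs[:, 1] >= threshold
        n_hard = int(hard.sum())
        counts.append(n_hard)
        if n_hard == 0:
            break
        train_set.extend(p for p, flag in zip(remaining, hard) if flag)
        remaining = [p for p, flag in zip(remaining, hard) if not flag]
        current = train(train_set, val_patches, current.structure, current.config)
    return train_set, current, counts


# ---------------------------------------------------------------------------
# checkpoint I/O: npz weights + JSON sidecar echoing structure and config
# ---------------------------------------------------------------------------


def save_result(result: TrainResult, path: str | Path) -> None:
    path = Path(path)
    weights = {f"param_{i}": w for i, w in enumerate(result.network.get_weights())}
    np.savez(path.with_suffix(".npz"), **weights)
    sidecar = {
        "structure": {
            "structure_id": result.structure.structure_id,
            "conv_kernel_sizes": list(result.structure.conv_kernel_sizes),
            "feature_maps": list(result.structure.feature_maps),
            "pool_kernel_sizes": list(result.structure.pool_kernel_sizes),
            "fc_outputs": list(result.structure.fc_outputs),
            "input_size": result.structure.input_size,
            "input_channels": result.structure.input_channels,
            "vgg": result.structure.vgg_blocks is not None,
            "freeze_through_block": result.structure.freeze_through_block,
        },
        "config": {
            "batch_size": result.config.batch_size,
            "initial_lr": result.config.initial_lr,
            "epochs": result.config.epochs,
            "optimizer": result.config.optimizer,
            "seed": result.config.seed,
        },
        "norm_mean": result.norm_mean,
        "norm_std": result.norm_std,
        "loss_history": result.loss_history,
        "val_loss_history": result.val_loss_history,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_result(path: str | Path) -> TrainResult:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    s = sidecar["structure"]
    if s["vgg"]:
        from .structures import FineTuneConfig, build_vgg16

        structure = build_vgg16(
            FineTuneConfig(
                head_classes=s["fc_outputs"][-1],
                freeze_through_block=s["freeze_through_block"],
            ),
            input_channels=s["input_channels"],
            input_size=s["input_size"],
        )
    else:
        structure = CNNStructure(
            structure_id=s["structure_id"],
            conv_kernel_sizes=tuple(s["conv_kernel_sizes"]),
            feature_maps=tuple(s["feature_maps"]),
            pool_kernel_sizes=tuple(s["pool_kernel_sizes"]),
            fc_outputs=tuple(s["fc_outputs"]),
            input_size=s["input_size"],
            input_channels=s["input_channels"],
        )
    net = build_network(structure, seed=0)
    archive = np.load(path.with_suffix(".npz"))
    net.set_weights([archive[f"param_{i}"] for i in range(len(archive.files))])
    cfg = TrainConfig(
        batch_size=sidecar["config"]["batch_size"],
        initial_lr=sidecar["config"]["initial_lr"],
        epochs=sidecar["config"]["epochs"],
        optimizer=sidecar["config"]["optimizer"],
        seed=sidecar["config"]["seed"],
    )
    return TrainResult(
        network=net,
        structure=structure,
        config=cfg,
        loss_history=list(sidecar["loss_history"]),
        val_loss_history=list(sidecar["val_loss_history"]),
        norm_mean=sidecar["norm_mean"],
        norm_std=sidecar["norm_std"],
    )
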