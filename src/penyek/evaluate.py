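"""Stratified k-fold cross-validation, confusion-matrix metrics and the
experiment harness tying image models, classifiers and folds together.

The positive class is always "BPH".  Metrics with a zero denominator
(e.g. specificity in a fold with no negatives) are reported as ``None``
— undefined, never 0 — and excluded from fold means.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from . import baselines as _baselines
from . import pipeline
from .cnn import TrainConfig, build_structure, build_vgg16, FineTuneConfig
from .cnn import predict as cnn_predict
from .cnn import train as cnn_train
from .preproc import Patch


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    """Fold-averaged metrics plus the per-fold breakdown.

    Top-level values are means over folds in which the metric is
    defined; ``None`` means the metric was undefined in every fold.
    """

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    auc: float | None
    per_fold: list[dict] = field(default_factory=list)


@dataclass(frozen=True)
class CVPlan:
    k: int
    assignments: np.ndarray  # fold index per item
    seed: int

    def fold_indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train_idx, test_idx) for one fold."""
        test = np.flatnonzero(self.assignments == fold)
        train = np.flatnonzero(self.assignments != fold)
        return train, test


def stratified_kfold(labels: Sequence[str], k: int, seed: int = 0) -> CVPlan:
    """Per-class round-robin fold assignment after a seeded shuffle.

    Fold class counts differ by at most 1; raises if any class has
    fewer than ``k`` members.
    """
    labels = np.asarray(labels)
    assignments = np.full(labels.size, -1, dtype=np.int64)
    rng = np.random.default_rng(seed)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < k:
            raise ValueError(
                f"class {cls!r} has {idx.size} members, fewer than k={k} folds"
            )
        idx = rng.permutation(idx)
        assignments[idx] = np.arange(idx.size) % k
    return CVPlan(k=k, assignments=assignments, seed=seed)


def confusion(
    predicted_labels: Sequence[str], true_labels: Sequence[str]
) -> ConfusionCounts:
    """Count tp/fp/tn/fn with BPH as the positive class."""
    pred = np.asarray(predicted_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise ValueError(
            f"length mismatch: {pred.size} predictions vs {true.size} truths"
        )
    p = pred == "BPH"
    t = true == "BPH"
    return ConfusionCounts(
        tp=int((p & t).sum()),
        fp=int((p & ~t).sum()),
        tn=int((~p & ~t).sum()),
        fn=int((~p & t).sum()),
    )


def auc_mann_whitney(scores: Sequence[float], true_labels: Sequence[str]) -> float | None:
    """AUC as the Mann-Whitney rank statistic over P(BPH), ties count 1/2."""
    scores = np.asarray(scores, dtype=np.float64)
    pos = np.asarray(true_labels) == "BPH"
    n_pos = int(pos.sum())
    n_neg = scores.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(scores)  # average ranks on ties
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def metrics(
    counts: ConfusionCounts,
    scores: Sequence[float] | None = None,
    true_labels: Sequence[str] | None = None,
) -> MetricsReport:
    """Accuracy, sensitivity, specificity and (if scores given) AUC."""
    auc = None
    if scores is not None:
        if true_labels is None:
            raise ValueError("true_labels are required to compute AUC from scores")
        auc = auc_mann_whitney(scores, true_labels)
    acc = _ratio(counts.tp + counts.tn, counts.total)
    sens = _ratio(counts.tp, counts.tp + counts.fn)
    spec = _ratio(counts.tn, counts.tn + counts.fp)
    fold = {
        "accuracy": acc,
        "sensitivity": sens,
        "specificity": spec,
        "auc": auc,
        "tp": counts.tp,
        "fp": counts.fp,
        "tn": counts.tn,
        "fn": counts.fn,
    }
    return MetricsReport(
        accuracy=acc, sensitivity=sens, specificity=spec, auc=auc, per_fold=[fold]
    )


def _mean_defined(values: list[float | None]) -> float | None:
    defined = [v for v in values if v is not None]
    if len(defined) < len(values):
        warnings.warn("metric undefined in some folds; excluded from the mean")
    return float(np.mean(defined)) if defined else None


def aggregate_folds(fold_reports: list[MetricsReport]) -> MetricsReport:
    per_fold = [r.per_fold[0] for r in fold_reports]
    return MetricsReport(
        accuracy=_mean_defined([r.accuracy for r in fold_reports]),
        sensitivity=_mean_defined([r.sensitivity for r in fold_reports]),
        specificity=_mean_defined([r.specificity for r in fold_reports]),
        auc=_mean_defined([r.auc for r in fold_reports]),
        per_fold=per_fold,
    )


# ---------------------------------------------------------------------------
# experiment arms
# ---------------------------------------------------------------------------

#: arm descriptor examples
#:   {"kind": "cnn", "image_model": "F", "structure": 5, "train": TrainConfig(...)}
#:   {"kind": "cnn", "image_model": "F", "structure": "vgg16",
#:    "finetune": FineTuneConfig(...), "train": TrainConfig(...)}
#:   {"kind": "baseline", "scheme": "RGB_hist", "n_trees": 200, "seed": 0}
#:   {"kind": "callable", "classify": fn(train_patches, test_patches) ->
#:                                    (predicted_labels, scores)}


def _fit_predict_cnn(
    arm: dict, train_patches: list[Patch], test_patches: list[Patch]
) -> tuple[np.ndarray, np.ndarray]:
    tc: TrainConfig = arm["train"]
    model = arm.get("image_model", "F")
    tr = pipeline.transform_patches(train_patches, model)
    te = pipeline.transform_patches(test_patches, model)
    input_size = tr[0].size
    channels = 3 if tr[0].is_rgb else 1
    if arm["structure"] == "vgg16":
        ft = arm.get("finetune", FineTuneConfig())
        structure = build_vgg16(ft, input_channels=channels, input_size=input_size)
    else:
        structure = build_structure(
            arm["structure"], input_size=input_size, input_channels=channels,
            head_classes=arm.get("head_classes", 2),
        )
    result = cnn_train(tr, [], structure, tc)
    probs = cnn_predict(result, te)
    pred = np.where(probs[:, 1] >= 0.5, "BPH", "benign")
    return pred, probs[:, 1]


def _fit_predict_baseline(
    arm: dict, train_patches: list[Patch], test_patches: list[Patch]
) -> tuple[np.ndarray, np.ndarray]:
    scheme = arm["scheme"]
    xtr = np.stack([_baselines.extract_features(p, scheme) for p in train_patches])
    xte = np.stack([_baselines.extract_features(p, scheme) for p in test_patches])
    clf = _baselines.train_rf(
        xtr,
        [p.label for p in train_patches],
        n_trees=arm.get("n_trees", 200),
        seed=arm.get("seed", 0),
    )
    return _baselines.classify(clf, xte)


def run_experiment(
    dataset: Sequence[Patch], arm: dict, cv: CVPlan
) -> MetricsReport:
    """Train on k-1 folds, evaluate on the held-out fold, average metrics.

    ``dataset`` order must match the labels used to build ``cv``.
    """
    kind = arm.get("kind")
    if kind == "cnn":
        fit_predict = lambda tr, te: _fit_predict_cnn(arm, tr, te)
    elif kind == "baseline":
        fit_predict = lambda tr, te: _fit_predict_baseline(arm, tr, te)
    elif kind == "callable":
        fit_predict = arm["classify"]
    else:
        raise ValueError(f"arm kind must be cnn|baseline|callable, got {kind!r}")
    dataset = list(dataset)
    fold_reports = []
    for fold in range(cv.k):
        train_idx, test_idx = cv.fold_indices(fold)
        tr = [dataset[i] for i in train_idx]
        te = [dataset[i] for i in test_idx]
        pred, scores = fit_predict(tr, te)
        true = [p.label for p in te]
        fold_reports.append(metrics(confusion(pred, true), scores, true))
    return aggregate_folds(fold_reports)


def structure_sweep(
    dataset: Sequence[Patch],
    image_model: str,
    tc: TrainConfig,
    cv: CVPlan,
    structures: Sequence[int] = (1, 2, 3, 4, 5, 6, 7),
) -> dict:
    """Average CV test accuracy over several structures for one image
    model (the aggregation mode used for per-model comparisons)."""
    accs = {}
    for sid in structures:
        arm = {"kind": "cnn", "image_model": image_model, "structure": sid, "train": tc}
        accs[sid] = run_experiment(dataset, arm, cv).accuracy
    defined = [a for a in accs.values() if a is not None]
    return {"per_structure": accs, "mean_accuracy": float(np.mean(defined))}


# ---------------------------------------------------------------------------
# report I/O
# ---------------------------------------------------------------------------

_COLUMNS = ["fold", "accuracy", "sensitivity", "specificity", "auc",
            "tp", "fp", "tn", "fn"]


def report_to_csv(report: MetricsReport, path: str | Path) -> None:
    """Per-fold rows plus a mean row."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for i, fold in enumerate(report.per_fold):
            writer.writerow([i] + [_fmt(fold.get(c)) for c in _COLUMNS[1:]])
        writer.writerow(
            ["mean", _fmt(report.accuracy), _fmt(report.sensitivity),
             _fmt(report.specificity), _fmt(report.auc), "", "", "", ""]
        )


def _fmt(v) -> str:
    if v is None:
        return "NA"
    if isinstance(v, float):
        return f"{v:.6f}"
    return str(v)


def report_to_json(report: MetricsReport, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "accuracy": report.accuracy,
                "sensitivity": report.sensitivity,
                "specificity": report.specificity,
                "auc": report.auc,
                "per_fold": report.per_fold,
            },
            indent=2,
        )
    )
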