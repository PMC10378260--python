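"""Confusion matrices, classification metrics, and experiment reports.

Binary bookkeeping follows the wake-positive convention: TP counts wake
epochs classified wake, TN counts sleep epochs classified sleep. Metrics:

    accuracy  = (TN + TP) / (TN + FP + TP + FN)
    precision = TP / (FP + TP)
    recall    = TP / (FN + TP)
    F1        = TP / (TP + (FP + FN) / 2)

Multiclass tasks reduce one-vs-rest per class. Ratios with a zero
denominator are reported as 0 with an explicit flag.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_matrix",
    "metrics",
    "per_class_metrics",
    "epoch_sweep",
    "report",
]


@dataclass
class ConfusionMatrix:
    """c x c count table; rows are true classes, columns predictions."""

    table: np.ndarray
    classes: list

    @property
    def total(self) -> int:
        return int(self.table.sum())

    def _binary_counts(self) -> tuple[int, int, int, int]:
        if len(self.classes) != 2:
            raise ValueError("binary counts require a 2-class matrix")
        # positive class is the second entry of the class order (wake)
        (tn, fp), (fn, tp) = self.table
        return int(tp), int(fp), int(tn), int(fn)

    @property
    def tp(self) -> int:
        return self._binary_counts()[0]

    @property
    def fp(self) -> int:
        return self._binary_counts()[1]

    @property
    def tn(self) -> int:
        return self._binary_counts()[2]

    @property
    def fn(self) -> int:
        return self._binary_counts()[3]


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    undefined: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "undefined": list(self.undefined),
        }


BINARY_CLASSES = ["sleep", "wake"]  # wake is the positive class


def confusion_matrix(y_true, y_pred, classes: list | None = None) -> ConfusionMatrix:
    """Count table over the declared class order (defaults to
    [sleep, wake], making wake the positive class)."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label sequences must have equal length")
    if not y_true:
        raise ValueError("empty input")
    cls = classes if classes is not None else BINARY_CLASSES
    index = {c: i for i, c in enumerate(cls)}
    table = np.zeros((len(cls), len(cls)), dtype=int)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise ValueError(f"unknown label: {t!r} or {p!r}")
        table[index[t], index[p]] += 1
    return ConfusionMatrix(table=table, classes=list(cls))


def _ratio(num: float, den: float, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return 0.0
    return num / den


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy/precision/recall/F1 from a binary confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp, fp, tn, fn = cm._binary_counts()
    undefined: list[str] = []
    return MetricsReport(
        accuracy=_ratio(tn + tp, tn + fp + tp + fn, "accuracy", undefined),
        precision=_ratio(tp, fp + tp, "precision", undefined),
        recall=_ratio(tp, fn + tp, "recall", undefined),
        f1=_ratio(tp, tp + 0.5 * (fp + fn), "f1", undefined),
        undefined=undefined,
    )


def per_class_metrics(cm: ConfusionMatrix) -> dict[str, MetricsReport]:
    """One-vs-rest precision/recall/F1 per class of a multiclass matrix."""
    if len(cm.classes) < 2:
        raise ValueError("need at least 2 classes")
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    out: dict[str, MetricsReport] = {}
    for i, c in enumerate(cm.classes):
        tp = int(cm.table[i, i])
        fp = int(cm.table[:, i].sum() - tp)
        fn = int(cm.table[i, :].sum() - tp)
        tn = total - tp - fp - fn
        undefined: list[str] = []
        out[c] = MetricsReport(
            accuracy=_ratio(tn + tp, total, "accuracy", undefined),
            precision=_ratio(tp, fp + tp, "precision", undefined),
            recall=_ratio(tp, fn + tp, "recall", undefined),
            f1=_ratio(tp, tp + 0.5 * (fp + fn), "f1", undefined),
            undefined=undefined,
        )
    return out


def epoch_sweep(
    data: dict,
    epoch_counts: list[int],
    seeds: list[int],
    model_builders: dict,
    train_config_base,
) -> list[dict]:
    """Train every model variant at every training-epoch count (fresh
    initialization per cell) and record test accuracy.

    ``data`` holds aligned arrays: features/images/labels plus *_val and
    *_test splits. Returns plot-ready rows with keys
    (model, epochs, seed, test_accuracy).
    """
    from dataclasses import replace

    from .model import predict, train

    if not epoch_counts:
        raise ValueError("epoch_counts must be non-empty")
    rows = []
    for name, builder in model_builders.items():
        for n_ep in epoch_counts:
            for seed in seeds:
                cfg = replace(train_config_base, epochs=n_ep, seed=seed)
                model = builder(seed=seed)
                train(model, data["features"], data["images"], data["labels"], cfg)
                pred, _ = predict(model, data["features_test"], data["images_test"])
                acc = float(np.mean(pred == data["labels_test"]))
                rows.append(
                    {"model": name, "epochs": n_ep, "seed": seed, "test_accuracy": acc}
                )
    return rows


def report(
    metrics_report,
    history,
    cm: ConfusionMatrix,
    out_dir: str | os.PathLike,
) -> dict:
    """Persist a machine-readable report plus confusion-matrix and
    loss/accuracy figures. Returns the report dict (also saved as JSON)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    if isinstance(metrics_report, MetricsReport):
        metrics_payload = metrics_report.as_dict()
    else:  # per-class dict
        metrics_payload = {c: r.as_dict() for c, r in metrics_report.items()}
    payload = {
        "metrics": metrics_payload,
        "confusion_matrix": {
            "classes": cm.classes,
            "table": cm.table.tolist(),
        },
        "history": {
            "loss": history.loss,
            "val_loss": history.val_loss,
            "accuracy": history.accuracy,
            "val_accuracy": history.val_accuracy,
        },
    }
    with open(os.path.join(out_dir, "report.json"), "w") as f:
        json.dump(payload, f, indent=2)

    # loss / accuracy curves
    for key, fname in (("loss", "loss.png"), ("accuracy", "accuracy.png")):
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(payload["history"][key], label=f"training {key}")
        if payload["history"][f"val_{key}"]:
            ax.plot(payload["history"][f"val_{key}"], label=f"validation {key}")
        ax.set_xlabel("training epoch")
        ax.set_ylabel(key)
        ax.legend()
        fig.tight_layout()
        fig.savefig(os.path.join(out_dir, fname), dpi=100)
        plt.close(fig)

    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.imshow(cm.table, cmap="Blues")
    for i in range(len(cm.classes)):
        for j in range(len(cm.classes)):
            ax.text(j, i, str(cm.table[i, j]), ha="center", va="center")
    ax.set_xticks(range(len(cm.classes)), cm.classes, rotation=45)
    ax.set_yticks(range(len(cm.classes)), cm.classes)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    fig.tight_layout()
    fig.savefig(os.path.join(out_dir, "confusion_matrix.png"), dpi=100)
    plt.close(fig)
    return payload
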