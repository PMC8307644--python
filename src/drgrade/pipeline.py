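"""Training loop, evaluation metrics and the ablation harness.

Evaluation follows the mean-Jaccard accuracy convention: with one label and
one prediction per image both sets are singletons, so the index reduces to
the fraction of exact matches.  Precision, recall and F1 are macro-averaged
over the K grades (each grade weighted equally regardless of its
frequency), and the reported F1 is the harmonic mean of the macro precision
and macro recall.  Per-class recall is always reported because minority-
grade recall is the quantity the complement-cross-entropy loss is meant to
improve.

Training is plain mini-batch SGD with momentum, fully deterministic given
the config seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix

from .losses import LossConfig, make_training_loss, LOSS_NAMES
from .model import BackboneSpec, TwoStreamModel, build_model
from .synthetic_data import (
    LabeledImageSet,
    SyntheticDatasetSpec,
    generate_dataset,
    train_test_split,
)

__all__ = [
    "TrainConfig",
    "MetricsReport",
    "evaluate",
    "train",
    "ablate",
    "minority_recall",
]

logger = logging.getLogger("drgrade")


@dataclass
class TrainConfig:
    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 0.01
    momentum: float = 0.9
    optimizer: str = "sgd"
    seed: int = 0
    loss: str = "cce"
    loss_config: LossConfig = field(default_factory=LossConfig)

    def __post_init__(self):
        if self.epochs < 0 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs must be >= 0, batch_size >= 1, lr > 0")
        if self.optimizer != "sgd":
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.loss not in LOSS_NAMES:
            raise ValueError(f"loss must be one of {LOSS_NAMES}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class_recall: np.ndarray
    confusion: np.ndarray          # (K, K) ints; rows = truth, cols = prediction

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "per_class_recall": [float(x) for x in self.per_class_recall],
            "confusion": self.confusion.astype(int).tolist(),
        }


def metrics_from_predictions(y_true: np.ndarray, y_pred: np.ndarray,
                             num_classes: int) -> MetricsReport:
    """Confusion matrix and macro metrics from label/prediction arrays.

    Classes absent from both truth and prediction contribute 0 to the
    macro averages (they are counted in the denominator K).
    """
    y_true = np.asarray(y_true, dtype=np.intp)
    y_pred = np.asarray(y_pred, dtype=np.intp)
    if len(y_true) == 0:
        raise ValueError("cannot evaluate on an empty set")
    cm = _sk_confusion_matrix(y_true, y_pred, labels=np.arange(num_classes))
    tp = np.diag(cm).astype(float)
    row = cm.sum(axis=1).astype(float)       # support per true class
    col = cm.sum(axis=0).astype(float)       # predictions per class
    with np.errstate(divide="ignore", invalid="ignore"):
        recall_c = np.where(row > 0, tp / row, 0.0)
        precision_c = np.where(col > 0, tp / col, 0.0)
    accuracy = float(tp.sum() / cm.sum())
    precision = float(precision_c.mean())
    recall = float(recall_c.mean())
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return MetricsReport(accuracy, precision, recall, float(f1), recall_c, cm)


def evaluate(model: TwoStreamModel, ds: LabeledImageSet,
             batch_size: int = 128) -> MetricsReport:
    """Score the model on a labelled set (argmax prediction, ties → lowest index)."""
    if len(ds) == 0:
        raise ValueError("cannot evaluate on an empty set")
    preds = model.predict(ds.images, batch_size=batch_size)
    return metrics_from_predictions(ds.labels, preds, model.num_classes)


def minority_recall(report: MetricsReport, class_counts,
                    n_rarest: int = 2) -> float:
    """Mean recall over the n rarest classes (by the given training counts)."""
    order = np.argsort(np.asarray(class_counts))
    return float(np.mean(report.per_class_recall[order[:n_rarest]]))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train(model: TwoStreamModel, train_ds: LabeledImageSet,
          cfg: TrainConfig, eval_ds: LabeledImageSet | None = None
          ) -> tuple[TwoStreamModel, pd.DataFrame]:
    """Mini-batch SGD with momentum on the configured loss.

    Returns the (mutated) model and a per-epoch history frame with the mean
    training loss, the training accuracy accumulated over the epoch's
    batches, optional held-out metrics, and the config hash + seed stamp.
    Aborts with a diagnostic if the loss turns non-finite.
    """
    loss_fn = make_training_loss(cfg.loss, cfg.loss_config)
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 1]))
    velocity = {k: np.zeros_like(p.data) for k, p in model.params.items()}
    n = len(train_ds)
    history: list[dict] = []
    stamp = {"config_hash": cfg.config_hash(), "seed": cfg.seed}

    for epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        losses, correct = [], 0
        for lo in range(0, n, cfg.batch_size):
            idx = perm[lo:lo + cfg.batch_size]
            probs = model.forward_tensor(train_ds.images[idx])
            loss = loss_fn(probs, train_ds.labels[idx])
            value = loss.item()
            if not np.isfinite(value):
                raise RuntimeError(
                    f"training diverged: non-finite loss {value} at epoch "
                    f"{epoch}, batch offset {lo} (loss={cfg.loss}, "
                    f"lr={cfg.learning_rate})"
                )
            for p in model.params.values():
                p.zero_grad()
            loss.backward()
            for k, p in model.params.items():
                if p.grad is None:
                    continue
                velocity[k] = cfg.momentum * velocity[k] - cfg.learning_rate * p.grad
                p.data = p.data + velocity[k]
            losses.append(value)
            correct += int((np.argmax(probs.data, axis=1) == train_ds.labels[idx]).sum())

        record = {
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            "train_accuracy": correct / n,
            **stamp,
        }
        if eval_ds is not None:
            rep = evaluate(model, eval_ds)
            record.update(eval_accuracy=rep.accuracy, eval_f1=rep.f1)
        history.append(record)
        logger.info(
            "epoch %d loss=%.4f acc=%.3f", epoch, record["train_loss"],
            record["train_accuracy"],
        )

    return model, pd.DataFrame(history)


# ---------------------------------------------------------------------------
# ablation harness
# ---------------------------------------------------------------------------

#: named model/config overrides; each entry changes a single axis
def _default_model_args() -> dict:
    return dict(
        spec_a=BackboneSpec("tiny", output_channels=16),
        spec_b=BackboneSpec("tiny", output_channels=24, width=10),
        d=256, num_classes=5, reduction_ratio=16,
    )


def ablate(grid: dict[str, dict], data_spec: SyntheticDatasetSpec,
           seeds, test_fraction: float = 0.21,
           train_cfg: TrainConfig | None = None) -> pd.DataFrame:
    """Run each named configuration over the given seeds on synthetic data.

    ``grid`` maps a configuration name to an override dict; recognised keys
    are the :func:`drgrade.model.build_model` arguments plus ``loss``.  Each
    entry should differ from the shared base in one named axis (single vs
    two-stream via ``mode``, homologous via ``shared``, backbone mix via
    ``spec_a``/``spec_b``, loss via ``loss``, attention width via
    ``reduction_ratio``).  Returns one row per configuration with
    mean ± s.d. of each metric over seeds, including minority-class recall.
    """
    base_cfg = train_cfg or TrainConfig()
    model_keys = {"spec_a", "spec_b", "d", "num_classes", "reduction_ratio",
                  "shared", "mode", "normalize", "input_size"}
    rows = []
    for name, overrides in grid.items():
        bad = set(overrides) - model_keys - {"loss"}
        if bad:
            raise ValueError(f"configuration {name!r} has unknown axes {sorted(bad)}")
        per_seed = []
        for seed in seeds:
            spec = SyntheticDatasetSpec(**{**_spec_dict(data_spec), "seed": int(seed)})
            ds = generate_dataset(spec)
            tr, te = train_test_split(ds, test_fraction, seed=int(seed))
            margs = _default_model_args()
            margs.update({k: v for k, v in overrides.items() if k in model_keys})
            margs["num_classes"] = spec.num_classes
            margs["input_size"] = spec.image_size
            mdl = build_model(seed=int(seed), **margs)
            cfg = TrainConfig(**{**asdict(base_cfg),
                                 "seed": int(seed),
                                 "loss": overrides.get("loss", base_cfg.loss),
                                 "loss_config": base_cfg.loss_config})
            mdl, _ = train(mdl, tr, cfg)
            rep = evaluate(mdl, te)
            per_seed.append({
                "accuracy": rep.accuracy, "precision": rep.precision,
                "recall": rep.recall, "f1": rep.f1,
                "minority_recall": minority_recall(rep, spec.class_counts),
            })
        frame = pd.DataFrame(per_seed)
        row = {"config": name, "n_seeds": len(per_seed)}
        for col in frame.columns:
            row[f"{col}_mean"] = float(frame[col].mean())
            row[f"{col}_sd"] = float(frame[col].std(ddof=0))
        rows.append(row)
    return pd.DataFrame(rows)


def _spec_dict(spec: SyntheticDatasetSpec) -> dict:
    return dict(
        num_classes=spec.num_classes, class_counts=spec.class_counts,
        image_size=spec.image_size, grade_params=spec.grade_params,
        background_noise_sd=spec.background_noise_sd, seed=spec.seed,
    )
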