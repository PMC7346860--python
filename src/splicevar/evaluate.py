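"""Cross-validation harness and evaluation reports."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .datasets import CVConfig, kfold_splits
from .metrics import auprc, auroc, binarize, confusion_metrics
from .models import SpliceSiteClassifier, TrainConfig, resolve_architecture


@dataclass(frozen=True)
class FoldMetrics:
    auprc: float
    auroc: float
    precision: float
    recall: float
    mcc: float


@dataclass(frozen=True)
class EvalReport:
    """Per-fold metrics plus their mean and standard deviation.

    The decision threshold for precision/recall/MCC is the strict
    ``probability > 0.5`` rule.
    """

    per_fold: tuple[FoldMetrics, ...]
    threshold: float = 0.5
    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)

    @classmethod
    def from_folds(cls, folds: list[FoldMetrics], threshold: float = 0.5
                   ) -> "EvalReport":
        names = ("auprc", "auroc", "precision", "recall", "mcc")
        mean = {m: float(np.mean([getattr(f, m) for f in folds])) for m in names}
        sd = {m: float(np.std([getattr(f, m) for f in folds], ddof=1))
              if len(folds) > 1 else 0.0 for m in names}
        return cls(tuple(folds), threshold, mean, sd)

    def to_dict(self) -> dict:
        return {"threshold": self.threshold,
                "per_fold": [asdict(f) for f in self.per_fold],
                "mean": dict(self.mean), "sd": dict(self.sd)}


def evaluate_predictions(probs, true_labels, threshold: float = 0.5
                         ) -> FoldMetrics:
    """All reported metrics for one set of probabilistic predictions."""
    probs = np.asarray(probs, dtype=float)
    true = np.asarray(true_labels, dtype=int)
    pred = binarize(probs, threshold)
    precision, recall, mcc = confusion_metrics(pred, true)
    return FoldMetrics(auprc(probs, true), auroc(probs, true),
                       precision, recall, mcc)


def cross_validate(model_name: str, dataset, cv: CVConfig,
                   train_config: TrainConfig) -> EvalReport:
    """k-fold cross-validation with a fresh model per fold.

    For each fold a new classifier is declared, trained on the k-1
    training portions and evaluated on the held-out portion; the previous
    fold's model is discarded. Folds are stratified by label.
    """
    arch = resolve_architecture(model_name)
    folds = []
    for train_records, val_records in kfold_splits(dataset, cv):
        clf = SpliceSiteClassifier(
            arch.value, epochs=train_config.epochs,
            batch_size=train_config.batch_size, lr0=train_config.lr0,
            decay_every=train_config.decay_every,
            decay_factor=train_config.decay_factor,
            momentum=train_config.momentum,
            random_state=train_config.seed)
        y_train = [r.label.value for r in train_records]
        clf.fit(train_records, y_train)
        probs = clf.predict_proba_splice(val_records)
        y_val = [1 if r.label.value == "positive" else 0 for r in val_records]
        folds.append(evaluate_predictions(probs, y_val))
    return EvalReport.from_folds(folds)
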