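"""Two-stage training (contrastive pre-training, fine-tuning) and evaluation.

Stage 1 optimizes the temporal encoder and projection heads with the
combined contrastive objective.  Stage 2 freezes the encoder by default and
trains the cross-modal attention blocks and classifier with cross-entropy
(a flag unfreezes the encoder for fully end-to-end fine-tuning).
Evaluation uses accuracy and F1 from one-vs-rest confusion counts, with
macro averaging over classes, under stratified k-fold cross-validation
assigned at the trial level so overlapping blocks of one trial never
straddle the train/test boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ._tensor import Tensor
from .losses import MerclWeights, mercl_loss
from .nn import Adam
from .pipeline import FeatureSet, MerclModel, ModelConfig

__all__ = ["TrainConfig", "ConfusionCounts", "MetricsReport", "CvReport",
           "pretrain", "finetune", "predict", "compute_metrics",
           "cross_validate"]


@dataclass
class TrainConfig:
    pretrain_epochs: int = 30
    finetune_epochs: int = 150
    batch_size: int = 32
    lr_pretrain: float = 1e-3
    lr_finetune: float = 1e-4
    seed: int = 0
    freeze_encoders: bool = True
    weights: MerclWeights = field(default_factory=MerclWeights)
    optimizer: str = "adam"

    def __post_init__(self):
        if self.pretrain_epochs < 1 or self.finetune_epochs < 1:
            raise ValueError("epoch counts must be >= 1")


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self):
        return self.tp + self.tn + self.fp + self.fn

    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    def f1(self) -> float:
        den = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / den if den else 0.0


@dataclass
class MetricsReport:
    accuracy: float
    macro_f1: float
    per_class: dict                    # class -> ConfusionCounts
    degenerate_classes: list           # classes with TP=FP=FN=0 (F1=0 by convention)


@dataclass
class CvReport:
    fold_accuracy: list
    fold_f1: list
    mean_accuracy: float
    sd_accuracy: float
    mean_f1: float
    sd_f1: float
    fold_assignment: dict              # trial_id -> fold index
    config: dict


def _minibatches(n, batch_size, rng):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def _log_line(log_file, record):
    if log_file is not None:
        log_file.write(json.dumps(record) + "\n")


def pretrain(features: FeatureSet, model: MerclModel, cfg: TrainConfig,
             log_path=None) -> list:
    """Stage 1: optimize encoder + projections with the contrastive loss.

    Returns the per-step loss log (also written as JSON lines if
    ``log_path`` is given).  Raises on divergence, naming the offending
    loss term.
    """
    if cfg.optimizer != "adam":
        raise ValueError(f"unsupported optimizer {cfg.optimizer!r}")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.encoder_parameters(), lr=cfg.lr_pretrain)
    model.train()
    log = []
    log_file = open(log_path, "w") if log_path else None
    try:
        for epoch in range(cfg.pretrain_epochs):
            for batch in _minibatches(len(features), cfg.batch_size, rng):
                sub = features.subset(batch)
                h = model.encode(sub.as_dict())
                z = model.embed(h)
                result = mercl_loss(z, sub.labels, sub.energy_flags, cfg.weights)
                for name, val in (("amcl", result.amcl), ("emcl", result.emcl),
                                  ("smcl", result.smcl)):
                    if not np.isfinite(val):
                        raise FloatingPointError(
                            f"pre-training diverged: {name} loss is {val} "
                            f"at epoch {epoch}")
                opt.zero_grad()
                result.total.backward()
                opt.step()
                rec = {"stage": "pretrain", "epoch": epoch,
                       **result.breakdown()}
                log.append(rec)
                _log_line(log_file, rec)
    finally:
        if log_file:
            log_file.close()
    model.eval()
    return log


def _frozen_h(model: MerclModel, features: FeatureSet) -> dict:
    model.eval()
    h = model.encode(features.as_dict())
    return {m: v.data.copy() for m, v in h.items()}


def finetune(features: FeatureSet, model: MerclModel, cfg: TrainConfig,
             log_path=None) -> list:
    """Stage 2: train CMA + classifier with cross-entropy.

    With ``freeze_encoders`` (default) the encoder runs once in eval mode
    and its parameters are untouched; otherwise encoder parameters join the
    optimizer and gradients flow end to end.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    params = model.head_parameters()
    if not cfg.freeze_encoders:
        params = params + model.encoder_parameters()
    opt = Adam(params, lr=cfg.lr_finetune)
    model.cma.train()
    model.classifier.train()
    frozen = _frozen_h(model, features) if cfg.freeze_encoders else None
    if not cfg.freeze_encoders:
        for m in model.encoder_modules():
            m.train()
    log = []
    log_file = open(log_path, "w") if log_path else None
    try:
        for epoch in range(cfg.finetune_epochs):
            for batch in _minibatches(len(features), cfg.batch_size, rng):
                sub = features.subset(batch)
                if frozen is not None:
                    h = {m: Tensor(frozen[m][batch]) for m in frozen}
                else:
                    h = model.encode(sub.as_dict())
                logits, _ = model.fuse_and_classify(h)
                loss = model.classifier.cross_entropy(logits, sub.labels)
                if not np.isfinite(loss.item()):
                    raise FloatingPointError(
                        f"fine-tuning diverged: cross-entropy is {loss.item()} "
                        f"at epoch {epoch}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                rec = {"stage": "finetune", "epoch": epoch,
                       "cross_entropy": loss.item()}
                log.append(rec)
                _log_line(log_file, rec)
    finally:
        if log_file:
            log_file.close()
    model.eval()
    return log


def predict(features: FeatureSet, model: MerclModel):
    """Eval-mode class predictions for every block."""
    from .fusion import classify
    model.eval()
    h = model.encode(features.as_dict())
    logits, fused = model.fuse_and_classify(h)
    return classify(fused, model.classifier)


def compute_metrics(predictions, labels, n_classes: int | None = None) -> MetricsReport:
    """Accuracy and macro F1 from one-vs-rest confusion counts.

    ``Accuracy = (TP + TN) / (TP + TN + FP + FN)`` per class one-vs-rest
    (equal to the fraction of correct decisions overall) and
    ``F1 = 2 TP / (2 TP + FP + FN)`` macro-averaged; a class with
    TP = FP = FN = 0 contributes F1 = 0 and is flagged as degenerate.
    """
    pred = np.asarray(predictions, dtype=int).reshape(-1)
    true = np.asarray(labels, dtype=int).reshape(-1)
    if pred.size == 0 or pred.size != true.size:
        raise ValueError("predictions and labels must be nonempty and equal length")
    if n_classes is None:
        n_classes = int(max(pred.max(), true.max())) + 1
    per_class, f1s, degenerate = {}, [], []
    for c in range(n_classes):
        tp = int(np.sum((pred == c) & (true == c)))
        fp = int(np.sum((pred == c) & (true != c)))
        fn = int(np.sum((pred != c) & (true == c)))
        tn = int(np.sum((pred != c) & (true != c)))
        counts = ConfusionCounts(tp, tn, fp, fn)
        per_class[c] = counts
        if tp == fp == fn == 0:
            degenerate.append(c)
        f1s.append(counts.f1())
    accuracy = float(np.mean(pred == true))
    return MetricsReport(accuracy=accuracy, macro_f1=float(np.mean(f1s)),
                         per_class=per_class, degenerate_classes=degenerate)


def _stratified_trial_folds(trial_ids, trial_labels, k, rng):
    folds = {}
    for cls in np.unique(trial_labels):
        members = [t for t, y in zip(trial_ids, trial_labels) if y == cls]
        if len(members) < k:
            raise ValueError(
                f"class {cls} has only {len(members)} trials; stratified "
                f"{k}-fold assignment needs at least {k} per class — reduce k "
                f"or add trials")
        members = list(rng.permutation(members))
        for i, t in enumerate(members):
            folds[t] = i % k
    return folds


def cross_validate(features: FeatureSet, in_width: int,
                   model_cfg: ModelConfig | None = None,
                   cfg: TrainConfig | None = None, k: int = 4) -> CvReport:
    """Stratified k-fold evaluation of the full two-stage pipeline.

    Folds are assigned at the trial level (stratified by label) so that
    overlapping blocks from one trial never appear on both sides of the
    split.  Each fold trains a fresh model from the same seed family and
    evaluates on its held-out trials; the report aggregates the per-fold
    accuracy and macro F1 as mean ± sd.
    """
    model_cfg = model_cfg or ModelConfig()
    cfg = cfg or TrainConfig()
    rng = np.random.default_rng(cfg.seed)
    trial_ids = []
    trial_labels = []
    for t, y in zip(features.trial_ids, features.labels):
        if t not in trial_ids:
            trial_ids.append(t)
            trial_labels.append(y)
    fold_of = _stratified_trial_folds(trial_ids, np.array(trial_labels), k, rng)

    accs, f1s = [], []
    for fold in range(k):
        test_mask = np.array([fold_of[t] == fold for t in features.trial_ids])
        train_set = features.subset(np.where(~test_mask)[0])
        test_set = features.subset(np.where(test_mask)[0])
        fold_model_cfg = ModelConfig(**{**asdict(model_cfg),
                                        "seed": model_cfg.seed + fold})
        model = MerclModel(in_width, fold_model_cfg)
        fold_cfg = TrainConfig(**{**asdict(cfg), "seed": cfg.seed + fold,
                                  "weights": cfg.weights})
        pretrain(train_set, model, fold_cfg)
        finetune(train_set, model, fold_cfg)
        report = compute_metrics(predict(test_set, model).labels, test_set.labels,
                                 model_cfg.n_classes)
        accs.append(report.accuracy)
        f1s.append(report.macro_f1)
    return CvReport(fold_accuracy=accs, fold_f1=f1s,
                    mean_accuracy=float(np.mean(accs)),
                    sd_accuracy=float(np.std(accs)),
                    mean_f1=float(np.mean(f1s)), sd_f1=float(np.std(f1s)),
                    fold_assignment=fold_of,
                    config={"train": {**asdict(cfg), "weights": asdict(cfg.weights)},
                            "model": asdict(model_cfg), "k": k})
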