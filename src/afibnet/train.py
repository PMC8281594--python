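"""The k-fold class-weighted training and evaluation protocol.

Episodes are partitioned into k = 10 folds (~90:10 train:validation
per fold), either **inter-patient** — the unit of assignment is the
subject, so no subject ever appears on both sides of a fold — or
**intra-patient** — episode-level stratified assignment.  Both modes
stratify by class so every fold sees every class.

Class imbalance is handled by weighting the cross-entropy loss with
inverse-frequency weights computed on each fold's training split:

    w_c = n_total / (n_classes * n_c)

Training is plain mini-batch gradient descent with the Adam update
rule at the configured hyperparameters (defaults: learning rate 1e-4,
batch size 16, 100 epochs, no early stopping, no schedule); epoch
shuffling is seeded, so the whole protocol is deterministic given the
root seed.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _nn
from .metrics import MetricsReport, compute_metrics, fold_average, report_frame
from .model import AFibNetModel, ModelConfig, build_model, save_checkpoint

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig", "FoldPlan", "make_folds", "class_weights",
    "train_fold", "evaluate", "run_protocol", "ProtocolResult",
]


@dataclass
class TrainConfig:
    """Optimization hyperparameters; defaults as the method prescribes."""

    learning_rate: float = 1e-4
    batch_size: int = 16
    epochs: int = 100
    k: int = 10
    seed: int = 0
    class_weights: dict[str, float] | None = None  # None -> inverse frequency

    def __post_init__(self) -> None:
        if self.learning_rate < 0 or self.batch_size < 1 or self.epochs < 0 or self.k < 2:
            raise ValueError("invalid training hyperparameters")


@dataclass
class FoldPlan:
    """k train/validation index partitions plus per-fold class weights."""

    folds: list[dict]  # each: {"train": ndarray, "val": ndarray, "class_weights": dict}
    split_mode: str
    classes: tuple[str, ...]
    k: int

    def __post_init__(self) -> None:
        n = self.k
        if len(self.folds) != n:
            raise ValueError("fold count mismatch")


def class_weights(labels, classes) -> dict[str, float]:
    """Inverse-frequency weights: n_total / (n_classes * n_class)."""
    labels = list(labels)
    n_total = len(labels)
    out = {}
    for c in classes:
        n_c = sum(1 for l in labels if l == c)
        if n_c == 0:
            raise ValueError(f"class {c!r} absent from the training split")
        out[c] = n_total / (len(classes) * n_c)
    return out


def make_folds(labels, subjects, k: int = 10, split_mode: str = "inter_patient",
               seed: int = 0) -> FoldPlan:
    """Build the k-fold partition.

    inter_patient: subjects (stratified by their majority class) are
    shuffled and dealt round-robin to folds; fold f validates on its
    subjects' episodes and trains on everyone else's.  intra_patient:
    the same dealing at episode level.  Deterministic given seed.
    """
    labels = np.asarray(list(labels))
    subjects = np.asarray([str(s) for s in subjects])
    if len(labels) != len(subjects):
        raise ValueError("labels and subjects must be parallel")
    classes = tuple(sorted(set(labels), key=lambda c: ("N", "AF", "NON_AF").index(c)
                           if c in ("N", "AF", "NON_AF") else 99))
    rng = np.random.Generator(np.random.Philox(key=seed))
    n = len(labels)
    fold_of = np.empty(n, dtype=int)

    if split_mode == "inter_patient":
        uniq = sorted(set(subjects))
        if len(uniq) < k:
            raise ValueError(
                f"inter-patient split needs at least k={k} subjects, got {len(uniq)}"
            )
        # Majority class per subject, for stratified dealing.
        subj_class = {}
        for s in uniq:
            ls = labels[subjects == s]
            vals, cnts = np.unique(ls, return_counts=True)
            subj_class[s] = vals[np.argmax(cnts)]
        subj_fold = {}
        for c in classes:
            members = [s for s in uniq if subj_class[s] == c]
            order = rng.permutation(len(members))
            for pos, j in enumerate(order):
                subj_fold[members[j]] = pos % k
        for s in uniq:
            if s not in subj_fold:  # subject of a class outside `classes`
                subj_fold[s] = int(rng.integers(k))
        for i in range(n):
            fold_of[i] = subj_fold[subjects[i]]
    elif split_mode == "intra_patient":
        for c in classes:
            idx = np.flatnonzero(labels == c)
            order = rng.permutation(len(idx))
            for pos, j in enumerate(order):
                fold_of[idx[j]] = pos % k
    else:
        raise ValueError(f"unknown split_mode {split_mode!r}")

    folds = []
    for f in range(k):
        val = np.flatnonzero(fold_of == f)
        train = np.flatnonzero(fold_of != f)
        if split_mode == "inter_patient":
            overlap = set(subjects[train]) & set(subjects[val])
            assert not overlap, f"subject leakage across fold {f}: {sorted(overlap)[:5]}"
        folds.append({
            "train": train,
            "val": val,
            "class_weights": class_weights(labels[train], classes),
        })
    return FoldPlan(folds=folds, split_mode=split_mode, classes=classes, k=k)


def _encode_labels(labels, classes) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    try:
        return np.array([index[l] for l in labels])
    except KeyError as e:
        raise ValueError(f"label {e.args[0]!r} outside the configured class set {classes}")


def train_fold(model: AFibNetModel, values: np.ndarray, labels, train_idx,
               config: TrainConfig, weights: dict[str, float] | None = None):
    """Train the model in place on the given episode indices.

    Returns (model, loss_log) where loss_log holds the mean weighted
    training loss of each epoch.  Runs the full configured epoch count;
    there is no early stopping.
    """
    classes = model.config.classes
    labels = np.asarray(list(labels))
    train_idx = np.asarray(train_idx)
    y = _encode_labels(labels[train_idx], classes)
    present = set(y.tolist())
    missing = [c for i, c in enumerate(classes) if i not in present]
    if missing:
        raise ValueError(f"class(es) {missing} absent from the training split")
    w_map = weights or config.class_weights or class_weights(labels[train_idx], classes)
    w = np.array([w_map[classes[i]] for i in y], dtype=np.float64)
    x = np.ascontiguousarray(values[train_idx], dtype=np.float32)

    net = model.network
    opt = _nn.Adam(net.params, net.grads, lr=config.learning_rate)
    rng = np.random.Generator(np.random.Philox(key=config.seed))
    n = len(train_idx)
    loss_log = []
    binary = model.config.n_classes == 2
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        total, batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            sel = order[start:start + config.batch_size]
            logits = net.forward(x[sel][:, :, None])
            if binary:
                loss, grad = _nn.weighted_bce(logits, y[sel].astype(np.float64), w[sel])
            else:
                loss, grad = _nn.weighted_cce(logits, y[sel], w[sel])
            net.backward(grad.reshape(logits.shape))
            opt.step()
            total += loss
            batches += 1
        loss_log.append(total / max(batches, 1))
        logger.debug("epoch %d/%d: loss %.5f", epoch + 1, config.epochs, loss_log[-1])
    return model, loss_log


def evaluate(model: AFibNetModel, values: np.ndarray, labels) -> MetricsReport:
    """Evaluate on labeled episodes; returns the full metrics report."""
    labels = list(labels)
    if len(labels) == 0:
        raise ValueError("cannot evaluate on an empty episode set")
    _encode_labels(labels, model.config.classes)  # validate vocabulary
    _, predicted = model.predict(np.asarray(values))
    return compute_metrics(labels, predicted, model.config.classes)


@dataclass
class ProtocolResult:
    """Outputs of one protocol run: per-fold reports, their headline
    summaries, the fold-averaged summary, and per-fold loss logs."""

    reports: list[MetricsReport]
    summaries: list[dict]
    average: dict
    loss_logs: list[list[float]]
    plan: FoldPlan
    fold_indices: list[int]


def run_protocol(values: np.ndarray, labels, subjects, model_config: ModelConfig,
                 train_config: TrainConfig, split_mode: str = "inter_patient",
                 out_dir=None, folds: list[int] | None = None,
                 save_checkpoints: bool = False) -> ProtocolResult:
    """Compose make_folds -> train_fold -> evaluate over the folds.

    ``folds`` restricts the run to a subset of fold indices (all k by
    default).  When ``out_dir`` is given, per-fold and averaged metric
    tables (percent, 2 decimals), loss logs, the resolved config, and
    optionally checkpoints are persisted there.  End-to-end
    deterministic given the root seed.
    """
    values = np.asarray(values)
    labels = list(labels)
    if out_dir is not None:
        os.makedirs(str(out_dir), exist_ok=True)
    plan = make_folds(labels, subjects, k=train_config.k, split_mode=split_mode,
                      seed=train_config.seed)
    if tuple(plan.classes) != tuple(model_config.classes):
        raise ValueError(
            f"data classes {plan.classes} do not match model classes {model_config.classes}"
        )
    run_folds = list(range(plan.k)) if folds is None else list(folds)
    reports, summaries, loss_logs = [], [], []
    for f in run_folds:
        fold = plan.folds[f]
        model = build_model(model_config, seed=train_config.seed + f)
        try:
            model, losses = train_fold(model, values, labels, fold["train"],
                                       train_config, weights=fold["class_weights"])
            report = evaluate(model, values[fold["val"]], [labels[i] for i in fold["val"]])
        except Exception as e:
            raise RuntimeError(f"fold {f}: {e}") from e
        reports.append(report)
        summaries.append(report.summary())
        loss_logs.append(losses)
        logger.info("fold %d: %s", f, {k: round(v, 4) for k, v in report.summary().items()})
        if out_dir is not None and save_checkpoints:
            save_checkpoint(model, os.path.join(str(out_dir), f"fold{f}.npz"))
    average = fold_average(summaries)
    result = ProtocolResult(reports=reports, summaries=summaries, average=average,
                            loss_logs=loss_logs, plan=plan, fold_indices=run_folds)
    if out_dir is not None:
        _persist(result, model_config, train_config, split_mode, out_dir)
    return result


def _persist(result: ProtocolResult, model_config: ModelConfig,
             train_config: TrainConfig, split_mode: str, out_dir) -> None:
    os.makedirs(str(out_dir), exist_ok=True)
    frame = report_frame(result.summaries, result.average)
    frame.to_csv(os.path.join(str(out_dir), "metrics.csv"), index=False)
    payload = {
        "split_mode": split_mode,
        "folds_run": result.fold_indices,
        "summaries": result.summaries,
        "average": result.average,
        "loss_logs": result.loss_logs,
        "train_config": asdict(train_config),
        "model_config": model_config.to_dict(),
    }
    with open(os.path.join(str(out_dir), "report.json"), "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
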