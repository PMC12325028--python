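"""Training, cross-validation and evaluation of the three-view model.

The loss for one subject is the cross-entropy of the soft-voted fused
probabilities plus an equally weighted auxiliary cross-entropy per
branch, so every branch keeps its own gradient signal inside the
ensemble.  Optimisation is Adam with L2 weight decay folded into the
gradient, with early stopping on a stratified 20% inner validation
split (patience in epochs, best parameters restored).  Evaluation uses
stratified k-fold cross-validation and reports accuracy, sensitivity,
specificity, F1 and AUC as per-fold values with mean +/- standard
error.
"""
from __future__ import annotations

import copy
import math
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold, train_test_split

from .fc import FCMatrix
from .hypergraph import Hypergraph
from .knn import knn_hyperedges
from .local import recursive_partition
from .model import BRANCHES, ModelConfig, SubjectCache, UMHLModel, softmax
from .prior import build_prior_hypergraph
from .simulate import CohortDataset

__all__ = [
    "TrainConfig",
    "MetricsReport",
    "FittedModel",
    "build_views",
    "train_model",
    "cross_validate",
    "compute_metrics",
    "predict_proba",
]

log = logging.getLogger("umhl")


@dataclass
class TrainConfig:
    """Optimisation + construction settings (defaults follow the method)."""

    lr: float = 5e-4
    weight_decay: float = 1e-5
    epochs: int = 100
    early_stop_patience: int = 10
    folds: int = 5
    seed: int = 0
    batch_size: int = 16
    # hypergraph construction
    k: int = 5
    t: float = 0.3
    d_max: int = 4
    centers: int | None = None
    max_edges: int | None = None
    # architecture
    hidden_dim: int = 64
    mask_rate: float = 0.2
    normalize: bool = True
    vote: str = "logits"
    fisher_z: bool = False

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.folds < 2:
            raise ValueError("need at least 2 folds")
        if self.epochs < 1 or self.early_stop_patience < 1:
            raise ValueError("epochs and patience must be >= 1")

    def resolved_max_edges(self, n_rois: int) -> int:
        if self.max_edges is not None:
            return self.max_edges
        s = self.centers if self.centers is not None else math.ceil(math.sqrt(n_rois))
        return min(s * 2 ** self.d_max, n_rois)


@dataclass
class MetricsReport:
    """Per-fold classification metrics with mean and standard error."""

    fold_metrics: list[dict[str, float]]
    mean: dict[str, float] = field(init=False)
    se: dict[str, float] = field(init=False)

    METRICS = ("acc", "sen", "spe", "f1", "auc")

    def __post_init__(self) -> None:
        if not self.fold_metrics:
            raise ValueError("need at least one fold")
        self.mean = {}
        self.se = {}
        for m in self.METRICS:
            vals = np.array([f[m] for f in self.fold_metrics])
            if ((vals < 0) | (vals > 1)).any():
                raise ValueError(f"metric {m} outside [0, 1]: {vals}")
            self.mean[m] = float(vals.mean())
            self.se[m] = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0

    @property
    def acc(self) -> float:
        return self.mean["acc"]

    @property
    def sen(self) -> float:
        return self.mean["sen"]

    @property
    def spe(self) -> float:
        return self.mean["spe"]

    @property
    def f1(self) -> float:
        return self.mean["f1"]

    @property
    def auc(self) -> float:
        return self.mean["auc"]

    def to_dict(self) -> dict:
        return {"folds": self.fold_metrics, "mean": self.mean, "se": self.se}


@dataclass
class FittedModel:
    """A trained model plus everything needed to evaluate new subjects."""

    model: UMHLModel
    config: TrainConfig
    history: dict


def compute_metrics(y_true: np.ndarray, y_prob: np.ndarray) -> dict[str, float]:
    """ACC/SEN/SPE/F1 at the 0.5 threshold plus midrank AUC.

    ``y_prob`` is the positive-class (patient) probability; a subject
    is called positive when it exceeds 0.5, matching the argmax rule
    with ties resolved toward the control class.  AUC uses the
    rank-statistic (Mann-Whitney) form with midranks for ties; it is
    0.5 when one class is absent or the scores are constant.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_prob = np.asarray(y_prob, dtype=float)
    if y_true.shape != y_prob.shape:
        raise ValueError("y_true and y_prob must align")
    pred = (y_prob > 0.5).astype(int)
    tp = int(np.sum((pred == 1) & (y_true == 1)))
    tn = int(np.sum((pred == 0) & (y_true == 0)))
    fp = int(np.sum((pred == 1) & (y_true == 0)))
    fn = int(np.sum((pred == 0) & (y_true == 1)))
    n = len(y_true)
    acc = (tp + tn) / n if n else 0.0
    sen = tp / (tp + fn) if (tp + fn) else 0.0
    spe = tn / (tn + fp) if (tn + fp) else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    n_pos, n_neg = tp + fn, tn + fp
    if n_pos == 0 or n_neg == 0:
        auc = 0.5
    else:
        ranks = rankdata(y_prob)
        auc = (ranks[y_true == 1].mean() - (n_pos + 1) / 2.0) / n_neg
    return {"acc": acc, "sen": sen, "spe": spe, "f1": f1, "auc": float(auc)}


def build_views(
    subjects: Sequence[FCMatrix],
    prior_hg: Hypergraph,
    config: TrainConfig,
) -> list[dict[str, Hypergraph]]:
    """Per-subject hypergraph triples (prior shared, local/global per FC)."""
    views = []
    for fc in subjects:
        local_hg, _ = recursive_partition(
            fc, t=config.t, d_max=config.d_max, n_centers=config.centers
        )
        views.append(
            {
                "prior": prior_hg,
                "local": local_hg,
                "global": knn_hyperedges(fc, k=config.k),
            }
        )
    return views


def build_caches(
    model: UMHLModel,
    subjects: Sequence[FCMatrix],
    views: Sequence[dict[str, Hypergraph]],
) -> list[SubjectCache]:
    return [model.build_cache(fc, v) for fc, v in zip(subjects, views)]


def _onehot(label: int, c: int) -> np.ndarray:
    y = np.zeros(c)
    y[label] = 1.0
    return y


def _subject_loss_and_grad(
    model: UMHLModel,
    cache: SubjectCache,
    label: int,
    grads: dict[str, np.ndarray],
    training: bool,
    rng: np.random.Generator | None,
) -> float:
    """Loss (fused + per-branch CE) and gradient accumulation for one subject."""
    cfg = model.config
    acts = model.forward_subject(cache, training=training, rng=rng)
    y = _onehot(label, cfg.n_classes)
    logits = {b: acts[b]["logits"] for b in BRANCHES}
    branch_probs = {b: softmax(logits[b]) for b in BRANCHES}
    eps = 1e-12

    loss = 0.0
    dlogits = {b: branch_probs[b] - y for b in BRANCHES}  # auxiliary CE terms
    for b in BRANCHES:
        loss -= float(np.log(branch_probs[b][label] + eps))

    if cfg.vote == "logits":
        fused = softmax(sum(logits.values()))
        dfused = fused - y
        for b in BRANCHES:
            dlogits[b] = dlogits[b] + dfused
    else:  # vote == "probs"
        s = sum(branch_probs.values())
        fused = softmax(s)
        ds = fused - y
        for b in BRANCHES:
            p = branch_probs[b]
            dlogits[b] = dlogits[b] + p * (ds - float(p @ ds))
    loss -= float(np.log(fused[label] + eps))

    if grads is not None:
        model.backward_subject(cache, acts, dlogits, grads)
    return loss


class _Adam:
    """Standard Adam with bias correction; weight decay added to grads."""

    def __init__(self, params: dict[str, np.ndarray], lr: float, weight_decay: float):
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, p in params.items():
            g = grads[k] + self.wd * p
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)


def predict_proba(model: UMHLModel, caches: Sequence[SubjectCache]) -> np.ndarray:
    """Fused class-probability matrix (subjects x classes), mask off."""
    out = np.zeros((len(caches), model.config.n_classes))
    for i, cache in enumerate(caches):
        acts = model.forward_subject(cache, training=False)
        out[i] = model.fused_probs(acts)
    return out


def _evaluate_acc_and_ce(
    model: UMHLModel, caches: Sequence[SubjectCache], labels: np.ndarray
) -> tuple[float, float]:
    probs = predict_proba(model, caches)
    pred = np.argmax(probs, axis=1)
    acc = float(np.mean(pred == labels))
    ce = float(-np.mean(np.log(probs[np.arange(len(labels)), labels] + 1e-12)))
    return acc, ce


def train_model(
    dataset: CohortDataset,
    config: TrainConfig,
    subject_idx: Sequence[int] | None = None,
    views: Sequence[dict[str, Hypergraph]] | None = None,
    caches: Sequence[SubjectCache] | None = None,
    model: UMHLModel | None = None,
    seed: int | None = None,
) -> FittedModel:
    """Fit the three-view model on (a subset of) a cohort.

    An inner stratified 80/20 split of the training subjects drives
    early stopping on validation accuracy.  Precomputed ``views`` /
    ``caches`` (aligned with the full cohort) can be passed to avoid
    rebuilding hypergraphs, e.g. across cross-validation folds.
    Deterministic given the seed.
    """
    idx = np.arange(dataset.n_subjects) if subject_idx is None else np.asarray(subject_idx)
    labels = dataset.labels[idx]
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training set contains a single class")
    if counts.min() < 2:
        raise ValueError("need at least 2 subjects per class to train")

    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    n_rois = dataset.subjects[0].n_rois
    prior_hg = build_prior_hypergraph(dataset.parcellation)
    if model is None:
        mconfig = ModelConfig(
            n_rois=n_rois,
            n_prior_edges=prior_hg.n_edges,
            max_edges=config.resolved_max_edges(n_rois),
            hidden_dim=config.hidden_dim,
            mask_rate=config.mask_rate,
            normalize=config.normalize,
            vote=config.vote,
            fisher_z=config.fisher_z,
        )
        model = UMHLModel.initialize(mconfig, rng)
    if caches is None:
        if views is None:
            views = build_views(dataset.subjects, prior_hg, config)
        caches = build_caches(model, dataset.subjects, views)

    # inner stratified split for early stopping
    tr_idx, val_idx = train_test_split(
        idx, test_size=0.2, stratify=labels, random_state=int(rng.integers(2**31 - 1))
    )
    tr_caches = [caches[i] for i in tr_idx]
    tr_labels = dataset.labels[tr_idx]
    val_caches = [caches[i] for i in val_idx]
    val_labels = dataset.labels[val_idx]

    # early-stopping score: validation accuracy, ties broken by lower
    # validation cross-entropy (accuracy alone is too coarse on small
    # inner splits)
    best_score = (-np.inf, -np.inf)
    best_params = copy.deepcopy(model.params)
    best_epoch = 0
    stall = 0
    opt = _Adam(model.params, lr=config.lr, weight_decay=config.weight_decay)
    history: dict = {"train_loss": [], "val_acc": []}

    n_train = len(tr_idx)
    for epoch in range(config.epochs):
        order = rng.permutation(n_train)
        epoch_loss = 0.0
        for start in range(0, n_train, config.batch_size):
            batch = order[start : start + config.batch_size]
            grads = model.zero_grads()
            batch_loss = 0.0
            for i in batch:
                batch_loss += _subject_loss_and_grad(
                    model, tr_caches[i], int(tr_labels[i]), grads, training=True, rng=rng
                )
            for k in grads:
                grads[k] /= len(batch)
            opt.step(model.params, grads)
            epoch_loss += batch_loss
        epoch_loss /= n_train
        val_acc, val_ce = _evaluate_acc_and_ce(model, val_caches, val_labels)
        history["train_loss"].append(epoch_loss)
        history["val_acc"].append(val_acc)
        log.debug("epoch %d: loss=%.4f val_acc=%.3f val_ce=%.4f", epoch, epoch_loss, val_acc, val_ce)
        score = (val_acc, -val_ce)
        if score > best_score:
            best_score = score
            best_params = copy.deepcopy(model.params)
            best_epoch = epoch
            stall = 0
        else:
            stall += 1
            if stall >= config.early_stop_patience:
                break
    model.params = best_params
    history["best_epoch"] = best_epoch
    history["best_val_acc"] = float(best_score[0])
    return FittedModel(model=model, config=config, history=history)


def cross_validate(dataset: CohortDataset, config: TrainConfig) -> MetricsReport:
    """Stratified k-fold CV; metrics computed on held-out folds only.

    Hypergraph views are built once per subject and shared across
    folds (construction does not depend on other subjects, so there is
    no leakage).  Each fold trains from a fresh seeded initialisation.
    """
    labels = dataset.labels
    if len(np.unique(labels)) < 2:
        raise ValueError("cross-validation needs both classes present")
    n_rois = dataset.subjects[0].n_rois
    prior_hg = build_prior_hypergraph(dataset.parcellation)
    views = build_views(dataset.subjects, prior_hg, config)

    # one model shell per fold; caches depend only on normalization
    mconfig = ModelConfig(
        n_rois=n_rois,
        n_prior_edges=prior_hg.n_edges,
        max_edges=config.resolved_max_edges(n_rois),
        hidden_dim=config.hidden_dim,
        mask_rate=config.mask_rate,
        normalize=config.normalize,
        vote=config.vote,
        fisher_z=config.fisher_z,
    )
    seed_rng = np.random.default_rng(config.seed)
    shell = UMHLModel.initialize(mconfig, seed_rng)
    caches = build_caches(shell, dataset.subjects, views)

    skf = StratifiedKFold(n_splits=config.folds, shuffle=True, random_state=config.seed)
    fold_metrics = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        fold_seed = int(seed_rng.integers(2**31 - 1))
        fold_model = UMHLModel.initialize(mconfig, np.random.default_rng(fold_seed))
        fitted = train_model(
            dataset,
            config,
            subject_idx=tr,
            caches=caches,
            model=fold_model,
            seed=fold_seed,
        )
        probs = predict_proba(fitted.model, [caches[i] for i in te])
        fold_metrics.append(compute_metrics(labels[te], probs[:, 1]))
        log.info("fold %d: %s", fold, fold_metrics[-1])
    return MetricsReport(fold_metrics=fold_metrics)
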