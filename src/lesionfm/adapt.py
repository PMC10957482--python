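"""Task-specific adaptation: frozen-feature linear probing and fine-tuning.

Two routes turn a pretrained encoder into a task model:

* **features** — extract the frozen backbone representation (projection head
  discarded; 4,096 dims for the full-size configuration) and train a
  logistic-regression probe with a hyperparameter search on a tuning split;
* **fine-tune** — continue gradient training of all layers with a
  classification head, cross-entropy loss, momentum SGD with step-wise
  learning-rate decay, and checkpoint selection on the tuning split.

The reduced-training-data protocol (stratified, optionally nested subsets at
50/20/10%) lives here too; tuning and test sets are never subsampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from . import nn
from .augment import AugmentationPolicy, apply_view, make_finetune_policy
from .encoder import Checkpoint, Encoder, EncoderConfig
from .types import Patch


def extract_features(
    source: Union[Checkpoint, Encoder],
    patches: Sequence[Patch],
    case_ids: Optional[Sequence[str]] = None,
    batch: int = 32,
) -> pd.DataFrame:
    """Frozen-encoder features, one row per patch (deterministic, eval mode)."""
    encoder = source.build_encoder() if isinstance(source, Checkpoint) else source
    rows = []
    for s in range(0, len(patches), batch):
        rows.append(encoder.features(list(patches[s:s + batch]), train=False))
    feats = np.vstack(rows) if rows else np.empty((0, encoder.config.feature_dim))
    if case_ids is None:
        case_ids = [f"case_{i:04d}" for i in range(len(patches))]
    return pd.DataFrame(feats, index=list(case_ids),
                        columns=[f"f{j:04d}" for j in range(feats.shape[1])])


@dataclass
class ProbeModel:
    """A multinomial logistic probe over standardized frozen features."""

    model: Pipeline
    C: float
    class_weight: Optional[str]
    search_budget: int
    seed: Optional[int] = None
    tuning_score: float = float("nan")

    def predict_proba(self, features) -> np.ndarray:
        return self.model.predict_proba(np.asarray(features))

    def predict(self, features) -> np.ndarray:
        return self.model.predict(np.asarray(features))


def fit_linear_probe(
    features,
    labels,
    tune_features=None,
    tune_labels=None,
    search_budget: int = 18,
    rng: Optional[np.random.Generator] = None,
    max_iter: int = 2000,
) -> ProbeModel:
    """L2 logistic regression on all features with a grid hyperparameter search.

    Features are standardized (train statistics) inside the model; the
    regularization strength (log-grid 1e-4..1e4) and class weighting are
    selected by balanced accuracy on the tuning split; no feature selection
    is performed.  Without a tuning split the defaults (C=1, unweighted) are
    used.  Deterministic given the same budget and data.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    grid = [(C, w) for C in np.logspace(-4, 4, 9) for w in (None, "balanced")]
    grid = grid[:max(1, search_budget)]

    def make(C, w):
        return Pipeline([("scale", StandardScaler()),
                         ("lr", LogisticRegression(C=C, class_weight=w, max_iter=max_iter))])

    best = None
    if tune_features is not None and tune_labels is not None:
        Xt = np.asarray(tune_features, dtype=np.float64)
        yt = np.asarray(tune_labels)
        for C, w in grid:
            m = make(C, w)
            m.fit(X, y)
            score = balanced_accuracy_score(yt, m.predict(Xt))
            if best is None or score > best[0] + 1e-12:
                best = (score, C, w, m)
        score, C, w, model = best
    else:
        C, w = 1.0, None
        model = make(C, w)
        model.fit(X, y)
        score = float("nan")
    return ProbeModel(model=model, C=C, class_weight=w,
                      search_budget=len(grid), tuning_score=float(score))


# ---------------------------------------------------------------------------
# fine-tuning


@dataclass
class TaskModel:
    """Encoder backbone + linear classification head."""

    encoder: Encoder
    head: nn.Linear
    task: str = "site"
    n_classes: int = 2
    meta: dict = field(default_factory=dict)

    def logits(self, patches, train: bool = False) -> np.ndarray:
        feats = self.encoder.features(patches, train=train)
        return self.head.forward(feats, train=train)

    def predict_proba(self, patches) -> np.ndarray:
        return nn.softmax(self.logits(patches, train=False))

    def predict(self, patches) -> np.ndarray:
        return self.logits(patches, train=False).argmax(axis=1)

    def score(self, patches) -> np.ndarray:
        """Scalar risk score: probability of class 1 (binary tasks)."""
        return self.predict_proba(patches)[:, 1]

    def parameters(self) -> List[nn.Param]:
        return self.encoder.backbone.parameters() + self.head.parameters()

    def state_arrays(self) -> List[np.ndarray]:
        return self.encoder.backbone.state_arrays() + [self.head.W.v, self.head.b.v]


@dataclass
class FineTuneConfig:
    epochs: int = 10
    batch: int = 16
    base_lr: float = 0.5
    momentum: float = 0.9
    weight_decay: float = 1e-6
    lars: bool = True           # layer-wise adaptive rates, as in pretraining
    lr_step_epochs: int = 4     # step-wise learning rate decay interval
    lr_gamma: float = 0.3


def fine_tune(
    init: Optional[Checkpoint],
    patches: Sequence[Patch],
    labels: Sequence[int],
    n_classes: int,
    tune_patches: Optional[Sequence[Patch]] = None,
    tune_labels: Optional[Sequence[int]] = None,
    encoder_config: Optional[EncoderConfig] = None,
    policy: Optional[AugmentationPolicy] = None,
    config: FineTuneConfig = FineTuneConfig(),
    task: str = "site",
    rng: Optional[np.random.Generator] = None,
) -> Tuple[TaskModel, pd.DataFrame]:
    """Train all layers with cross-entropy; select the best epoch on tuning data.

    ``init`` may be a foundation checkpoint (transfer), ``None`` with an
    ``encoder_config`` (random initialization), or a checkpoint from a
    previously fine-tuned model (transfer across use cases).
    """
    rng = np.random.default_rng(rng)
    y = np.asarray(labels, dtype=int)
    if y.max() >= n_classes:
        raise ValueError("label exceeds n_classes")
    if init is not None:
        encoder = init.build_encoder()
    else:
        if encoder_config is None:
            raise ValueError("random init requires an encoder_config")
        encoder = Encoder(encoder_config, rng=rng)
    policy = make_finetune_policy() if policy is None else policy
    head = nn.Linear(encoder.config.feature_dim, n_classes, rng=rng)
    model = TaskModel(encoder=encoder, head=head, task=task, n_classes=n_classes)

    opt = nn.SGD(model.parameters(), lr=config.base_lr, momentum=config.momentum,
                 weight_decay=config.weight_decay, lars=config.lars)
    n = len(patches)
    trace = []
    best_score, best_state = -np.inf, None
    for epoch in range(config.epochs):
        lr = nn.step_decay_lr(config.base_lr, epoch, config.lr_step_epochs, config.lr_gamma)
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, config.batch):
            idx = order[s:s + config.batch]
            if len(idx) == 0:
                continue
            aug = [apply_view(patches[i], policy, rng) for i in idx]
            arr = np.stack([p.values for p in aug])[:, None].astype(np.float32)
            feats = model.encoder.backbone.forward(arr, train=True)
            logits = model.head.forward(feats, train=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(f"divergent fine-tuning loss at epoch {epoch}")
            dfeats = model.head.backward(dlogits)
            model.encoder.backbone.backward(dfeats)
            opt.step(lr=lr)
            opt.zero_grad()
            losses.append(loss)
        row = {"epoch": epoch, "loss": float(np.mean(losses)), "lr": lr}
        if tune_patches is not None and tune_labels is not None:
            pred = model.predict(list(tune_patches))
            score = balanced_accuracy_score(np.asarray(tune_labels), pred)
            row["tune_balanced_accuracy"] = float(score)
            if score > best_score:
                best_score = score
                best_state = [a.copy() for a in model.state_arrays()]
        trace.append(row)
    if best_state is not None:
        for dst, src in zip(model.state_arrays(), best_state):
            dst[...] = src
        model.meta["best_tune_balanced_accuracy"] = float(best_score)
    return model, pd.DataFrame(trace)


# ---------------------------------------------------------------------------
# reduced-training-data protocol


def subsample_training(
    labels: Sequence,
    fraction: float,
    rng: Optional[np.random.Generator] = None,
    within: Optional[Sequence[int]] = None,
) -> np.ndarray:
    """Stratified index subset containing ``fraction`` of each class.

    ``within`` restricts sampling to a previous (larger) subset so nested
    chains 10% within 20% within 50% can be built.  Raises if any class
    would drop to zero cases.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(rng)
    y = np.asarray(labels)
    pool = np.arange(len(y)) if within is None else np.asarray(sorted(within))
    if fraction == 1.0:
        return pool
    out = []
    for cls in np.unique(y):
        cls_all = np.flatnonzero(y == cls)
        k = int(round(fraction * len(cls_all)))
        if k == 0:
            raise ValueError(f"class {cls!r} would drop to zero cases at fraction {fraction}")
        cls_pool = pool[np.isin(pool, cls_all)]
        if k > len(cls_pool):
            raise ValueError("nested pool too small for the requested fraction")
        out.append(rng.choice(cls_pool, size=k, replace=False))
    return np.sort(np.concatenate(out))


def nested_subsamples(
    labels: Sequence,
    fractions: Sequence[float] = (0.5, 0.2, 0.1),
    rng: Optional[np.random.Generator] = None,
) -> Dict[float, np.ndarray]:
    """Nested stratified subsets: each smaller fraction is inside the larger."""
    rng = np.random.default_rng(rng)
    out: Dict[float, np.ndarray] = {}
    within = None
    for f in sorted(fractions, reverse=True):
        idx = subsample_training(labels, f, rng=rng, within=within)
        out[f] = idx
        within = idx
    return out
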