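"""Saliency attribution and the gene-expression association screen.

Saliency uses smooth guided back-propagation: the gradient of the predicted
class logit with respect to the input is averaged over several noisy copies
of the input (SmoothGrad), with negative gradients zeroed at every rectifier
during the backward pass (guided back-propagation).

The radiogenomic screen filters a genes x cases expression matrix to genes
expressed above the overall mean, keeps the top 500 by standard deviation,
correlates each with per-case model predictions and selects genes with
|r| > 0.1 for downstream enrichment tools.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import nn
from .adapt import TaskModel
from .metrics import wilcoxon_signed_rank
from .types import Patch

log = logging.getLogger(__name__)


@dataclass
class SaliencyVolume:
    """Voxelwise attribution aligned to the input patch."""

    values: np.ndarray              # absolute attribution, non-negative
    signed: np.ndarray              # signed mean guided gradient
    meta: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("saliency values must be finite")


def smooth_guided_saliency(
    model: TaskModel,
    patch: Patch,
    n_noise: int = 25,
    noise_sd: float = 0.1,
    rng: Optional[np.random.Generator] = None,
) -> SaliencyVolume:
    """Smooth guided back-propagation for the predicted class logit.

    ``noise_sd`` is on the normalized [0, 1] intensity scale (default 10% of
    the dynamic range).  With ``n_noise=1, noise_sd=0`` this reduces to plain
    guided back-propagation.
    """
    if not patch.normalized:
        raise ValueError("saliency expects a normalized patch")
    if n_noise < 1:
        raise ValueError("n_noise must be >= 1")
    rng = np.random.default_rng(rng)
    has_relu = any(isinstance(l, nn.ReLU) for l in model.encoder.backbone.layers) or any(
        isinstance(l, nn.Bottleneck) for l in model.encoder.backbone.layers)
    if not has_relu:
        warnings.warn("model has no rectifier nonlinearities; guided rule is a no-op")

    base = patch.values[None, None].astype(np.float32)
    logits = model.logits([patch], train=False)
    target = int(np.argmax(logits[0]))
    onehot = np.zeros_like(logits)
    onehot[0, target] = 1.0

    acc = np.zeros_like(base, dtype=np.float64)
    for _ in range(n_noise):
        x = base if noise_sd == 0 else (base + rng.normal(0.0, noise_sd, size=base.shape)
                                        ).astype(np.float32)
        feats = model.encoder.backbone.forward(x, train=False)
        model.head.forward(feats, train=False)
        dfeats = model.head.backward(onehot.astype(np.float32), guided=True)
        dx = model.encoder.backbone.backward(dfeats, guided=True)
        acc += dx.astype(np.float64)
    for p in model.parameters():  # discard gradients accumulated along the way
        p.g[...] = 0.0
    signed = (acc / n_noise)[0, 0]
    return SaliencyVolume(
        values=np.abs(signed),
        signed=signed,
        meta={"target_class": target, "n_noise": n_noise, "noise_sd": noise_sd},
    )


# ---------------------------------------------------------------------------
# gene-expression association screen


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """A gene-expression matrix is a genes x cases DataFrame without NaNs."""
    if expr.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    return expr


def filter_genes(expr: pd.DataFrame, top_k: int = 500) -> List[str]:
    """Mean filter then SD ranking.

    Step 1 keeps genes whose per-gene mean strictly exceeds the overall
    matrix mean; step 2 ranks survivors by per-gene standard deviation
    (descending) and keeps at most ``top_k``.
    """
    validate_expression(expr)
    if expr.shape[0] < 1:
        raise ValueError("need at least one gene")
    overall = float(expr.to_numpy().mean())
    gene_means = expr.mean(axis=1)
    survivors = expr.index[gene_means > overall]
    sds = expr.loc[survivors].std(axis=1, ddof=1)
    ranked = sds.sort_values(ascending=False, kind="stable")
    return list(ranked.index[: min(top_k, len(ranked))])


def correlate_predictions(
    preds: Sequence[float],
    expr: pd.DataFrame,
    threshold: float = 0.1,
    absolute: bool = True,
) -> pd.DataFrame:
    """Per-gene Pearson correlation of expression with model predictions.

    Returns a table (gene_id, r, abs_r, selected) where ``selected`` marks
    genes with |r| > threshold (or r > threshold in signed mode).  Constant
    genes are excluded with a log entry.
    """
    preds = np.asarray(preds, dtype=float)
    if preds.size < 3:
        raise ValueError("need at least 3 cases")
    if preds.size != expr.shape[1]:
        raise ValueError("predictions and expression cases are misaligned")
    validate_expression(expr)
    rows = []
    for gene, x in expr.iterrows():
        xv = x.to_numpy(dtype=float)
        if np.std(xv) == 0:
            log.info("gene %s is constant; excluded from the correlation screen", gene)
            continue
        r = float(stats.pearsonr(preds, xv).statistic)
        crit = abs(r) if absolute else r
        rows.append({"gene_id": gene, "r": r, "abs_r": abs(r), "selected": bool(crit > threshold)})
    out = pd.DataFrame(rows, columns=["gene_id", "r", "abs_r", "selected"])
    return out.sort_values("abs_r", ascending=False, kind="stable").reset_index(drop=True)


def compare_correlation_magnitudes(rA: Sequence[float], rB: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p for paired per-gene |r| vectors."""
    rA = np.abs(np.asarray(rA, dtype=float))
    rB = np.abs(np.asarray(rB, dtype=float))
    if rA.shape != rB.shape:
        raise ValueError("gene sets must match")
    return wilcoxon_signed_rank(rA, rB)
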