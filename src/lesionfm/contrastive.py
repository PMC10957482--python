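"""Lesion-centric contrastive pretraining (a modified SimCLR for 3D CT).

Positive pairs are two augmented views of the patch around the same lesion
seed point; negatives come from two sources, both enabled by default:

* the views of *other* lesions in the batch (cross-lesion comparisons —
  for n seeds there are exactly n x 2(n-1) unordered such pairs), and
* one random non-lesion patch per scan, sampled uniformly over windows that
  do not overlap the lesion's own patch window.

The NT-Xent loss for anchor view i with positive partner j is

    -log  exp(cos(z_i, z_j)/tau) / sum_{k in N(i)} exp(cos(z_i, z_k)/tau)

where N(i) contains j, the other lesions' views and the negative-patch
embeddings, and tau defaults to 0.1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import nn
from .augment import AugmentationPolicy, apply_view, make_pretrain_policy
from .encoder import Checkpoint, Encoder, EncoderConfig
from .types import LesionRecord, Patch, SeedPoint, VolumeGrid
from .volumes import extract_patch, normalize_intensity, patch_window


@dataclass(frozen=True)
class LossParams:
    temperature: float = 0.1
    include_cross_views: bool = True
    include_negatives: bool = True

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class PairBatch:
    """2n lesion views (pairs at indices (2i, 2i+1)) plus pooled negatives."""

    lesion_views: List[Patch]
    negative_patches: List[Patch]
    provenance: List[str]

    def __post_init__(self) -> None:
        if len(self.lesion_views) % 2 != 0:
            raise ValueError("lesion_views count must be even (two views per seed)")

    @property
    def n_pairs(self) -> int:
        return len(self.lesion_views) // 2


def pair_bookkeeping(n_pairs: int) -> Dict[str, int]:
    """Enumerate the comparison structure of a batch of ``n_pairs`` seeds.

    Counts are produced by explicit enumeration over view indices, not by a
    formula, so either reading of the comparison count can be asserted.
    """
    seed_of = [i // 2 for i in range(2 * n_pairs)]
    positive = sum(1 for i, j in combinations(range(2 * n_pairs), 2) if seed_of[i] == seed_of[j])
    cross = sum(1 for i, j in combinations(range(2 * n_pairs), 2) if seed_of[i] != seed_of[j])
    return {
        "positive_pairs": positive,
        "cross_lesion_negative_pairs": cross,        # unordered; equals n * 2(n-1)
        "cross_lesion_comparisons_per_anchor": 2 * (n_pairs - 1),
    }


def sample_negative(
    vol: VolumeGrid,
    lesion_seed: SeedPoint,
    edge_voxels: int,
    rng: Optional[np.random.Generator] = None,
    max_tries: int = 1000,
) -> Patch:
    """A random patch whose window has zero overlap with the lesion's window.

    Centers are uniform over the admissible set (rejection sampling).  If no
    admissible center exists the farthest in-volume center is returned with
    a warning.
    """
    rng = np.random.default_rng(rng)
    if not vol.is_isotropic():
        raise ValueError("sample_negative requires an isotropic volume")
    L = edge_voxels
    h, h2 = L // 2, L - L // 2
    shape = np.asarray(vol.shape)
    seed_idx = np.rint(vol.world_to_index(lesion_seed.xyz)).astype(int)
    w_lo, w_hi = patch_window(seed_idx, L)

    lo_c = np.full(3, h)
    hi_c = shape - h2  # inclusive upper bound for centers
    if np.any(hi_c < lo_c):
        warnings.warn("volume smaller than the patch; negative window clipped")
        lo_c = np.minimum(lo_c, hi_c)

    def admissible_exists() -> bool:
        for a in range(3):
            # some center on axis a puts the window fully before/after the lesion
            if w_lo[a] - h2 >= lo_c[a] or w_hi[a] + h <= hi_c[a]:
                return True
        return False

    def disjoint(center: np.ndarray) -> bool:
        lo, hi = patch_window(center, L)
        return bool(np.any((hi <= w_lo) | (lo >= w_hi)))

    if admissible_exists():
        for _ in range(max_tries):
            c = rng.integers(lo_c, hi_c + 1)
            if disjoint(c):
                pos = vol.index_to_world(c)
                return extract_patch(vol, SeedPoint(tuple(pos)), edge_voxels=L)
    warnings.warn("no admissible non-overlapping window; using the farthest in-volume center")
    corners = np.array(np.meshgrid(*[[lo_c[a], hi_c[a]] for a in range(3)])).reshape(3, -1).T
    far = corners[np.argmax(np.linalg.norm(corners - seed_idx, axis=1))]
    return extract_patch(vol, SeedPoint(tuple(vol.index_to_world(far))), edge_voxels=L)


def build_pair_batch(
    records: Sequence[LesionRecord],
    volumes: Sequence[VolumeGrid],
    policy: Optional[AugmentationPolicy] = None,
    rng: Optional[np.random.Generator] = None,
    edge_voxels: int = 24,
) -> PairBatch:
    """Two augmented views per lesion plus one non-lesion negative per scan."""
    if len(records) < 2:
        raise ValueError("need at least 2 lesions for contrastive pairs")
    if len(records) != len(volumes):
        raise ValueError("records and volumes must align")
    rng = np.random.default_rng(rng)
    policy = make_pretrain_policy() if policy is None else policy
    views: List[Patch] = []
    negatives: List[Patch] = []
    provenance: List[str] = []
    for rec, vol in zip(records, volumes):
        base = normalize_intensity(extract_patch(vol, rec.seed, edge_voxels=edge_voxels))
        views.append(apply_view(base, policy, rng))
        views.append(apply_view(base, policy, rng))
        negatives.append(normalize_intensity(
            sample_negative(vol, rec.seed, edge_voxels=edge_voxels, rng=rng)))
        provenance.append(rec.scan_id)
    return PairBatch(lesion_views=views, negative_patches=negatives, provenance=provenance)


# ---------------------------------------------------------------------------
# NT-Xent


def _check_embeddings(z: np.ndarray) -> None:
    norms = np.linalg.norm(z, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("zero-norm embedding")
    if np.any(np.abs(norms - 1.0) > 1e-5):
        raise ValueError("embeddings must be unit-normalized")


def _ntxent_parts(views: np.ndarray, negatives: Optional[np.ndarray],
                  params: LossParams) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Similarity logits, allowed-candidate mask and positive-target mask."""
    n2 = views.shape[0]
    if n2 % 2 != 0:
        raise ValueError("views must come in pairs")
    cand = views if negatives is None or not params.include_negatives else np.vstack([views, negatives])
    sim = views @ cand.T / params.temperature
    m = cand.shape[0]
    allowed = np.zeros((n2, m), dtype=bool)
    target = np.zeros((n2, m), dtype=bool)
    for i in range(n2):
        j = i ^ 1  # partner view of the same seed
        target[i, j] = True
        allowed[i, j] = True
        if params.include_cross_views:
            for k in range(n2):
                if k // 2 != i // 2:
                    allowed[i, k] = True
        if params.include_negatives and m > n2:
            allowed[i, n2:] = True
    return sim, allowed, target


def nt_xent(views: np.ndarray, negatives: Optional[np.ndarray] = None,
            params: LossParams = LossParams()) -> float:
    """Mean NT-Xent loss over all 2n anchor views (embeddings already unit-norm)."""
    views = np.asarray(views, dtype=np.float64)
    _check_embeddings(views)
    if negatives is not None and len(negatives):
        negatives = np.asarray(negatives, dtype=np.float64)
        _check_embeddings(negatives)
    else:
        negatives = None
    sim, allowed, target = _ntxent_parts(views, negatives, params)
    masked = np.where(allowed, sim, -np.inf)
    lse = np.logaddexp.reduce(masked, axis=1)
    pos = sim[target].reshape(views.shape[0])
    return float(np.mean(lse - pos))


def nt_xent_grad(views: np.ndarray, negatives: Optional[np.ndarray],
                 params: LossParams = LossParams()) -> Tuple[float, np.ndarray, np.ndarray]:
    """Loss and gradients w.r.t. the unit view/negative embeddings."""
    views = np.asarray(views, dtype=np.float64)
    _check_embeddings(views)
    has_negs = negatives is not None and len(negatives) > 0 and params.include_negatives
    negs = np.asarray(negatives, dtype=np.float64) if has_negs else None
    if negs is not None:
        _check_embeddings(negs)
    sim, allowed, target = _ntxent_parts(views, negs, params)
    n2 = views.shape[0]
    masked = np.where(allowed, sim, -np.inf)
    mx = masked.max(axis=1, keepdims=True)
    e = np.where(allowed, np.exp(masked - mx), 0.0)
    p = e / e.sum(axis=1, keepdims=True)
    loss = float(np.mean(np.log(e.sum(axis=1)) + mx[:, 0] - sim[target].reshape(n2)))
    dsim = (p - target.astype(float)) / n2
    cand = views if negs is None else np.vstack([views, negs])
    d_anchor = dsim @ cand / params.temperature
    d_cand = dsim.T @ views / params.temperature
    d_views = d_anchor + d_cand[:n2]
    d_negs = d_cand[n2:] if negs is not None else np.zeros((0, views.shape[1]))
    return loss, d_views.astype(np.float32), d_negs.astype(np.float32)


# ---------------------------------------------------------------------------
# pretraining loop


@dataclass
class PretrainConfig:
    epochs: int = 20
    batch_pairs: int = 8
    base_lr: float = 0.5
    momentum: float = 0.9
    weight_decay: float = 1e-6
    warmup_frac: float = 0.2
    lars: bool = True
    accum_steps: int = 1  # gradient accumulation reproduces larger effective batches
    recalibrate_bn: bool = True  # refresh BN statistics on clean patches at the end
    loss: LossParams = field(default_factory=LossParams)


def pretrain(
    records: Sequence[LesionRecord],
    volumes: Sequence[VolumeGrid],
    encoder: Encoder,
    config: PretrainConfig = PretrainConfig(),
    policy: Optional[AugmentationPolicy] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[Checkpoint, pd.DataFrame]:
    """Contrastive pretraining; returns a checkpoint and the per-epoch loss trace."""
    if len(records) < 2:
        raise ValueError("pretraining needs at least 2 scans")
    rng = np.random.default_rng(rng)
    policy = make_pretrain_policy() if policy is None else policy
    edge = encoder.config.input_edge
    n = len(records)
    bp = min(config.batch_pairs, n)
    steps_per_epoch = max(1, n // bp)
    total_steps = max(1, config.epochs * steps_per_epoch // max(1, config.accum_steps))

    opt = nn.SGD(encoder.parameters(), lr=config.base_lr, momentum=config.momentum,
                 weight_decay=config.weight_decay, lars=config.lars)
    trace = []
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        accum = 0
        for s in range(steps_per_epoch):
            idx = order[s * bp:(s + 1) * bp]
            if len(idx) < 2:
                continue
            batch = build_pair_batch([records[i] for i in idx], [volumes[i] for i in idx],
                                     policy=policy, rng=rng, edge_voxels=edge)
            arr = np.stack([p.values for p in batch.lesion_views + batch.negative_patches])[:, None]
            z = encoder.project(arr.astype(np.float32), train=True)
            n2 = 2 * len(idx)
            loss, dv, dn = nt_xent_grad(z[:n2], z[n2:], config.loss)
            if not np.isfinite(loss):
                raise RuntimeError(f"divergent loss at epoch {epoch}, step {s}: {loss}")
            grad_z = np.vstack([dv, dn]) if len(dn) else dv
            encoder.backward_from_embedding_grad(grad_z.astype(np.float32))
            losses.append(loss)
            accum += 1
            if accum >= config.accum_steps:
                lr = nn.warmup_cosine_lr(config.base_lr, step, total_steps, config.warmup_frac)
                opt.step(lr=lr)
                opt.zero_grad()
                accum = 0
                step += 1
        if accum:
            lr = nn.warmup_cosine_lr(config.base_lr, step, total_steps, config.warmup_frac)
            opt.step(lr=lr)
            opt.zero_grad()
            step += 1
        if losses:
            trace.append({"epoch": epoch, "loss": float(np.mean(losses)),
                          "lr": nn.warmup_cosine_lr(config.base_lr, max(0, step - 1),
                                                    total_steps, config.warmup_frac)})
    if config.recalibrate_bn and config.epochs > 0:
        clean = [normalize_intensity(extract_patch(v, r.seed, edge_voxels=edge))
                 for r, v in zip(records, volumes)]
        encoder.recalibrate_bn(clean)
    ckpt = Checkpoint.from_encoder(encoder, kind="pretrained", epochs=config.epochs)
    return ckpt, pd.DataFrame(trace, columns=["epoch", "loss", "lr"])
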