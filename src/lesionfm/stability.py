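"""Test-retest and simulated inter-reader stability of features and predictions.

Test-retest agreement of continuous predictions is quantified with the
intraclass correlation coefficient ICC(2,1) (two-way random effects,
absolute agreement, single measurement), and feature reproducibility with
Spearman correlation and R^2 on flattened feature matrices.  Inter-reader
variability is simulated by perturbing each lesion seed point with
independent per-axis Gaussian offsets (variance 16 voxels^2, i.e. SD 4
voxels, by default) and repeating feature extraction and prediction over
many trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
from scipy import stats

from .types import Patch, SeedPoint, VolumeGrid
from .volumes import extract_patch, normalize_intensity


def icc_agreement(a, b) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    Computed from the two-way ANOVA mean squares of the n x 2 measurement
    table (subjects x repeats).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need two equal-length 1D prediction vectors")
    n = a.size
    if n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    x = np.column_stack([a, b])  # n subjects x k=2 raters
    if np.allclose(x, x.mean()):
        raise ValueError("zero total variance; ICC undefined")
    k = 2
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))


def feature_concordance(F1, F2) -> Dict[str, float]:
    """Spearman rho and R^2 between flattened test/retest feature matrices."""
    F1 = np.asarray(F1, dtype=float).ravel()
    F2 = np.asarray(F2, dtype=float).ravel()
    if F1.shape != F2.shape:
        raise ValueError("feature matrices must have the same shape")
    if np.std(F1) == 0 or np.std(F2) == 0:
        raise ValueError("constant features; correlation undefined")
    rho = stats.spearmanr(F1, F2).statistic
    r = stats.pearsonr(F1, F2).statistic
    return {"spearman_rho": float(rho), "r_squared": float(r ** 2)}


def perturb_seed(
    seed: SeedPoint,
    variance_voxels: float = 16.0,
    rng: Optional[np.random.Generator] = None,
    spacing_mm: float = 1.0,
) -> SeedPoint:
    """Seed plus independent per-axis normal offsets (variance in voxel^2)."""
    if variance_voxels < 0:
        raise ValueError("variance must be non-negative")
    rng = np.random.default_rng(rng)
    if variance_voxels == 0:
        return seed
    offset = rng.normal(0.0, np.sqrt(variance_voxels), size=3) * spacing_mm
    return SeedPoint(tuple(seed.xyz + offset))


@dataclass
class PerturbationStudy:
    """Raw trials and summaries of a seed-perturbation experiment."""

    n_trials: int
    variance_voxels: float
    offsets_mm: np.ndarray                 # (n_trials, n_cases, 3)
    per_case_mse: np.ndarray               # (n_trials, n_cases) vs unperturbed reference
    per_case_mse_vs_mean: np.ndarray       # (n_trials, n_cases) vs per-case trial mean
    predictions: Optional[np.ndarray] = None   # (n_trials, n_cases)
    reference_predictions: Optional[np.ndarray] = None
    per_trial_auc: Optional[np.ndarray] = None
    summary: Dict[str, float] = field(default_factory=dict)


def perturbation_study(
    feature_fn: Callable[[Sequence[Patch]], np.ndarray],
    volumes: Sequence[VolumeGrid],
    seeds: Sequence[SeedPoint],
    n_trials: int = 50,
    variance_voxels: float = 16.0,
    edge_voxels: int = 24,
    predict_fn: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    labels: Optional[Sequence[int]] = None,
    standardize_features: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> PerturbationStudy:
    """Repeat feature extraction/prediction under random seed perturbations.

    For each trial every seed is perturbed, patches are re-extracted and
    features recomputed; the study reports per-case feature MSE against the
    unperturbed reference (and against the per-case trial mean), the
    mean/variance of the prediction sets, and a per-trial discrimination AUC
    when binary labels and a prediction head are provided.

    ``standardize_features`` divides every feature by its across-case
    standard deviation in the unperturbed reference, making MSE comparable
    between models whose feature scales differ.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(rng)
    n_cases = len(volumes)

    def patches_at(seed_list):
        return [normalize_intensity(extract_patch(v, s, edge_voxels=edge_voxels))
                for v, s in zip(volumes, seed_list)]

    ref_feats = np.asarray(feature_fn(patches_at(seeds)), dtype=float)
    ref_preds = np.asarray(predict_fn(ref_feats), dtype=float) if predict_fn else None
    scale = None
    if standardize_features:
        scale = ref_feats.std(axis=0)
        scale[scale == 0] = 1.0
        ref_feats = ref_feats / scale

    feats_all = np.empty((n_trials,) + ref_feats.shape)
    offsets = np.empty((n_trials, n_cases, 3))
    preds = np.empty((n_trials, n_cases)) if predict_fn else None
    spacing = volumes[0].spacing[0] if n_cases else 1.0
    for t in range(n_trials):
        pseeds = [perturb_seed(s, variance_voxels, rng, spacing_mm=spacing) for s in seeds]
        offsets[t] = np.stack([p.xyz - s.xyz for p, s in zip(pseeds, seeds)])
        ft = np.asarray(feature_fn(patches_at(pseeds)), dtype=float)
        if predict_fn:
            preds[t] = np.asarray(predict_fn(ft), dtype=float)
        feats_all[t] = ft if scale is None else ft / scale

    per_case_mse = ((feats_all - ref_feats[None]) ** 2).mean(axis=2)
    trial_mean = feats_all.mean(axis=0, keepdims=True)
    per_case_mse_vs_mean = ((feats_all - trial_mean) ** 2).mean(axis=2)

    per_trial_auc = None
    if predict_fn and labels is not None:
        from .metrics import auc_roc

        y = np.asarray(labels)
        per_trial_auc = np.array([auc_roc(y, preds[t]) for t in range(n_trials)])

    summary = {
        "median_feature_mse": float(np.median(per_case_mse)),
        "mean_feature_mse": float(np.mean(per_case_mse)),
    }
    if preds is not None:
        summary["prediction_mean"] = float(preds.mean())
        summary["prediction_variance_across_trials"] = float(preds.var(axis=0).mean())
    if per_trial_auc is not None:
        summary["auc_mean"] = float(per_trial_auc.mean())
        summary["auc_variance"] = float(per_trial_auc.var())
    return PerturbationStudy(
        n_trials=n_trials,
        variance_voxels=variance_voxels,
        offsets_mm=offsets,
        per_case_mse=per_case_mse,
        per_case_mse_vs_mean=per_case_mse_vs_mean,
        predictions=preds,
        reference_predictions=ref_preds,
        per_trial_auc=per_trial_auc,
        summary=summary,
    )
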