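"""Desk-scale benchmark experiments on synthetic cohorts.

These functions bundle the package's end-to-end evaluations at a size that
runs on one CPU in minutes: the pretrained-vs-random linear-probe
comparison with the reduced-training-data protocol, the seed-perturbation
stability comparison, a test-retest study, a survival adaptation of the
frozen features, and the radiogenomic screen.  Every function is a pure
function of its seed.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .adapt import (extract_features, fine_tune, fit_linear_probe, subsample_training,
                    FineTuneConfig)
from .augment import make_finetune_policy
from .contrastive import PretrainConfig, pretrain
from .encoder import Encoder, EncoderConfig
from .metrics import auc_roc, balanced_accuracy, cox_univariate, km_logrank
from .pipeline import cohort_patches, split_indices
from .stability import feature_concordance, icc_agreement, perturbation_study
from .synthetic import (SyntheticCohort, make_classification_cohort, make_expression,
                        make_retest_pair, make_survival_cohort)
from .volumes import extract_patch, normalize_intensity

PATCH_EDGE = 24


def _spawn(seed: int, n: int) -> List[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def probe_benchmark(
    seed: int,
    n_cases: int = 240,
    n_classes: int = 3,
    epochs: int = 20,
    fractions: Sequence[float] = (1.0, 0.1),
    include_scratch: bool = True,
    n_subsample_draws: int = 3,
    cohort: Optional[SyntheticCohort] = None,
) -> Dict:
    """Pretrained-features vs random-encoder probes, plus the data-efficiency
    protocol (probe at reduced training fractions, from-scratch supervised
    fine-tuning at the same fractions).

    Returns a dict with balanced accuracies, the probe gap, relative drops,
    and the trained/random encoders for follow-up studies.
    """
    r_cohort, r_split, r_enc, r_pre, r_sub, r_ft = _spawn(seed, 6)
    if cohort is None:
        cohort = make_classification_cohort(n_cases, K=n_classes, rng=r_cohort)
    labels = np.array([rec.site_class for rec in cohort.lesions])
    patches = cohort_patches(cohort, PATCH_EDGE)
    train, tune, test = split_indices(labels, r_split)

    enc_seed = int(r_enc.integers(0, 2**31 - 1))
    random_encoder = Encoder(EncoderConfig(), rng=np.random.default_rng(enc_seed))
    random_encoder.recalibrate_bn([patches[i] for i in train])
    encoder = Encoder(EncoderConfig(), rng=np.random.default_rng(enc_seed))
    ckpt, trace = pretrain([cohort.lesions[i] for i in train],
                           [cohort.volumes[i] for i in train], encoder,
                           PretrainConfig(epochs=epochs), rng=r_pre)

    feats_pre = extract_features(encoder, patches)
    feats_rand = extract_features(random_encoder, patches)

    def probe_ba(feats: pd.DataFrame, train_idx: np.ndarray) -> float:
        probe = fit_linear_probe(feats.iloc[train_idx], labels[train_idx],
                                 feats.iloc[tune], labels[tune])
        return balanced_accuracy(labels[test], probe.predict_proba(feats.iloc[test]))

    out: Dict = {
        "seed": seed,
        "n_cases": n_cases,
        "final_pretrain_loss": float(trace.loss.iloc[-1]) if len(trace) else float("nan"),
        "probe_pretrained": {},
        "probe_random": {},
        "scratch_finetune": {},
    }
    # reduced fractions are averaged over independent stratified draws to
    # keep the data-efficiency point estimates from being dominated by the
    # luck of a single tiny subset
    subsets = {1.0: [np.asarray(train)]}
    for frac in fractions:
        if frac < 1.0:
            subsets[frac] = [np.asarray(train)[subsample_training(labels[train], frac, rng=r_sub)]
                             for _ in range(n_subsample_draws)]
    for frac in fractions:
        out["probe_pretrained"][frac] = float(np.mean(
            [probe_ba(feats_pre, idx) for idx in subsets[frac]]))
    out["probe_random"][1.0] = probe_ba(feats_rand, subsets[1.0][0])
    out["probe_gap_full"] = out["probe_pretrained"][1.0] - out["probe_random"][1.0]

    if include_scratch:
        ft_policy = make_finetune_policy(translate_voxels=4)  # scaled to the 24-voxel patch
        for frac in fractions:
            bas = []
            for idx in subsets[frac]:
                ft_seed = int(r_ft.integers(0, 2**31 - 1))
                model, _ = fine_tune(None, [patches[i] for i in idx], labels[idx],
                                     n_classes,
                                     tune_patches=[patches[i] for i in tune],
                                     tune_labels=labels[tune],
                                     encoder_config=EncoderConfig(), policy=ft_policy,
                                     config=FineTuneConfig(epochs=12),
                                     rng=np.random.default_rng(ft_seed))
                pred = model.predict_proba([patches[i] for i in test])
                bas.append(balanced_accuracy(labels[test], pred))
            out["scratch_finetune"][frac] = float(np.mean(bas))

    if 0.1 in out["probe_pretrained"]:
        full, ten = out["probe_pretrained"][1.0], out["probe_pretrained"][0.1]
        out["rel_drop_probe_pretrained"] = (full - ten) / max(full, 1e-9)
    if include_scratch and 0.1 in out["scratch_finetune"]:
        full, ten = out["scratch_finetune"][1.0], out["scratch_finetune"][0.1]
        out["rel_drop_scratch"] = (full - ten) / max(full, 1e-9)

    out["_encoder"] = encoder
    out["_random_encoder"] = random_encoder
    out["_cohort"] = cohort
    return out


def perturbation_benchmark(
    encoder: Encoder,
    random_encoder: Encoder,
    cohort: SyntheticCohort,
    n_cases: int = 24,
    n_trials: int = 10,
    variances: Sequence[float] = (4.0, 16.0, 32.0),
    seed: int = 0,
) -> Dict:
    """Seed-perturbation stability: MSE monotonicity in the perturbation
    variance (trained encoder) and the trained-vs-random comparison at the
    default variance, on standardized features."""
    vols = cohort.volumes[:n_cases]
    seeds = [r.seed for r in cohort.lesions[:n_cases]]
    out: Dict = {"median_mse_by_variance": {}}
    for var in variances:
        study = perturbation_study(lambda ps: encoder.features(ps), vols, seeds,
                                   n_trials=n_trials, variance_voxels=var,
                                   edge_voxels=PATCH_EDGE, standardize_features=True,
                                   rng=np.random.default_rng(seed))
        out["median_mse_by_variance"][var] = study.summary["median_feature_mse"]
    study_r = perturbation_study(lambda ps: random_encoder.features(ps), vols, seeds,
                                 n_trials=n_trials, variance_voxels=16.0,
                                 edge_voxels=PATCH_EDGE, standardize_features=True,
                                 rng=np.random.default_rng(seed))
    out["median_mse_pretrained"] = out["median_mse_by_variance"][16.0]
    out["median_mse_random"] = study_r.summary["median_feature_mse"]
    return out


def retest_benchmark(encoder: Encoder, cohort: SyntheticCohort, n_cases: int = 26,
                     seed: int = 0) -> Dict:
    """Test-retest agreement of frozen features and probe-style predictions
    on paired scans acquired minutes apart (n = 26 by default)."""
    rng = np.random.default_rng(seed)
    vols = cohort.volumes[:n_cases]
    recs = cohort.lesions[:n_cases]
    retest = [make_retest_pair(v, rng=rng) for v in vols]
    p1 = [normalize_intensity(extract_patch(v, r.seed, edge_voxels=PATCH_EDGE))
          for v, r in zip(vols, recs)]
    p2 = [normalize_intensity(extract_patch(v, r.seed, edge_voxels=PATCH_EDGE))
          for v, r in zip(retest, recs)]
    F1 = encoder.features(p1)
    F2 = encoder.features(p2)
    conc = feature_concordance(F1, F2)
    # model predictions as the repeated measurement: a probe fit on the test
    # scans, its class-0 probability evaluated on both scans of each pair
    labels = np.array([r.site_class for r in recs])
    probe = fit_linear_probe(F1, labels)
    pred1 = probe.predict_proba(F1)[:, 0]
    pred2 = probe.predict_proba(F2)[:, 0]
    return {
        "icc": icc_agreement(pred1, pred2),
        "feature_spearman": conc["spearman_rho"],
        "feature_r2": conc["r_squared"],
        "n": n_cases,
    }


def survival_benchmark(encoder: Encoder, seed: int, n_train: int = 160,
                       n_test: int = 120) -> Dict:
    """Prognostication from frozen features: a probe on the 2-year endpoint,
    ranked-score AUC on an independent test cohort, Kaplan-Meier risk
    stratification at the tuning-median threshold and a univariate Cox fit."""
    r_train, r_test, r_fit = _spawn(seed, 3)
    train_cohort = make_survival_cohort(n_train, rng=r_train)
    test_cohort = make_survival_cohort(n_test, rng=r_test)

    def featurize(cohort):
        patches = cohort_patches(cohort, PATCH_EDGE)
        return extract_features(encoder, patches)

    F_tr = featurize(train_cohort)
    F_te = featurize(test_cohort)
    lab_tr = np.array([r.label_2yr for r in train_cohort.lesions], dtype=object)
    keep = np.array([l is not None for l in lab_tr])
    idx = np.flatnonzero(keep)
    split = int(0.75 * len(idx))
    tr_idx, tu_idx = idx[:split], idx[split:]
    y_tr = lab_tr[tr_idx].astype(int)
    y_tu = lab_tr[tu_idx].astype(int)
    probe = fit_linear_probe(F_tr.iloc[tr_idx], y_tr, F_tr.iloc[tu_idx], y_tu)

    # risk score = probability of death within 2 years
    risk_te = 1.0 - probe.predict_proba(F_te)[:, 1]
    risk_tu = 1.0 - probe.predict_proba(F_tr.iloc[tu_idx])[:, 1]
    lab_te = np.array([r.label_2yr for r in test_cohort.lesions], dtype=object)
    te_keep = np.array([l is not None for l in lab_te])
    auc = auc_roc(1 - lab_te[te_keep].astype(int), risk_te[te_keep])

    times = np.array([r.time_days for r in test_cohort.lesions])
    events = np.array([r.event for r in test_cohort.lesions])
    km = km_logrank(risk_te, risk_tu, times, events)
    group = (risk_te > km["threshold"]).astype(int)
    cox = cox_univariate(group, times, events)
    return {
        "auc_2yr_death": auc,
        "logrank_p": km["p_value"],
        "cox_hr_high_vs_low": cox["hr"],
        "n_test": int(n_test),
    }


def gene_screen_benchmark(seed: int, n_cases: int = 130, G: int = 1000,
                          g_informative: int = 50, r_target: float = 0.6) -> Dict:
    """Recovery of phenotype-linked genes by the |r| > 0.1 screen."""
    from .interpret import correlate_predictions, filter_genes

    rng = np.random.default_rng(seed)
    pheno = rng.normal(size=n_cases)
    expr, info = make_expression(pheno, G=G, g_informative=g_informative,
                                 r_target=r_target, rng=rng)
    table = correlate_predictions(pheno, expr).set_index("gene_id")
    recovery = float(table.loc[info, "selected"].mean())
    noise_rate = float(table.drop(index=info)["selected"].mean())
    kept = filter_genes(expr, top_k=500)
    return {
        "informative_recovery": recovery,
        "noise_selection_rate": noise_rate,
        "n_filtered": len(kept),
        "n_cases": n_cases,
    }
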