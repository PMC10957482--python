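"""Performance metrics and statistical inference for model evaluation.

Classification is scored with balanced accuracy (mean per-class recall),
macro-averaged average precision (mAP) and AUC-ROC; uncertainty comes from
case-level bootstrap percentile intervals, and model pairs are compared with
label-permutation tests that refit both pipelines per permutation.  Survival
stratification uses Kaplan-Meier curves split at a tuning-set score
threshold, the two-group log-rank test and a univariate Cox model.
"""

from __future__ import annotations

import logging
import warnings
from typing import Callable, Dict, Optional, Sequence

import numpy as np
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy import stats
from sklearn.metrics import average_precision_score, balanced_accuracy_score

from .types import MetricResult

log = logging.getLogger(__name__)


def _decide(y_prob: np.ndarray, threshold: float) -> np.ndarray:
    """Class decisions: threshold rule for binary scores, argmax otherwise."""
    y_prob = np.asarray(y_prob)
    if y_prob.ndim == 1 or y_prob.shape[1] == 1:
        return (y_prob.reshape(-1) >= threshold).astype(int)
    if y_prob.shape[1] == 2:
        return (y_prob[:, 1] >= threshold).astype(int)
    return y_prob.argmax(axis=1)


def balanced_accuracy(y_true, y_prob, threshold: float = 0.5) -> float:
    """Mean per-class recall at the decision rule (0.5 threshold when binary)."""
    y_true = np.asarray(y_true)
    classes = np.unique(y_true)
    if classes.size < 2:
        raise ValueError("balanced accuracy needs at least two observed classes")
    return float(balanced_accuracy_score(y_true, _decide(y_prob, threshold)))


def mean_average_precision(y_true, y_prob) -> float:
    """One-vs-rest average precision per class, macro-averaged."""
    y_true = np.asarray(y_true)
    y_prob = np.asarray(y_prob)
    if y_prob.ndim == 1:
        y_prob = np.column_stack([1 - y_prob, y_prob])
    classes = np.arange(y_prob.shape[1])
    aps = []
    for k in classes:
        pos = (y_true == k).astype(int)
        if pos.sum() == 0:
            warnings.warn(f"class {k} has no positives; excluded from mAP")
            continue
        aps.append(average_precision_score(pos, y_prob[:, k]))
    if not aps:
        raise ValueError("no class with positives")
    return float(np.mean(aps))


def auc_roc(y_true, scores) -> float:
    """Probability that a random positive outranks a random negative.

    Computed as the normalized Mann-Whitney U statistic from midranks, so
    ties count half; identical to the trapezoidal ROC area.
    """
    y_true = np.asarray(y_true)
    classes = np.unique(y_true)
    if classes.size != 2:
        raise ValueError("AUC requires both classes present")
    pos = y_true == classes.max()
    n1 = int(pos.sum())
    n0 = len(y_true) - n1
    ranks = stats.rankdata(np.asarray(scores, dtype=float))
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def bootstrap_ci(
    metric_fn: Callable[[np.ndarray, np.ndarray], float],
    y_true,
    scores,
    B: int = 1000,
    level: float = 0.95,
    rng: Optional[np.random.Generator] = None,
    name: str = "metric",
    seed_label: Optional[int] = None,
) -> MetricResult:
    """Percentile bootstrap CI over case resamples.

    Resamples on which the metric is undefined (e.g. a missing class) are
    redrawn and logged; if more than 20% of replicates fail the interval is
    deemed unreliable and an error is raised.
    """
    rng = np.random.default_rng(rng)
    y_true = np.asarray(y_true)
    scores = np.asarray(scores)
    n = len(y_true)
    if n < 10:
        raise ValueError("bootstrap needs at least 10 cases")
    estimate = float(metric_fn(y_true, scores))
    reps = np.empty(B)
    attempts = failures = b = 0
    while b < B:
        attempts += 1
        idx = rng.integers(0, n, size=n)
        try:
            reps[b] = metric_fn(y_true[idx], scores[idx])
            b += 1
        except ValueError:
            failures += 1
        if attempts >= 50 and failures > 0.2 * attempts:
            raise ValueError("metric undefined on more than 20% of bootstrap replicates")
    if failures:
        log.info("bootstrap redrew %d degenerate resamples", failures)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(reps, [alpha, 1 - alpha])
    return MetricResult(name=name, estimate=estimate,
                        ci_low=float(min(lo, estimate)), ci_high=float(max(hi, estimate)),
                        n_resamples=B, seed=seed_label, level=level)


def permutation_compare(
    pipeline_a: Callable,
    pipeline_b: Callable,
    X_train,
    y_train,
    X_test,
    y_test,
    metric_fn: Callable[[np.ndarray, np.ndarray], float],
    n_perm: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> Dict[str, float]:
    """Two-sided refit permutation test for a metric difference.

    A pipeline is a callable ``(X_train, y_train, X_test) -> scores``.  The
    null distribution of the difference is built by permuting the *training*
    labels and refitting both pipelines; the p-value uses add-one smoothing,
    so p >= 1/(n_perm + 1).
    """
    rng = np.random.default_rng(rng)
    if n_perm < 20:
        warnings.warn("n_perm < 20 gives very coarse p-value resolution")
    y_train = np.asarray(y_train)
    y_test = np.asarray(y_test)
    delta_obs = metric_fn(y_test, pipeline_a(X_train, y_train, X_test)) - metric_fn(
        y_test, pipeline_b(X_train, y_train, X_test))
    count = 0
    for _ in range(n_perm):
        yp = rng.permutation(y_train)
        d = metric_fn(y_test, pipeline_a(X_train, yp, X_test)) - metric_fn(
            y_test, pipeline_b(X_train, yp, X_test))
        if abs(d) >= abs(delta_obs) - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return {"delta_obs": float(delta_obs), "p_value": float(p), "n_perm": n_perm}


def km_logrank(
    scores,
    tuning_scores,
    times,
    events,
    threshold_quantile: float = 0.5,
) -> Dict:
    """Kaplan-Meier risk stratification with the group threshold fixed on
    tuning-set scores (median by default) and a two-group log-rank test."""
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    threshold = float(np.quantile(np.asarray(tuning_scores, dtype=float), threshold_quantile))
    high = scores > threshold
    if high.all() or (~high).all():
        raise ValueError("threshold yields an empty risk group")
    if min(high.sum(), (~high).sum()) < 5:
        warnings.warn("a risk group has fewer than 5 cases")
    curves = {}
    for label, sel in (("high", high), ("low", ~high)):
        km = KaplanMeierFitter(label=label)
        km.fit(times[sel], events[sel])
        ci = km.confidence_interval_survival_function_
        curves[label] = {
            "timeline": km.survival_function_.index.to_numpy(),
            "survival": km.survival_function_.iloc[:, 0].to_numpy(),
            "ci_low": ci.iloc[:, 0].to_numpy(),
            "ci_high": ci.iloc[:, 1].to_numpy(),
            "n": int(sel.sum()),
        }
    res = logrank_test(times[high], times[~high], events[high], events[~high])
    return {
        "threshold": threshold,
        "curves": curves,
        "statistic": float(res.test_statistic),
        "p_value": float(res.p_value),
    }


def km_logrank_multigroup(groups, times, events) -> Dict[str, float]:
    """k-sample log-rank test (reduces to the two-sample test for two groups)."""
    res = multivariate_logrank_test(np.asarray(times, float), np.asarray(groups),
                                    np.asarray(events, int))
    return {"statistic": float(res.test_statistic), "p_value": float(res.p_value)}


def cox_univariate(group, times, events) -> Dict[str, float]:
    """Univariate Cox model with a binary group covariate (Efron ties)."""
    import pandas as pd

    group = np.asarray(group, dtype=int)
    events = np.asarray(events, dtype=int)
    if np.unique(group).size != 2:
        raise ValueError("need both groups present")
    if events.sum() == 0:
        raise ValueError("no events observed")
    df = pd.DataFrame({"group": group, "time": np.asarray(times, float), "event": events})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    s = cph.summary.loc["group"]
    return {
        "hr": float(s["exp(coef)"]),
        "log_hr": float(s["coef"]),
        "ci_low": float(s["exp(coef) lower 95%"]),
        "ci_high": float(s["exp(coef) upper 95%"]),
        "p_value": float(s["p"]),
    }


def wilcoxon_signed_rank(x, y, two_sided: bool = True) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Exact null distribution for n <= 25 without ties; normal approximation
    with continuity/tie correction otherwise.  All-zero differences are a
    degenerate input and raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    if np.all(d == 0):
        raise ValueError("all paired differences are zero")
    n_nonzero = int(np.count_nonzero(d))
    has_ties = len(np.unique(np.abs(d[d != 0]))) < n_nonzero
    method = "exact" if (n_nonzero <= 25 and not has_ties) else "asymptotic"
    res = stats.wilcoxon(x, y, alternative="two-sided" if two_sided else "greater",
                         method=method, correction=(method == "asymptotic"))
    return float(res.pvalue)
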