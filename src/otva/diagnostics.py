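"""Diagnostic-accuracy machinery: ROC curves, AUC with confidence intervals,
Youden-optimal cutoffs, confusion-matrix metrics, reconstruction of confusion
matrices from published summary statistics, and two-group comparisons from
summary statistics.

Orientation: RVOT is the positive class everywhere. A criterion whose high
side predicts LVOT can either be evaluated as-is (its RVOT-positive AUC then
falls below 0.5) or through ``direction=GE_PREDICTS_LVOT``, which evaluates
the rule family "value <= t predicts RVOT" and complements the AUC.

The AUC estimator is the Mann-Whitney U statistic with midrank tie handling,
which is exactly the trapezoidal area under the empirical ROC curve. The
default confidence interval is DeLong's; a stratified percentile bootstrap
is available as a cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .classification import CriterionRule, classify
from .core_types import (
    Call,
    DiagnosticMetrics,
    Direction,
    Origin,
    PatientRecord,
    ROCResult,
)

__all__ = [
    "SummaryStats", "roc_curve", "auc_mann_whitney", "youden_cutoff",
    "auc_ci", "metrics_from_calls", "confusion_from_summary",
    "two_group_test_from_summary", "evaluate_cohort",
]


@dataclass(frozen=True)
class SummaryStats:
    """Mean +/- SD of one group of size n, as printed in a summary table."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")


def _as_binary(labels: Sequence) -> np.ndarray:
    """RVOT -> 1, LVOT -> 0; anything else is rejected."""
    out = np.empty(len(labels), dtype=float)
    for i, lab in enumerate(labels):
        val = lab.value if isinstance(lab, Origin) else str(lab)
        if val == Origin.RVOT.value:
            out[i] = 1.0
        elif val == Origin.LVOT.value:
            out[i] = 0.0
        else:
            raise ValueError(f"label must be RVOT or LVOT, got {lab!r}")
    return out


def _check_two_class(y: np.ndarray) -> None:
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes (RVOT and LVOT) must be present")


def auc_mann_whitney(values: Sequence[float], labels: Sequence) -> float:
    """AUC as the Mann-Whitney probability: (concordant + 0.5*tied) pairs
    over n_pos*n_neg, positive class RVOT, higher value = more RVOT-like.

    Signed-infinite sentinel values are ranked like any extreme value.
    """
    v = np.asarray(values, dtype=float)
    if np.isnan(v).any():
        raise ValueError("values must be non-missing (drop NaN before calling)")
    y = _as_binary(labels)
    _check_two_class(y)
    pos, neg = v[y == 1.0], v[y == 0.0]
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u / (len(pos) * len(neg)))


def roc_curve(
    values: Sequence[float],
    labels: Sequence,
    direction: Direction = Direction.GE_PREDICTS_RVOT,
) -> ROCResult:
    """Empirical ROC curve with RVOT as the positive class.

    Thresholds run from the (0, 0) corner (no positives called) to (1, 1);
    point i applies the rule "score >= thresholds[i] predicts RVOT" (or
    "<=" in original units when ``direction`` is GE_PREDICTS_LVOT, in which
    case thresholds are reported on the original scale). The AUC is the
    trapezoidal area, identical to :func:`auc_mann_whitney` on the oriented
    scores. ``optimal_cutoff`` maximizes Youden's J with the midpoint
    convention (see :func:`youden_cutoff`).
    """
    v = np.asarray(values, dtype=float)
    if np.isnan(v).any():
        raise ValueError("values must be non-missing (drop NaN before calling)")
    y = _as_binary(labels)
    _check_two_class(y)
    score = v if direction is Direction.GE_PREDICTS_RVOT else -v

    uniq = np.unique(score)  # ascending
    desc = uniq[::-1]
    thresholds = np.concatenate(([np.inf], desc))
    n_pos = y.sum()
    n_neg = len(y) - n_pos
    tpr = np.empty(len(thresholds))
    fpr = np.empty(len(thresholds))
    for i, t in enumerate(thresholds):
        called = score >= t
        tpr[i] = (called & (y == 1.0)).sum() / n_pos
        fpr[i] = (called & (y == 0.0)).sum() / n_neg
    auc = float(np.trapezoid(tpr, fpr))

    # Youden-optimal threshold: max(TPR - FPR); ties -> higher specificity
    # (lower FPR), then lower threshold. Returned with midpoint convention.
    j = tpr - fpr
    degenerate = bool(np.all(j <= 1e-12))
    order = sorted(
        range(len(thresholds)),
        key=lambda i: (-j[i], fpr[i], thresholds[i]),
    )
    best = order[0]
    if degenerate:
        cutoff_score = float(uniq[0])  # lowest observed threshold, flagged
    else:
        t_best = thresholds[best]
        below = uniq[uniq < t_best]
        cutoff_score = float((below[-1] + t_best) / 2.0) if len(below) else float(t_best)

    if direction is Direction.GE_PREDICTS_LVOT:
        thresholds = -thresholds
        cutoff = -cutoff_score
    else:
        cutoff = cutoff_score

    return ROCResult(
        thresholds=thresholds.tolist(),
        tpr=tpr.tolist(),
        fpr=fpr.tolist(),
        auc=auc,
        optimal_cutoff=cutoff,
        direction=direction,
        degenerate=degenerate,
    )


def youden_cutoff(roc: ROCResult) -> float:
    """Youden-optimal cutoff of an ROC result (midpoint convention)."""
    if roc.optimal_cutoff is None:
        raise ValueError("ROC result carries no optimal cutoff")
    return roc.optimal_cutoff


# --------------------------------------------------------------------------
# AUC confidence intervals
# --------------------------------------------------------------------------

def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> Tuple[float, float]:
    """DeLong AUC and variance via midrank structural components."""
    m, n = len(pos), len(neg)
    all_scores = np.concatenate([pos, neg])
    r_all = stats.rankdata(all_scores)
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def auc_ci(
    values: Sequence[float],
    labels: Sequence,
    method: str = "delong",
    level: float = 0.95,
    seed: Optional[int] = None,
    n_boot: int = 2000,
) -> Tuple[float, float]:
    """Confidence interval for the Mann-Whitney AUC, clipped to [0, 1].

    ``method="delong"`` uses the DeLong variance with a normal interval;
    ``method="bootstrap"`` uses a stratified percentile bootstrap (resampling
    within each class; ``seed`` required).
    """
    v = np.asarray(values, dtype=float)
    y = _as_binary(labels)
    _check_two_class(y)
    pos, neg = v[y == 1.0], v[y == 0.0]
    alpha = 1.0 - level
    if method == "delong":
        auc, var = _delong_variance(pos, neg)
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        half = z * math.sqrt(max(var, 0.0))
        return (max(0.0, auc - half), min(1.0, auc + half))
    if method == "bootstrap":
        if seed is None:
            raise ValueError("bootstrap CI requires a seed")
        rng = np.random.default_rng(seed)
        aucs = np.empty(n_boot)
        for b in range(n_boot):
            p = pos[rng.integers(0, len(pos), len(pos))]
            q = neg[rng.integers(0, len(neg), len(neg))]
            u = stats.mannwhitneyu(p, q, alternative="two-sided").statistic
            aucs[b] = u / (len(p) * len(q))
        low, high = np.quantile(aucs, [alpha / 2.0, 1.0 - alpha / 2.0])
        return (max(0.0, float(low)), min(1.0, float(high)))
    raise ValueError(f"unknown CI method {method!r}")


# --------------------------------------------------------------------------
# Confusion-matrix metrics
# --------------------------------------------------------------------------

def metrics_from_calls(calls: Sequence, truths: Sequence) -> DiagnosticMetrics:
    """Confusion counts from per-patient calls against confirmed origins.

    INDETERMINATE calls are excluded and counted in ``n_indeterminate``.
    """
    if len(calls) != len(truths):
        raise ValueError("calls and truths must be aligned")
    if len(calls) == 0:
        raise ValueError("no calls supplied")
    tp = fp = tn = fn = skipped = 0
    for call, truth in zip(calls, truths):
        c = call.value if isinstance(call, Call) else str(call)
        t = truth.value if isinstance(truth, Origin) else str(truth)
        if c == Call.INDETERMINATE.value:
            skipped += 1
            continue
        if t == Origin.RVOT.value:
            tp += c == Call.RVOT.value
            fn += c == Call.LVOT.value
        elif t == Origin.LVOT.value:
            fp += c == Call.RVOT.value
            tn += c == Call.LVOT.value
        else:
            raise ValueError(f"truth label must be RVOT or LVOT, got {truth!r}")
    if tp + fp + tn + fn == 0:
        raise ValueError("no usable (determinate) calls")
    return DiagnosticMetrics(tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn),
                             n_indeterminate=skipped)


def confusion_from_summary(
    sens: float, spec: float, n_pos: int, n_neg: int
) -> DiagnosticMetrics:
    """Reconstruct the confusion matrix behind published sensitivity and
    specificity at known group sizes (positive class RVOT).

    tp = round(sens * n_pos), tn = round(spec * n_neg); PPV/NPV/accuracy are
    then recomputed from the integer counts.
    """
    if not (0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0):
        raise ValueError("sens and spec must lie in [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("group sizes must be >= 1")
    tp = int(math.floor(sens * n_pos + 0.5))
    tn = int(math.floor(spec * n_neg + 0.5))
    return DiagnosticMetrics(tp=tp, fp=n_neg - tn, tn=tn, fn=n_pos - tp)


def two_group_test_from_summary(
    a: SummaryStats, b: SummaryStats, variant: str = "student"
) -> Tuple[float, float, float]:
    """Two-sided two-sample t-test from summary statistics.

    ``variant="student"`` pools variances (df = n_a + n_b - 2);
    ``variant="welch"`` uses the Satterthwaite approximation.
    Returns (t, df, p).
    """
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    equal_var = variant == "student"
    res = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=equal_var
    )
    if equal_var:
        df = a.n + b.n - 2
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return float(res.statistic), float(df), float(res.pvalue)


# --------------------------------------------------------------------------
# Full cohort evaluation
# --------------------------------------------------------------------------

def _finite_summary(x: np.ndarray) -> Tuple[Optional[float], Optional[float], int]:
    fin = x[np.isfinite(x)]
    if len(fin) == 0:
        return None, None, 0
    sd = float(fin.std(ddof=1)) if len(fin) > 1 else 0.0
    return float(fin.mean()), sd, len(fin)


def evaluate_cohort(
    cohort: Iterable[PatientRecord],
    config=None,
    ci_method: str = "delong",
    seed: Optional[int] = None,
) -> dict:
    """Full diagnostic-accuracy report for a labeled cohort.

    One entry per enabled criterion: group summaries (mean +/- SD over finite
    values, Student t-test p), AUC with CI, Youden-optimal cutoff, and
    confusion metrics at both the preset cutoff and the Youden cutoff.
    Missing values are dropped per criterion with the counts reported.
    """
    from .ecg_indices import CriteriaConfig, compute_all  # avoid module cycle

    if config is None:
        config = CriteriaConfig.preset("published")
    cohort = list(cohort)
    labeled = [r for r in cohort if r.origin in (Origin.RVOT, Origin.LVOT)]
    if not labeled:
        raise ValueError("cohort carries no RVOT/LVOT origin labels")
    y_all = [r.origin for r in labeled]
    n_rvot = sum(1 for o in y_all if o is Origin.RVOT)
    n_lvot = len(y_all) - n_rvot
    if n_rvot == 0 or n_lvot == 0:
        raise ValueError("both classes (RVOT and LVOT) must be present")

    per_patient = [compute_all(rec, config) for rec in labeled]
    criteria = config.enabled_criteria()

    report: dict = {
        "schema_version": "1.0",
        "preset": config.preset_name,
        "n_rvot": n_rvot,
        "n_lvot": n_lvot,
        "ci_method": ci_method,
        "criteria": {},
    }

    for idx, name in enumerate(criteria):
        rule = config.rule(name)
        vals, labs, calls, truths = [], [], [], []
        n_missing = 0
        for results, origin in zip(per_patient, y_all):
            res = results[idx]
            assert res.criterion_name == name
            calls.append(res.predicted_origin)
            truths.append(origin)
            if res.value is None or (isinstance(res.value, float) and math.isnan(res.value)):
                n_missing += 1
            else:
                vals.append(res.value)
                labs.append(origin)
        v = np.asarray(vals, dtype=float)
        lab_bin = _as_binary(labs) if len(labs) else np.empty(0)
        entry: dict = {
            "cutoff": rule.cutoff,
            "comparator": rule.comparator(),
            "direction": rule.direction.value,
            "n_used": len(vals),
            "n_missing": n_missing,
        }
        pos, neg = v[lab_bin == 1.0], v[lab_bin == 0.0]
        for grp, arr in (("rvot", pos), ("lvot", neg)):
            mean, sd, n_fin = _finite_summary(arr)
            entry[f"{grp}_mean"], entry[f"{grp}_sd"] = mean, sd
            entry[f"{grp}_n_infinite"] = int(len(arr) - n_fin)
        fin_pos, fin_neg = pos[np.isfinite(pos)], neg[np.isfinite(neg)]
        if len(fin_pos) > 1 and len(fin_neg) > 1:
            t_res = stats.ttest_ind(fin_pos, fin_neg, equal_var=True)
            entry["p_value"] = float(t_res.pvalue)
        else:
            entry["p_value"] = None

        if len(pos) and len(neg):
            roc = roc_curve(v, labs, rule.direction)
            low, high = auc_ci(v, labs, method=ci_method, seed=seed)
            entry["auc"] = roc.auc
            entry["auc_ci_low"], entry["auc_ci_high"] = low, high
            entry["youden_cutoff"] = roc.optimal_cutoff
            entry["roc_degenerate"] = roc.degenerate
            entry["metrics_at_preset"] = metrics_from_calls(calls, truths).as_dict()
            youden_rule = CriterionRule(
                name, roc.optimal_cutoff, rule.direction, strict=False
            )
            youden_calls = [classify(x, youden_rule) for x in vals]
            entry["metrics_at_youden"] = metrics_from_calls(youden_calls, labs).as_dict()
        else:
            entry["auc"] = None
            entry["auc_ci_low"] = entry["auc_ci_high"] = None
            entry["youden_cutoff"] = None
            entry["roc_degenerate"] = None
            entry["metrics_at_preset"] = None
            entry["metrics_at_youden"] = None
        report["criteria"][name] = entry

    return report
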