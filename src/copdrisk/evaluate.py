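"""ROC/AUC with DeLong variance, paired score comparison, quartile-based
high-risk classification, predictive values, overlap counts and group means.

The AUC is the normalized Mann–Whitney statistic computed from placement
values (ties credited one half).  Its variance, and the covariance between
two scores evaluated on the same patients, follow DeLong's nonparametric
structural-component construction, which also yields the paired Z-test for
comparing correlated ROC curves.

High-risk classification uses the cohort's upper quartile: the threshold is
the third quartile (linear interpolation between order statistics) and a
patient is "high-risk" when the score strictly exceeds it — with
half-integer thresholds on integer scores this equals >= the next integer.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "RocResult",
    "ComparisonResult",
    "ClassificationReport",
    "OverlapReport",
    "GroupComparison",
    "roc_with_auc",
    "delong_test",
    "upper_quartile_threshold",
    "high_risk_flags",
    "classification_metrics",
    "overlap_counts",
    "compare_group_means",
]


def _as_arrays(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-d and aligned")
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    if y.all() or not y.any():
        raise ValueError("labels must contain both classes")
    return s, y


def _placement_components(scores: np.ndarray, labels: np.ndarray):
    """DeLong structural components.

    Returns ``(auc, v10, v01)`` where ``v10[i]`` is the placement of positive
    i among the negatives (fraction of negatives it outranks, ties half) and
    ``v01[j]`` the symmetric placement of negative j among positives.
    """
    pos = scores[labels]
    neg = scores[~labels]
    m, n = len(pos), len(neg)
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float(v10.mean())
    return auc, v10, v01


def _delong_variance(v10: np.ndarray, v01: np.ndarray) -> float:
    m, n = len(v10), len(v01)
    s10 = float(np.var(v10, ddof=1)) if m > 1 else float("nan")
    s01 = float(np.var(v01, ddof=1)) if n > 1 else float("nan")
    return s10 / m + s01 / n


@dataclass
class RocResult:
    """ROC curve with DeLong AUC inference for one score."""

    name: str
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    variance: float
    ci95: tuple[float, float]
    n_positive: int
    n_negative: int


def roc_with_auc(scores, labels, name: str = "score",
                 ci_scale: str = "linear") -> RocResult:
    """ROC curve, placement-value AUC, DeLong variance and 95% CI.

    ``ci_scale="linear"`` gives auc ± 1.96·√var truncated to [0, 1];
    ``ci_scale="logit"`` transforms the interval through the logistic scale,
    producing the asymmetric intervals common near AUC → 1.
    """
    s, y = _as_arrays(scores, labels)
    auc, v10, v01 = _placement_components(s, y)
    var = _delong_variance(v10, v01)
    se = math.sqrt(var) if var == var else float("nan")
    if ci_scale == "logit" and 0.0 < auc < 1.0:
        logit = math.log(auc / (1 - auc))
        se_logit = se / (auc * (1 - auc))
        lo = 1 / (1 + math.exp(-(logit - 1.959963984540054 * se_logit)))
        hi = 1 / (1 + math.exp(-(logit + 1.959963984540054 * se_logit)))
    else:
        lo = max(0.0, auc - 1.959963984540054 * se)
        hi = min(1.0, auc + 1.959963984540054 * se)
    fpr, tpr, thr = _sk_roc_curve(y.astype(int), s, drop_intermediate=False)
    return RocResult(
        name=name, thresholds=thr, fpr=fpr, tpr=tpr, auc=auc,
        variance=var, ci95=(lo, hi),
        n_positive=int(y.sum()), n_negative=int((~y).sum()),
    )


@dataclass
class ComparisonResult:
    """Paired DeLong comparison of two correlated AUCs."""

    name_a: str
    name_b: str
    auc_a: float
    auc_b: float
    z: float
    p_value: float
    degenerate: bool = False


def delong_test(scores_a, scores_b, labels,
                name_a: str = "a", name_b: str = "b") -> ComparisonResult:
    """Two-sided Z-test for the difference of two paired AUCs.

    Both scores must be evaluated on the same patients and outcome.  When the
    variance of the AUC difference is zero (identical rankings) the result is
    flagged degenerate with z = 0, p = 1.
    """
    sa, y = _as_arrays(scores_a, labels)
    sb, _ = _as_arrays(scores_b, labels)
    auc_a, v10_a, v01_a = _placement_components(sa, y)
    auc_b, v10_b, v01_b = _placement_components(sb, y)
    m, n = len(v10_a), len(v01_a)
    if m < 2 or n < 2:
        # variance of the difference is not estimable from a single placement
        return ComparisonResult(name_a, name_b, auc_a, auc_b,
                                z=float("nan"), p_value=float("nan"),
                                degenerate=True)
    var_a = _delong_variance(v10_a, v01_a)
    var_b = _delong_variance(v10_b, v01_b)
    cov = (float(np.cov(v10_a, v10_b, ddof=1)[0, 1]) / m
           + float(np.cov(v01_a, v01_b, ddof=1)[0, 1]) / n)
    var_diff = var_a + var_b - 2.0 * cov
    if var_diff <= 0 or not math.isfinite(var_diff):
        return ComparisonResult(name_a, name_b, auc_a, auc_b,
                                z=0.0, p_value=1.0, degenerate=True)
    z = (auc_a - auc_b) / math.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return ComparisonResult(name_a, name_b, auc_a, auc_b, z=float(z),
                            p_value=float(min(p, 1.0)))


def upper_quartile_threshold(scores) -> float:
    """Third quartile of the score distribution (linear interpolation).

    Classification into "high-risk" uses ``score > threshold``, so the top
    quarter of the cohort (up to tie mass at the quartile) is flagged.
    """
    s = np.asarray(scores, dtype=float)
    if s.size < 4:
        raise ValueError("need at least 4 scores to form quartiles")
    return float(np.quantile(s, 0.75))


def high_risk_flags(scores, threshold: float) -> np.ndarray:
    """Boolean high-risk indicator: score strictly above the threshold."""
    return np.asarray(scores, dtype=float) > threshold


@dataclass
class ClassificationReport:
    """Confusion counts and derived metrics at one threshold.

    Ratios with a zero denominator are NaN, never silently zero.
    """

    name: str
    threshold: float
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)
    ppv: float = field(init=False)
    npv: float = field(init=False)
    accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        def ratio(num: int, den: int) -> float:
            return num / den if den else float("nan")
        self.sensitivity = ratio(self.tp, self.tp + self.fn)
        self.specificity = ratio(self.tn, self.tn + self.fp)
        self.ppv = ratio(self.tp, self.tp + self.fp)
        self.npv = ratio(self.tn, self.tn + self.fn)
        self.accuracy = ratio(self.tp + self.tn, self.tp + self.fp + self.fn + self.tn)


def classification_metrics(high_risk, labels, name: str = "score",
                           threshold: float = float("nan")) -> ClassificationReport:
    """2×2 table of a high-risk classification against the outcome."""
    hr = np.asarray(high_risk).astype(bool)
    y = np.asarray(labels).astype(bool)
    if hr.shape != y.shape:
        raise ValueError("flag vectors must be aligned")
    return ClassificationReport(
        name=name, threshold=threshold,
        tp=int((hr & y).sum()), fp=int((hr & ~y).sum()),
        fn=int((~hr & y).sum()), tn=int((~hr & ~y).sum()),
    )


@dataclass
class OverlapReport:
    """Set overlaps between per-score high-risk classifications and deaths."""

    high_risk_sets: dict[str, set]
    death_set: set
    pairwise: dict[tuple[str, str], int]
    with_deaths: dict[str, int]

    def covered_by_union(self, target: str, others: Sequence[str]) -> bool:
        """True when every target high-risk patient is flagged by >= 1 other score."""
        union: set = set()
        for other in others:
            union |= self.high_risk_sets[other]
        return self.high_risk_sets[target] <= union


def overlap_counts(high_risk: Mapping[str, Sequence], labels,
                   ids: Sequence | None = None) -> OverlapReport:
    """Pairwise intersections of high-risk sets, and each set's overlap with
    the actual deaths (absolute numbers)."""
    y = np.asarray(labels).astype(bool)
    n = len(y)
    if ids is None:
        ids = np.arange(n)
    ids = np.asarray(ids)
    sets = {}
    for name, flags in high_risk.items():
        f = np.asarray(flags).astype(bool)
        if f.shape != y.shape:
            raise ValueError(f"{name}: flag vector not aligned with labels")
        sets[name] = set(ids[f].tolist())
    deaths = set(ids[y].tolist())
    names = list(sets)
    pairwise = {
        (a, b): len(sets[a] & sets[b])
        for i, a in enumerate(names) for b in names[i + 1:]
    }
    with_deaths = {name: len(sets[name] & deaths) for name in names}
    return OverlapReport(high_risk_sets=sets, death_set=deaths,
                         pairwise=pairwise, with_deaths=with_deaths)


@dataclass
class GroupComparison:
    """Score moments in the outcome group vs a reference, with Student's t."""

    mode: str
    mean_group: float
    sd_group: float
    mean_reference: float
    sd_reference: float
    t: float
    p_value: float
    n_group: int
    n_reference: int


def compare_group_means(scores, labels, mode: str = "vs_overall") -> GroupComparison:
    """Two-sided two-sample Student's t-test of the deceased group's scores.

    ``mode="vs_overall"`` compares against the whole cohort (the overlapping
    comparison some validation reports print); ``mode="vs_survivors"`` is the
    standard disjoint two-sample comparison.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    group = s[y]
    if mode == "vs_overall":
        reference = s
    elif mode == "vs_survivors":
        reference = s[~y]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if group.size == 0 or reference.size < 2:
        raise ValueError("group empty or reference too small")
    with warnings.catch_warnings():
        # near-constant groups trigger scipy's cancellation warning; the
        # resulting t/p are still the closed-form pooled values
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(group, reference, equal_var=True)
    return GroupComparison(
        mode=mode,
        mean_group=float(group.mean()),
        sd_group=float(group.std(ddof=1)) if group.size > 1 else float("nan"),
        mean_reference=float(reference.mean()),
        sd_reference=float(reference.std(ddof=1)),
        t=float(t), p_value=float(p),
        n_group=int(group.size), n_reference=int(reference.size),
    )
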