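"""Response-prediction statistics.

Everything needed to reproduce a biomarker performance table: the
Mann–Whitney group comparison, the empirical ROC AUC with a Z test
against 0.5 (DeLong placement variance), the Youden-index optimal
cutoff, DeLong's test for comparing two correlated ROC curves, and
confusion-matrix metrics with exact Clopper–Pearson intervals.

Progressive disease (PD) is always the positive class, and scores are
oriented so that larger values are more PD-like (log2 fold changes are
used as-is: rising ctDNA predicts progression).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

PD = "PD"
NON_PD = "non-PD"


# ---------------------------------------------------------------------------
# confusion matrices and exact intervals


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")
        if self.n == 0:
            raise ValueError("confusion matrix must contain at least one subject")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, predicted_pd, is_pd) -> "ConfusionMatrix":
        predicted_pd = np.asarray(predicted_pd, dtype=bool)
        is_pd = np.asarray(is_pd, dtype=bool)
        if predicted_pd.shape != is_pd.shape:
            raise ValueError("predictions and labels differ in length")
        return cls(
            tp=int(np.sum(predicted_pd & is_pd)),
            fp=int(np.sum(predicted_pd & ~is_pd)),
            tn=int(np.sum(~predicted_pd & ~is_pd)),
            fn=int(np.sum(~predicted_pd & is_pd)),
        )


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Clopper–Pearson) binomial interval, returned in percent.

    Beta-quantile form; the lower bound is 0 when k = 0 and the upper
    bound 100 when k = n. Report-level rounding (one decimal) is left to
    the caller.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, n={n}]")
    lo, hi = proportion_confint(k, n, alpha=alpha, method="beta")
    lo = 0.0 if k == 0 else float(lo)
    hi = 1.0 if k == n else float(hi)
    return 100.0 * lo, 100.0 * hi


@dataclass
class MetricWithCI:
    """A proportion metric in percent with its exact 95% interval."""

    name: str
    k: int
    n: int
    estimate: float  # percent; NaN when undefined
    ci_low: float
    ci_high: float
    defined: bool = True

    def rounded(self, decimals: int = 1) -> tuple[float, float, float]:
        return (
            round(self.estimate, decimals),
            round(self.ci_low, decimals),
            round(self.ci_high, decimals),
        )


def _metric(name: str, k: int, denom: int, alpha: float) -> MetricWithCI:
    if denom == 0:
        return MetricWithCI(name, 0, 0, math.nan, math.nan, math.nan, defined=False)
    lo, hi = clopper_pearson(k, denom, alpha)
    return MetricWithCI(name, k, denom, 100.0 * k / denom, lo, hi)


def confusion_metrics(m: ConfusionMatrix, alpha: float = 0.05) -> dict[str, MetricWithCI]:
    """Sensitivity, specificity, PPV, NPV and accuracy with exact CIs.

    Metrics with a zero denominator are returned flagged undefined
    (NaN estimate) rather than raising, so a degenerate classification
    still yields the remaining metrics.
    """
    return {
        "sensitivity": _metric("sensitivity", m.tp, m.tp + m.fn, alpha),
        "specificity": _metric("specificity", m.tn, m.tn + m.fp, alpha),
        "ppv": _metric("ppv", m.tp, m.tp + m.fp, alpha),
        "npv": _metric("npv", m.tn, m.tn + m.fn, alpha),
        "accuracy": _metric("accuracy", m.tp + m.tn, m.n, alpha),
    }


# ---------------------------------------------------------------------------
# Mann–Whitney


@dataclass
class MannWhitneyResult:
    u: float
    p: float
    method: str


def mann_whitney(group_a, group_b) -> MannWhitneyResult:
    """Two-sided Mann–Whitney U test (U reported for ``group_a``).

    Exact enumeration when the pooled sample is small (n_a + n_b <= 20)
    and tie-free; otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        # every observation tied: no evidence either way
        return MannWhitneyResult(u=a.size * b.size / 2.0, p=1.0, method="degenerate")
    has_ties = np.unique(pooled).size < pooled.size
    if a.size + b.size <= 20 and not has_ties:
        method = "exact"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        method = "asymptotic"
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    return MannWhitneyResult(u=float(res.statistic), p=float(min(res.pvalue, 1.0)), method=method)


# ---------------------------------------------------------------------------
# ROC / AUC via DeLong placements


def _split(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    pos = scores[labels]
    neg = scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values.

    ``v10[i]`` is the fraction of negatives that positive i beats
    (ties count 1/2); ``v01[j]`` the fraction of positives that
    negative j loses to. Their common mean is the AUC.
    """
    gt = (pos[:, None] > neg[None, :]).astype(float)
    eq = (pos[:, None] == neg[None, :]).astype(float)
    mat = gt + 0.5 * eq
    return mat.mean(axis=1), mat.mean(axis=0)


def roc_auc(scores, labels) -> float:
    """Empirical AUC = (concordant pairs + half ties) / (n_pos * n_neg)."""
    pos, neg = _split(scores, labels)
    v10, _ = _placements(pos, neg)
    return float(v10.mean())


@dataclass
class AucZTest:
    auc: float
    z: float
    p: float
    small_sample: bool = False


def auc_ztest(scores, labels) -> AucZTest:
    """Two-sided Z test of AUC = 0.5 with DeLong's variance estimator.

    With a degenerate variance (perfect separation at tiny n) the normal
    approximation collapses; the result is then flagged ``small_sample``
    with p = 0 (or 1 when the AUC is exactly 0.5).
    """
    pos, neg = _split(scores, labels)
    v10, v01 = _placements(pos, neg)
    auc = float(v10.mean())
    var = _delong_variance(v10, v01)
    if var <= 0:
        p = 1.0 if auc == 0.5 else 0.0
        z = 0.0 if auc == 0.5 else math.copysign(math.inf, auc - 0.5)
        return AucZTest(auc=auc, z=z, p=p, small_sample=True)
    z = (auc - 0.5) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return AucZTest(auc=auc, z=float(z), p=float(p))


def _delong_variance(v10: np.ndarray, v01: np.ndarray) -> float:
    s10 = float(np.var(v10, ddof=1)) if v10.size > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if v01.size > 1 else 0.0
    return s10 / v10.size + s01 / v01.size


@dataclass
class DeLongComparison:
    auc_1: float
    auc_2: float
    z: float
    p: float


def delong_compare(scores_1, scores_2, labels) -> DeLongComparison:
    """DeLong test for the difference of two correlated AUCs.

    Both score vectors must be measured on the same subjects in the same
    order. A zero-variance difference (e.g. one score a monotone
    transform of the other) yields p = 1 when the AUCs agree.
    """
    s1 = np.asarray(scores_1, dtype=float)
    s2 = np.asarray(scores_2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError("paired score vectors differ in length")
    labels = np.asarray(labels, dtype=bool)
    pos1, neg1 = _split(s1, labels)
    pos2, neg2 = _split(s2, labels)
    v10_1, v01_1 = _placements(pos1, neg1)
    v10_2, v01_2 = _placements(pos2, neg2)
    auc1, auc2 = float(v10_1.mean()), float(v10_2.mean())
    m, n = v10_1.size, v01_1.size
    if m > 1:
        s10 = np.cov(np.vstack([v10_1, v10_2]), ddof=1)
    else:
        s10 = np.zeros((2, 2))
    if n > 1:
        s01 = np.cov(np.vstack([v01_1, v01_2]), ddof=1)
    else:
        s01 = np.zeros((2, 2))
    var = (
        s10[0, 0] / m + s10[1, 1] / m - 2 * s10[0, 1] / m
        + s01[0, 0] / n + s01[1, 1] / n - 2 * s01[0, 1] / n
    )
    diff = auc1 - auc2
    if var <= 0:
        p = 1.0 if diff == 0 else 0.0
        z = 0.0 if diff == 0 else math.copysign(math.inf, diff)
        return DeLongComparison(auc1, auc2, z, p)
    z = diff / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return DeLongComparison(auc1, auc2, float(z), float(p))


# ---------------------------------------------------------------------------
# Youden cutoff


@dataclass
class RocResult:
    """ROC summary at the Youden-optimal cutoff.

    The classification rule is ``score > cutoff`` predicts PD.
    ``degenerate`` marks the uninformative case (best J <= 0, e.g. all
    scores tied), where the cutoff falls back to -inf.
    """

    auc: float
    auc_p: float
    cutoff: float
    sens_at_cutoff: float  # percent
    spec_at_cutoff: float  # percent
    j: float
    n_pos: int
    n_neg: int
    degenerate: bool = False
    small_sample: bool = False


def youden_cutoff(scores, labels, cutoff_style: str = "midpoint") -> RocResult:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Candidate thresholds sit midway between adjacent distinct sorted
    scores, plus -inf and +inf (``cutoff_style="observed"`` uses the
    observed score values instead of midpoints). Ties on J break toward
    higher sensitivity, then lower cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    labels_arr = np.asarray(labels, dtype=bool)
    pos, neg = _split(scores, labels_arr)
    ztest = auc_ztest(scores, labels_arr)

    distinct = np.unique(scores)
    if cutoff_style == "midpoint":
        interior = (distinct[:-1] + distinct[1:]) / 2.0 if distinct.size > 1 else np.array([])
    elif cutoff_style == "observed":
        interior = distinct
    else:
        raise ValueError(f"unknown cutoff_style {cutoff_style!r}")
    candidates = np.concatenate([[-math.inf], interior, [math.inf]])

    best = None
    for c in candidates:
        sens = float(np.mean(pos > c))
        spec = float(np.mean(neg <= c))
        j = sens + spec - 1.0
        rank = (j, sens, -c)  # maximize J, then sensitivity, then prefer lower cutoff
        if best is None or rank > best[0]:
            best = (rank, c, sens, spec, j)

    _, cutoff, sens, spec, j = best
    return RocResult(
        auc=ztest.auc,
        auc_p=ztest.p,
        cutoff=float(cutoff),
        sens_at_cutoff=100.0 * sens,
        spec_at_cutoff=100.0 * spec,
        j=j,
        n_pos=pos.size,
        n_neg=neg.size,
        degenerate=j <= 0,
        small_sample=ztest.small_sample,
    )
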