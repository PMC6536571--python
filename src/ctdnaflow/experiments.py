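"""Repeated-run validation experiments over synthetic cohorts.

These studies quantify how well the pipeline recovers the quantities the
generator builds in: the separating fold-change cutoff, the group PFS
medians, the log-rank test's type-I error under the null, the AUC/U
identity, and per-class filter recall. They are used by the test suite
and the reproduction script; each takes an explicit seed and derives
per-run seeds deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .diagnostics import mann_whitney, roc_auc
from .filters import filter_pipeline
from .monitoring import MARKER_CTDNA
from .pipeline import run_pipeline
from .survival import SurvivalRecord, logrank_test
from .synthetic import CohortConfig, generate_full_cohort, generate_tagged_calls

#: Truncation bounds giving cohorts a known separating threshold between
#: the per-cycle log2 fold changes of the two response groups.
SEPARATION_GUARD = (-0.4, 0.1)


def _derive_seed(base: int, i: int) -> int:
    return int((base * 100_003 + i) % 2**31)


@dataclass
class RecoveryStudy:
    """Per-run outcomes of the cutoff/KM recovery experiment."""

    n_runs: int
    cutoff_in_gap: list[bool] = field(default_factory=list)
    km_above_months: list[float] = field(default_factory=list)
    km_below_months: list[float] = field(default_factory=list)

    @property
    def cutoff_recovery_rate(self) -> float:
        return float(np.mean(self.cutoff_in_gap))

    def km_above_rate(self, lo: float = 1.0, hi: float = 4.0) -> float:
        m = np.asarray(self.km_above_months)
        return float(np.mean((lo <= m) & (m <= hi)))

    def km_below_rate(self, lo: float = 6.0, hi: float = 13.0) -> float:
        m = np.asarray(self.km_below_months)
        return float(np.mean((lo <= m) & (m <= hi)))


def cutoff_recovery_study(n_runs: int = 50, seed: int = 0) -> RecoveryStudy:
    """Repeated study-scale cohorts with a guaranteed group separation.

    Each run generates an n=41 cohort whose per-cycle log2 fold changes
    are truncated to the :data:`SEPARATION_GUARD` bounds (non-PD below
    -0.4, PD above +0.1, a known separating threshold between them),
    runs the full pipeline, and records (a) whether the Youden cutoff of
    the ctDNA C1/C0 row lies strictly inside the measured inter-group
    gap and (b) the Kaplan-Meier median PFS of the cutoff-stratified
    groups.
    """
    study = RecoveryStudy(n_runs=n_runs)
    for i in range(n_runs):
        config = CohortConfig(seed=_derive_seed(seed, i), log2fc_bounds=SEPARATION_GUARD)
        cohort, whitelist = generate_full_cohort(config)
        result = run_pipeline(cohort, whitelist)
        row = next(
            (r for r in result.rows if r.marker == MARKER_CTDNA and r.interval == "C1/C0"),
            None,
        )
        if row is None:
            study.cutoff_in_gap.append(False)
            continue
        is_pd = {p.patient_id: p.is_pd for p in cohort}
        values = {
            fc.patient_id: fc.value
            for fc in result.fold_changes
            if fc.marker == MARKER_CTDNA and fc.to_timepoint == "C1"
        }
        pd_scores = [v for pid, v in values.items() if is_pd[pid]]
        nonpd_scores = [v for pid, v in values.items() if not is_pd[pid]]
        in_gap = bool(
            pd_scores
            and nonpd_scores
            and max(nonpd_scores) < row.roc.cutoff < min(pd_scores)
        )
        study.cutoff_in_gap.append(in_gap)
        if result.survival is not None:
            study.km_above_months.append(result.survival.above.median)
            study.km_below_months.append(result.survival.below.median)
    return study


def logrank_type1_study(
    n_reps: int = 500, n_per_group: int = 20, median_months: float = 6.0, seed: int = 0
) -> float:
    """Rejection rate of the log-rank test at alpha=0.05 under the null.

    Both groups draw from the same exponential; the rate should sit near
    the nominal 5%.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(5,)))
    scale = median_months / np.log(2.0)
    rejections = 0
    for _ in range(n_reps):
        times = rng.exponential(scale, size=2 * n_per_group)
        groups = [
            [
                SurvivalRecord(patient_id=f"G{g}{j}", time=float(t), event=True)
                for j, t in enumerate(times[g * n_per_group : (g + 1) * n_per_group])
            ]
            for g in (0, 1)
        ]
        if logrank_test(groups[0], groups[1]).p < 0.05:
            rejections += 1
    return rejections / n_reps


def auc_u_identity_max_diff(n_datasets: int = 25, seed: int = 0) -> float:
    """Max |AUC - U/(n_pos * n_neg)| over random datasets (should be ~0)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(6,)))
    worst = 0.0
    for _ in range(n_datasets):
        n_pos = int(rng.integers(4, 12))
        n_neg = int(rng.integers(4, 20))
        pos = rng.normal(0.4, 1.0, n_pos)
        neg = rng.normal(0.0, 1.0, n_neg)
        auc = roc_auc(np.concatenate([pos, neg]), [1] * n_pos + [0] * n_neg)
        u = mann_whitney(pos, neg).u
        worst = max(worst, abs(auc - u / (n_pos * n_neg)))
    return worst


@dataclass
class FilterRecallResult:
    recall: dict[str, float]
    somatic_false_removal_rate: float
    n_calls: int


def filter_recall_study(seed: int = 0) -> FilterRecallResult:
    """Per-class removal recall on a 500-call tagged sample.

    Recall for a contaminant class is the fraction of injected calls of
    that class absent from the pipeline output; the somatic
    false-removal rate is the fraction of true somatic calls wrongly
    removed.
    """
    sample = generate_tagged_calls(
        n_somatic=350, n_germline=50, n_artifact=50, n_noise=50, seed=seed
    )
    result = filter_pipeline(
        sample.plasma_calls, sample.pbl_calls, sample.avg_depth, sample.whitelist
    )
    passed_keys = {c.key for c in result.passed}
    recall = {}
    for cls in ("germline", "artifact", "noise"):
        injected = [c for c in sample.plasma_calls if c.truth_class == cls]
        removed = [c for c in injected if c.key not in passed_keys]
        recall[cls] = len(removed) / len(injected)
    somatic = [c for c in sample.plasma_calls if c.truth_class == "somatic"]
    removed_somatic = [c for c in somatic if c.key not in passed_keys]
    return FilterRecallResult(
        recall=recall,
        somatic_false_removal_rate=len(removed_somatic) / len(somatic),
        n_calls=len(sample.plasma_calls),
    )
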