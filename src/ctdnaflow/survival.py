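"""Progression-free survival: Kaplan–Meier curves and log-rank comparison.

PFS runs from the first treatment cycle to first progression or death;
patients without an observed event are right-censored. Groups are
defined by the fold-change cutoff from the monitoring stage (above vs
at-or-below). Estimation and testing are delegated to lifelines; the
median is the earliest time at which the survival curve drops to 0.5 or
below, and is infinite (never reached) when the curve stays above 0.5.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .monitoring import PD, classify

GROUP_ABOVE = "above-cutoff"
GROUP_BELOW = "below-cutoff"


@dataclass
class SurvivalRecord:
    patient_id: str
    time: float  # months
    event: bool  # True: progression or death observed; False: censored
    group: str | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.time) or self.time <= 0:
            raise ValueError(f"survival time must be finite and positive, got {self.time}")


@dataclass
class KMEstimate:
    """Product-limit estimate for one group.

    ``median`` is +inf when the curve never reaches 0.5 (undefined
    median, all-censored or high survival).
    """

    times: np.ndarray
    survival: np.ndarray
    median: float
    n: int
    n_events: int
    group: str | None = None


def km_estimate(records: list[SurvivalRecord], group: str | None = None) -> KMEstimate:
    """Kaplan–Meier estimator for one group of survival records.

    Ties between events and censorings at the same time follow the usual
    convention (events first, censored subjects leave the risk set after
    their time).
    """
    if not records:
        raise ValueError("km_estimate requires at least one record")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    fitter = KaplanMeierFitter()
    fitter.fit(times, event_observed=events)
    sf = fitter.survival_function_
    median = float(fitter.median_survival_time_)
    return KMEstimate(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
        median=median,
        n=len(records),
        n_events=int(events.sum()),
        group=group,
    )


@dataclass
class LogrankResult:
    chi_square: float
    p: float


def logrank_test(group_a: list[SurvivalRecord], group_b: list[SurvivalRecord]) -> LogrankResult:
    """Two-group log-rank test (hypergeometric variance, 1 df, two-sided)."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    n_events = sum(r.event for r in group_a) + sum(r.event for r in group_b)
    if n_events == 0:
        raise ValueError("log-rank test undefined without any observed events")
    res = _ll_logrank(
        np.array([r.time for r in group_a], dtype=float),
        np.array([r.time for r in group_b], dtype=float),
        event_observed_A=np.array([r.event for r in group_a], dtype=bool),
        event_observed_B=np.array([r.event for r in group_b], dtype=bool),
    )
    return LogrankResult(chi_square=float(res.test_statistic), p=float(res.p_value))


class DegenerateStratification(ValueError):
    """All patients fell on one side of the cutoff; no comparison possible."""


@dataclass
class StratifiedGroups:
    above: list[SurvivalRecord] = field(default_factory=list)
    below: list[SurvivalRecord] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)

    @property
    def counts(self) -> tuple[int, int]:
        return len(self.above), len(self.below)


def stratify_by_cutoff(
    fold_changes,
    cutoff: float,
    survival_records: dict[str, SurvivalRecord] | list[SurvivalRecord],
) -> StratifiedGroups:
    """Split patients into above/below-cutoff groups by their fold change.

    ``fold_changes`` is an iterable of objects with ``patient_id`` and
    ``value``. Patients lacking a survival record are excluded with a
    warning; an empty side raises :class:`DegenerateStratification`.
    """
    if not isinstance(survival_records, dict):
        survival_records = {r.patient_id: r for r in survival_records}
    groups = StratifiedGroups()
    for fc in fold_changes:
        rec = survival_records.get(fc.patient_id)
        if rec is None:
            warnings.warn(
                f"patient {fc.patient_id} has no survival record; excluded", stacklevel=2
            )
            groups.excluded.append(fc.patient_id)
            continue
        if classify(fc.value, cutoff) == PD:
            rec.group = GROUP_ABOVE
            groups.above.append(rec)
        else:
            rec.group = GROUP_BELOW
            groups.below.append(rec)
    if not groups.above or not groups.below:
        raise DegenerateStratification(
            "all patients fall on one side of the cutoff "
            f"(above={len(groups.above)}, below={len(groups.below)}); "
            "survival comparison aborted"
        )
    return groups
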