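"""Prognostic evaluation: Harrell's c-index, quartile groups, Kaplan-Meier,
and the log-rank test.

Conventions pinned here (the literature varies and reproducibility demands a
choice): Harrell's c counts risk-score ties as 1/2 and treats pairs with
equal times and both events as non-comparable; when an event and a censored
observation share a time, the censored subject is taken to have outlived the
event. Quartile cut-offs use linearly interpolated empirical percentiles
(NumPy's default, "type 7") with right-closed intervals. The log-rank
statistic is delegated to lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Optional, Sequence

import numpy as np

__all__ = [
    "SurvivalRecord",
    "EmptyScoreError",
    "concordance_index",
    "quartile_groups",
    "km_estimator",
    "logrank_test",
]


class EmptyScoreError(ValueError):
    """An aggregate was requested over an empty collection; no score exists."""


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient: follow-up time, event indicator, and a risk/marker score.

    ``event`` is 1 for disease-specific death, 0 for censoring.
    ``true_density`` is only populated for synthetic cohorts.
    """

    patient_id: str
    time: float
    event: int
    score: Optional[float] = None
    true_density: Optional[float] = None

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("time must be positive")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")

    def with_score(self, score: float) -> "SurvivalRecord":
        return replace(self, score=score)


Direction = Literal["higher_score_higher_risk", "higher_score_lower_risk"]


def concordance_index(
    records: Sequence[SurvivalRecord],
    direction: Direction = "higher_score_higher_risk",
) -> float:
    """Harrell's concordance index of ``score`` against censored survival.

    Over every comparable pair (the subject with the shorter observed time
    experienced the event), the pair is concordant when the higher risk
    belongs to the shorter survivor; tied risks count 1/2. For protective
    markers pass ``direction="higher_score_lower_risk"``, which negates the
    scores.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    if any(r.score is None for r in records):
        raise ValueError("every record needs a score")
    sign = 1.0 if direction == "higher_score_higher_risk" else -1.0
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    risks = sign * np.array([float(r.score) for r in records])

    comparable = 0
    concordant = 0.0
    n = len(records)
    for i in range(n):
        for j in range(i + 1, n):
            ti, tj, ei, ej = times[i], times[j], events[i], events[j]
            if ti == tj:
                if ei == ej:
                    continue  # both events (or both censored): not comparable
                short, long_ = (i, j) if ei == 1 else (j, i)
            elif ti < tj:
                if ei == 0:
                    continue
                short, long_ = i, j
            else:
                if ej == 0:
                    continue
                short, long_ = j, i
            comparable += 1
            if risks[short] > risks[long_]:
                concordant += 1.0
            elif risks[short] == risks[long_]:
                concordant += 0.5
    if comparable == 0:
        raise ValueError("no comparable pairs in cohort")
    return concordant / comparable


def quartile_groups(
    scores: Sequence[float], cutoffs: Optional[Sequence[float]] = None
) -> tuple[list[str], tuple[float, float, float]]:
    """Assign Q1..Q4 labels by quartile cut-offs.

    Without explicit ``cutoffs`` the 25/50/75 empirical percentiles of
    ``scores`` (linear interpolation) are used; intervals are right-closed:
    Q1 = (-inf, p25], Q2 = (p25, p50], Q3 = (p50, p75], Q4 = (p75, inf).
    Supplying ``cutoffs`` scores new patients against a fixed reference
    cohort.
    """
    scores = np.asarray(scores, dtype=float)
    if cutoffs is None:
        if len(np.unique(scores)) < 4:
            raise ValueError("need >= 4 distinct scores to derive quartile cutoffs")
        p25, p50, p75 = np.percentile(scores, [25, 50, 75])
    else:
        p25, p50, p75 = (float(c) for c in cutoffs)
    labels = []
    for s in scores:
        if s <= p25:
            labels.append("Q1")
        elif s <= p50:
            labels.append("Q2")
        elif s <= p75:
            labels.append("Q3")
        else:
            labels.append("Q4")
    return labels, (float(p25), float(p50), float(p75))


def km_estimator(
    records: Sequence[SurvivalRecord],
) -> list[tuple[float, int, int, float]]:
    """Kaplan-Meier product-limit estimate.

    Returns one row ``(time, at_risk, events, survival)`` per distinct
    observed time in increasing order, where ``survival`` is S(t) just after
    that time. Censored-only times appear with ``events=0`` and leave the
    survival value unchanged. S(0) = 1 by construction (not emitted as a row).
    """
    if not records:
        raise ValueError("need at least one record")
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]

    rows: list[tuple[float, int, int, float]] = []
    s = 1.0
    n_at_risk = len(times)
    i = 0
    while i < len(times):
        t = times[i]
        j = i
        d = 0
        while j < len(times) and times[j] == t:
            d += int(events[j])
            j += 1
        if d > 0:
            s *= 1.0 - d / n_at_risk
        rows.append((float(t), int(n_at_risk), int(d), float(s)))
        n_at_risk -= j - i
        i = j
    return rows


def logrank_test(
    records: Sequence[SurvivalRecord], group_labels: Sequence[str]
) -> tuple[float, int, float]:
    """Log-rank test across >= 2 groups; returns (chi_square, df, p_value)."""
    from lifelines.statistics import multivariate_logrank_test

    if len(records) != len(group_labels):
        raise ValueError("records and group_labels length mismatch")
    groups = sorted(set(group_labels))
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    result = multivariate_logrank_test(times, np.asarray(group_labels), events)
    df = len(groups) - 1
    return float(result.test_statistic), df, float(result.p_value)
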