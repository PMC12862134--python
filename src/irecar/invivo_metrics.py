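"""Caliper tumor volumes, treatment/endpoint triggers, response classes,
and Kaplan-Meier / log-rank survival analysis.

Conventions of the in-vivo study this mirrors:

* tumor volume from orthogonal calipers, V = 0.5 * length * width^2 (mm^3);
* animals are treated once the volume exceeds 100 mm^3 (strict);
* euthanasia when any caliper dimension reaches 12 mm;
* "eradicated" means volume 0 at the first measurement at or after 48 h
  post-treatment (measurements are thrice-weekly, so +2 days);
* progression-free survival runs from treatment to the first
  progression/recurrence event, censored at the day-60 study end;
* group survival curves are compared pairwise with log-rank tests under a
  Bonferroni correction (k = number of pairwise comparisons).

The product-limit estimator and the log-rank statistic are computed with
lifelines; the surrounding trial logic (triggers, response labels, PFS
event construction) is this module's own.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

__all__ = [
    "CaliperRecord",
    "SubjectRecord",
    "KMCurve",
    "ResponseClass",
    "tumor_volume",
    "treatment_trigger",
    "endpoint_trigger",
    "classify_response",
    "km_estimate",
    "logrank_pairwise",
    "pfs_records",
    "os_records",
]

TREATMENT_VOLUME_MM3 = 100.0
ENDPOINT_DIMENSION_MM = 12.0
ERADICATION_WINDOW_DAYS = 2
FOLLOWUP_END_DAY = 60


@dataclass(frozen=True)
class CaliperRecord:
    animal_id: str
    day: int
    length_mm: float
    width_mm: float

    def __post_init__(self) -> None:
        if self.width_mm < 0 or self.length_mm < 0:
            raise ValueError("caliper dimensions must be non-negative")


@dataclass
class SubjectRecord:
    """One animal: volume series (day, mm^3), treatment day, endpoint."""

    animal_id: str
    group: str
    volume_series: list[tuple[int, float]]
    treatment_day: int
    endpoint_day: int
    event: str  # "progression", "death", or "censored"

    def __post_init__(self) -> None:
        if self.endpoint_day < self.treatment_day:
            raise ValueError("endpoint precedes treatment")
        if any(v < 0 for _, v in self.volume_series):
            raise ValueError("negative tumor volume")


@dataclass(frozen=True)
class KMCurve:
    """Product-limit curve: (time, at-risk, events, survival probability) rows."""

    times: tuple[float, ...]
    at_risk: tuple[int, ...]
    events: tuple[int, ...]
    survival: tuple[float, ...]

    def survival_at(self, t: float) -> float:
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if ti <= t:
                s = si
        return s


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Caliper volume 0.5 * length * width^2 (mm^3); length is the larger axis.

    Swapped inputs are reordered with a warning rather than rejected.
    """
    if length_mm < 0 or width_mm < 0:
        raise ValueError("caliper dimensions must be non-negative")
    if width_mm > length_mm:
        warnings.warn("width exceeds length; swapping caliper axes", stacklevel=2)
        length_mm, width_mm = width_mm, length_mm
    return 0.5 * length_mm * width_mm**2


def treatment_trigger(volume_mm3: float) -> bool:
    """True once the tumor volume strictly exceeds 100 mm^3."""
    if volume_mm3 < 0:
        raise ValueError("volume must be non-negative")
    return volume_mm3 > TREATMENT_VOLUME_MM3


def endpoint_trigger(length_mm: float, width_mm: float) -> bool:
    """True when any caliper dimension reaches 12 mm (euthanasia rule)."""
    if length_mm < 0 or width_mm < 0:
        raise ValueError("caliper dimensions must be non-negative")
    return max(length_mm, width_mm) >= ENDPOINT_DIMENSION_MM


class ResponseClass:
    ERADICATED_DURABLE = "eradicated_durable"
    ERADICATED_RECURRENT = "eradicated_recurrent"
    STABLE_OR_PROGRESSIVE = "stable_or_progressive"


def classify_response(subject: SubjectRecord) -> tuple[str, int | None]:
    """Response label and progression day for one animal.

    * eradicated: volume 0 at the first measurement >= 48 h post-treatment;
      durable if it stays 0, recurrent otherwise (progression day = first
      later day with volume > 0);
    * non-eradicated: progression day = first post-treatment day with
      volume exceeding the pre-treatment (treatment-day) volume, if any.
    """
    series = sorted(subject.volume_series)
    post = [(d, v) for d, v in series if d >= subject.treatment_day + ERADICATION_WINDOW_DAYS]
    if not post:
        raise ValueError(f"{subject.animal_id}: no post-treatment measurements")
    pre = [v for d, v in series if d <= subject.treatment_day]
    baseline = pre[-1] if pre else series[0][1]

    if post[0][1] == 0.0:
        recur = [(d, v) for d, v in post if v > 0]
        if recur:
            return ResponseClass.ERADICATED_RECURRENT, recur[0][0]
        return ResponseClass.ERADICATED_DURABLE, None
    prog = [(d, v) for d, v in series if d > subject.treatment_day and v > baseline]
    if prog:
        return ResponseClass.STABLE_OR_PROGRESSIVE, prog[0][0]
    return ResponseClass.STABLE_OR_PROGRESSIVE, None


def pfs_records(subjects: list[SubjectRecord]) -> pd.DataFrame:
    """Progression-free survival table: (animal_id, group, time, event).

    Time runs from treatment to the first progression/recurrence event;
    animals without one are censored at the earlier of their endpoint day
    and the day-60 follow-up end.
    """
    rows = []
    for s in subjects:
        label, prog_day = classify_response(s)
        if prog_day is not None:
            rows.append((s.animal_id, s.group, prog_day - s.treatment_day, 1))
        else:
            end = min(s.endpoint_day, FOLLOWUP_END_DAY)
            rows.append((s.animal_id, s.group, end - s.treatment_day, 0))
    return pd.DataFrame(rows, columns=["animal_id", "group", "time", "event"])


def os_records(subjects: list[SubjectRecord]) -> pd.DataFrame:
    """Overall-survival table: death/euthanasia is the event, others censored."""
    rows = [
        (
            s.animal_id,
            s.group,
            s.endpoint_day - s.treatment_day,
            1 if s.event == "death" else 0,
        )
        for s in subjects
    ]
    return pd.DataFrame(rows, columns=["animal_id", "group", "time", "event"])


def km_estimate(records: list[tuple[float, int]]) -> KMCurve:
    """Product-limit survival curve from (time, event-flag) pairs.

    Event flag 1 = event observed, 0 = censored.  Ties share the
    simultaneous risk set; censored subjects leave the risk set without a
    survival drop.
    """
    if not records:
        raise ValueError("no survival records")
    times = np.array([t for t, _ in records], dtype=float)
    events = np.array([e for _, e in records], dtype=int)
    if (times < 0).any():
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    out_t, out_r, out_d, out_s = [], [], [], []
    for t, row in kmf.event_table.iterrows():
        if t == 0 and row["observed"] == 0 and row["censored"] == 0:
            continue
        out_t.append(float(t))
        out_r.append(int(row["at_risk"]))
        out_d.append(int(row["observed"]))
        out_s.append(float(kmf.survival_function_at_times(t).iloc[0]))
    return KMCurve(tuple(out_t), tuple(out_r), tuple(out_d), tuple(out_s))


def logrank_pairwise(
    groups: dict[str, list[tuple[float, int]]],
    k_comparisons: int | None = None,
) -> pd.DataFrame:
    """Pairwise log-rank tests with Bonferroni correction.

    ``groups`` maps group name to (time, event) records.  ``k_comparisons``
    defaults to the number of pairs; adjusted p = min(1, p * k).
    Returns columns (group_a, group_b, statistic, p, p_adjusted).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, recs in groups.items():
        if not recs:
            raise ValueError(f"group {name!r} has no subjects")
    pairs = list(itertools.combinations(sorted(groups), 2))
    k = k_comparisons if k_comparisons is not None else len(pairs)
    rows = []
    for a, b in pairs:
        ta = np.array([t for t, _ in groups[a]], dtype=float)
        ea = np.array([e for _, e in groups[a]], dtype=int)
        tb = np.array([t for t, _ in groups[b]], dtype=float)
        eb = np.array([e for _, e in groups[b]], dtype=int)
        res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
        rows.append((a, b, float(res.test_statistic), float(res.p_value),
                     min(1.0, float(res.p_value) * k)))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p", "p_adjusted"])
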