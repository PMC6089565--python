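"""Longitudinal ctDNA monitoring and the sustained-increase classifier.

The monitoring rule flags a patient as a likely non-responder when the
plasma concentration of at least one of their mutations rises to twice the
baseline concentration or more, and that increase is *confirmed in the
immediately next successive sample* (both consecutive post-baseline draws
at or above the fold threshold).  Concentrations below the assay's limit
of detection are treated as zero.  Mutations undetectable at baseline are
excluded from monitoring — a fold change from zero is undefined.

Flagged patients are paired with imaging: the paired outcome is the first
radiological evaluation on or after the first exceeding blood draw, and
the lead time is the gap between that draw and the imaging date.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TimePoint",
    "ImagingEvent",
    "MonitoringCall",
    "build_timelines",
    "timelines_from_concentrations",
    "percent_change_series",
    "sustained_increase_flag",
    "classify_patient",
    "select_representative_mutation",
    "evaluate_against_imaging",
    "classification_metrics",
]

logger = logging.getLogger(__name__)

DEFAULT_FOLD_THRESHOLD = 2.0
DEFAULT_PAIRING_WINDOW_DAYS = 21.0

RECIST_OUTCOMES = ("PD", "SD", "PR", "CR")


@dataclass(frozen=True)
class TimePoint:
    """One plasma sample: per-mutation concentrations in copies/mL plasma."""

    sample_id: str
    day: float
    concentrations: dict[str, float]
    below_lod: dict[str, bool] = field(default_factory=dict)

    def effective(self, mutation: str) -> float:
        """Concentration with below-LoD values mapped to zero."""
        c = self.concentrations.get(mutation, 0.0)
        if self.below_lod.get(mutation, False):
            return 0.0
        return c


@dataclass(frozen=True)
class ImagingEvent:
    day: float
    outcome: str  # PD / SD / PR / CR
    modality: str = "CT"
    sum_diameters_mm: float | None = None

    def __post_init__(self) -> None:
        if self.outcome not in RECIST_OUTCOMES:
            raise ValueError(f"outcome must be one of {RECIST_OUTCOMES}, got {self.outcome!r}")


@dataclass(frozen=True)
class MonitoringCall:
    patient_id: str
    flagged: bool
    evaluable: bool = True
    flag_day: float | None = None  # day of the confirming (second) sample
    first_exceed_day: float | None = None
    triggering_mutation: str | None = None
    n_post_baseline: int = 0
    paired_imaging_outcome: str | None = None
    lead_time_days: float | None = None


def build_timelines(
    quant: pd.DataFrame,
    timeline: pd.DataFrame,
    exclude_assays: Sequence[str] = ("B2M",),
) -> dict[str, list[TimePoint]]:
    """Assemble per-patient ordered timelines from flat tables.

    ``quant`` needs columns sample_id, assay_id, copies_per_ml_plasma,
    below_lod; ``timeline`` needs patient_id, sample_id, day.  Samples are
    ordered by day within each patient.  Reference assays (the B2M total
    cfDNA assay by default) are excluded — they quantify background, not a
    tumour mutation.
    """
    quant_by_sample: dict[str, dict[str, tuple[float, bool]]] = {}
    excluded = set(exclude_assays)
    for _, row in quant.iterrows():
        if str(row["assay_id"]) in excluded:
            continue
        quant_by_sample.setdefault(str(row["sample_id"]), {})[str(row["assay_id"])] = (
            float(row["copies_per_ml_plasma"]),
            bool(row["below_lod"]),
        )
    timelines: dict[str, list[TimePoint]] = {}
    for pid, grp in timeline.groupby("patient_id"):
        points = []
        for _, row in grp.sort_values("day").iterrows():
            sid = str(row["sample_id"])
            assays = quant_by_sample.get(sid, {})
            points.append(
                TimePoint(
                    sample_id=sid,
                    day=float(row["day"]),
                    concentrations={a: c for a, (c, _) in assays.items()},
                    below_lod={a: b for a, (_, b) in assays.items()},
                )
            )
        timelines[str(pid)] = points
    return timelines


def timelines_from_concentrations(
    df: pd.DataFrame,
    value_col: str = "true_copies_per_ml",
) -> dict[str, list[TimePoint]]:
    """Timelines straight from a long concentration table (columns
    patient_id, sample_id, assay_id, day, ``value_col``) — used to run the
    classifier on noise-free ground-truth trajectories."""
    timelines: dict[str, list[TimePoint]] = {}
    for pid, grp in df.groupby("patient_id"):
        points = []
        for (sid, day), sub in sorted(grp.groupby(["sample_id", "day"]), key=lambda t: t[0][1]):
            points.append(
                TimePoint(
                    sample_id=str(sid),
                    day=float(day),
                    concentrations=dict(
                        zip(sub["assay_id"].astype(str), sub[value_col].astype(float))
                    ),
                )
            )
        timelines[str(pid)] = points
    return timelines


def _baseline_point(timeline: Sequence[TimePoint]) -> TimePoint:
    """Baseline = the latest sample drawn on or before day 0."""
    pre = [tp for tp in timeline if tp.day <= 0]
    if not pre:
        raise ValueError("timeline has no baseline (day <= 0) sample")
    return max(pre, key=lambda tp: tp.day)


def percent_change_series(
    timeline: Sequence[TimePoint], mutation: str
) -> list[tuple[float, float]]:
    """Percent change from baseline, per post-baseline sample.

    change = 100·(c_t − c_0)/c_0; below-LoD concentrations count as zero,
    so an undetectable follow-up reads −100%.  Raises if the mutation is
    undetectable at baseline (excluded from percent-change analysis).
    """
    base = _baseline_point(timeline)
    c0 = base.effective(mutation)
    if c0 <= 0:
        raise ValueError(
            f"mutation {mutation!r} undetectable at baseline: percent change undefined"
        )
    out = []
    for tp in timeline:
        if tp.day <= base.day:
            continue
        out.append((tp.day, 100.0 * (tp.effective(mutation) - c0) / c0))
    return out


def sustained_increase_flag(
    series: Sequence[tuple[float, float]],
    baseline: float,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
) -> tuple[bool, float | None, float | None]:
    """Detect a fold increase confirmed in the next successive sample.

    ``series`` is the post-baseline (day, concentration) sequence in time
    order.  The flag raises at the earliest pair of *consecutive* samples
    that are both at or above ``fold_threshold`` × baseline; returns
    (flagged, first_exceed_day, confirm_day).
    """
    if baseline <= 0:
        raise ValueError("baseline concentration must be positive")
    cutoff = fold_threshold * baseline
    for (d1, c1), (d2, c2) in zip(series, series[1:]):
        if c1 >= cutoff and c2 >= cutoff:
            return True, d1, d2
    return False, None, None


def classify_patient(
    patient_id: str,
    timeline: Sequence[TimePoint],
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
) -> MonitoringCall:
    """Patient-level call: flagged iff any baseline-detectable mutation shows
    a confirmed sustained increase.

    The triggering mutation is the flagging mutation with the earliest
    confirming sample; ties go to the higher baseline concentration, then
    the lexicographically smaller label.  A patient with no mutation
    detectable at baseline is marked unevaluable.
    """
    base = _baseline_point(timeline)
    post = [tp for tp in timeline if tp.day > base.day]
    eligible = sorted(m for m in base.concentrations if base.effective(m) > 0)
    if not eligible:
        logger.info("patient %s unevaluable: no mutation detectable at baseline", patient_id)
        return MonitoringCall(
            patient_id=patient_id, flagged=False, evaluable=False, n_post_baseline=len(post)
        )
    candidates = []  # (confirm_day, -baseline_conc, label, first_exceed_day)
    for m in eligible:
        c0 = base.effective(m)
        series = [(tp.day, tp.effective(m)) for tp in post]
        flagged, d_first, d_confirm = sustained_increase_flag(series, c0, fold_threshold)
        if flagged:
            candidates.append((d_confirm, -c0, m, d_first))
    if not candidates:
        return MonitoringCall(
            patient_id=patient_id, flagged=False, evaluable=True, n_post_baseline=len(post)
        )
    d_confirm, neg_c0, label, d_first = min(candidates)
    return MonitoringCall(
        patient_id=patient_id,
        flagged=True,
        evaluable=True,
        flag_day=d_confirm,
        first_exceed_day=d_first,
        triggering_mutation=label,
        n_post_baseline=len(post),
    )


def select_representative_mutation(
    timeline: Sequence[TimePoint],
    at_day: float,
    pairing_window: float = DEFAULT_PAIRING_WINDOW_DAYS,
) -> str | None:
    """Mutation with the highest concentration in the sample paired to a
    given day (the latest draw within ``pairing_window`` days before or on
    ``at_day``).  Ties break to the higher baseline concentration, then
    lexicographically.  Returns None when no draw falls in the window.
    """
    in_window = [tp for tp in timeline if tp.day <= at_day and at_day - tp.day <= pairing_window]
    if not in_window:
        return None
    paired = max(in_window, key=lambda tp: tp.day)
    if not paired.concentrations:
        return None
    base = _baseline_point(timeline)
    ranked = sorted(
        paired.concentrations,
        key=lambda m: (-paired.effective(m), -base.effective(m), m),
    )
    return ranked[0]


def evaluate_against_imaging(
    calls: Sequence[MonitoringCall],
    timelines: Mapping[str, Sequence[TimePoint]],
    imaging: Mapping[str, Sequence[ImagingEvent]],
    pairing_window: float = DEFAULT_PAIRING_WINDOW_DAYS,
) -> dict:
    """Pair monitoring calls with radiology and summarise predictive value.

    For each flagged patient the paired outcome is the first imaging event
    on or after the first exceeding draw; PPV is the fraction of those with
    progressive disease.  Flagged patients with no subsequent imaging are
    excluded from the PPV denominator and reported separately.  Also
    reports the baseline-to-last-evaluation summary: among radiological
    non-responders (last imaging PD), the fraction with at least one
    mutation above its baseline concentration in the draw paired with that
    last evaluation.
    """
    calls = sorted(calls, key=lambda c: c.patient_id)
    paired_calls: list[MonitoringCall] = []
    flagged_no_imaging: list[str] = []
    lead_times: list[float] = []
    n_flagged_pd = 0
    n_flagged_with_imaging = 0

    for call in calls:
        if not call.flagged:
            paired_calls.append(call)
            continue
        events = sorted(imaging.get(call.patient_id, []), key=lambda e: e.day)
        following = [e for e in events if e.day >= call.first_exceed_day]
        if not following:
            flagged_no_imaging.append(call.patient_id)
            paired_calls.append(call)
            continue
        ev = following[0]
        lead = ev.day - call.first_exceed_day
        lead_times.append(lead)
        n_flagged_with_imaging += 1
        if ev.outcome == "PD":
            n_flagged_pd += 1
        paired_calls.append(
            MonitoringCall(
                patient_id=call.patient_id,
                flagged=True,
                evaluable=call.evaluable,
                flag_day=call.flag_day,
                first_exceed_day=call.first_exceed_day,
                triggering_mutation=call.triggering_mutation,
                n_post_baseline=call.n_post_baseline,
                paired_imaging_outcome=ev.outcome,
                lead_time_days=lead,
            )
        )

    ppv = n_flagged_pd / n_flagged_with_imaging if n_flagged_with_imaging else None

    # Baseline-to-last-evaluation increase among radiological non-responders.
    n_nonresp = 0
    n_nonresp_increase = 0
    for pid, events in imaging.items():
        events = sorted(events, key=lambda e: e.day)
        if not events or events[-1].outcome != "PD":
            continue
        timeline = timelines.get(pid)
        if not timeline:
            continue
        last = events[-1]
        in_window = [
            tp for tp in timeline if tp.day <= last.day and last.day - tp.day <= pairing_window
        ]
        if not in_window:
            continue
        paired = max(in_window, key=lambda tp: tp.day)
        try:
            base = _baseline_point(timeline)
        except ValueError:
            continue
        eligible = [m for m in base.concentrations if base.effective(m) > 0]
        if not eligible:
            continue
        n_nonresp += 1
        if any(paired.effective(m) > base.effective(m) for m in eligible):
            n_nonresp_increase += 1

    return {
        "calls": paired_calls,
        "n_flagged": sum(c.flagged for c in calls),
        "n_flagged_with_imaging": n_flagged_with_imaging,
        "n_flagged_pd": n_flagged_pd,
        "ppv": ppv,
        "flagged_without_imaging": flagged_no_imaging,
        "lead_times_days": sorted(lead_times),
        "median_lead_time_days": float(np.median(lead_times)) if lead_times else None,
        "n_radiological_nonresponders_evaluated": n_nonresp,
        "n_nonresponders_with_ctdna_increase": n_nonresp_increase,
        "nonresponder_increase_fraction": (
            n_nonresp_increase / n_nonresp if n_nonresp else None
        ),
    }


def classification_metrics(
    calls: Sequence[MonitoringCall],
    truth_nonresponder: Mapping[str, bool],
    min_post_baseline: int = 2,
) -> dict:
    """Sensitivity/specificity/PPV of the flag against ground-truth labels.

    Restricted to evaluable patients with at least ``min_post_baseline``
    post-baseline draws (a confirmed increase needs two).
    """
    tp = fp = tn = fn = 0
    n_excluded = 0
    for call in calls:
        if not call.evaluable or call.n_post_baseline < min_post_baseline:
            n_excluded += 1
            continue
        truth = truth_nonresponder[call.patient_id]
        if call.flagged and truth:
            tp += 1
        elif call.flagged and not truth:
            fp += 1
        elif not call.flagged and truth:
            fn += 1
        else:
            tn += 1
    return {
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
        "n_excluded": n_excluded,
        "sensitivity": tp / (tp + fn) if (tp + fn) else None,
        "specificity": tn / (tn + fp) if (tn + fp) else None,
        "ppv": tp / (tp + fp) if (tp + fp) else None,
        "npv": tn / (tn + fn) if (tn + fn) else None,
    }
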