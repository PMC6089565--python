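"""Supporting clinical statistics.

RECIST 1.1 tumour-size summation (sum of longest diameters of up to five
target lesions, at most two per organ when organ labels are available),
Spearman rank correlation for the tumour-size / ctDNA-concentration
relationship, and Kaplan–Meier survival summaries including the
reverse-KM median follow-up (product-limit estimator with the event
indicator flipped, so death censors follow-up rather than ending it).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.utils import median_survival_times
from scipy import stats

__all__ = [
    "LesionSet",
    "SurvivalRecord",
    "KmSummary",
    "recist_sum",
    "spearman_correlation",
    "km_summary",
]


@dataclass(frozen=True)
class LesionSet:
    patient_id: str
    diameters_mm: tuple[float, ...]
    organs: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.diameters_mm):
            raise ValueError("lesion diameters must be positive")
        if self.organs is not None and len(self.organs) != len(self.diameters_mm):
            raise ValueError("organs must align with diameters")


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    time: float  # months from treatment start
    event: bool  # death observed

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("survival time must be positive")


class KmSummary(NamedTuple):
    median_os: float | None  # None = not reached
    ci_low: float | None
    ci_high: float | None
    median_follow_up: float | None
    n: int
    n_events: int


def recist_sum(
    diameters_mm: Sequence[float],
    max_lesions: int = 5,
    organs: Sequence[str] | None = None,
    max_per_organ: int = 2,
) -> float:
    """Sum of the largest target-lesion diameters, capped at ``max_lesions``.

    With organ labels, at most ``max_per_organ`` lesions per organ are
    eligible (RECIST 1.1); without labels the global top-``max_lesions``
    rule applies.
    """
    d = list(diameters_mm)
    if not d:
        raise ValueError("at least one lesion is required")
    if any(x <= 0 for x in d):
        raise ValueError("lesion diameters must be positive")
    if organs is not None:
        if len(organs) != len(d):
            raise ValueError("organs must align with diameters")
        eligible: list[float] = []
        per_organ: dict[str, int] = {}
        for diam, org in sorted(zip(d, organs), key=lambda t: -t[0]):
            if per_organ.get(org, 0) < max_per_organ:
                eligible.append(diam)
                per_organ[org] = per_organ.get(org, 0) + 1
        d = eligible
    return float(sum(sorted(d, reverse=True)[:max_lesions]))


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with mid-rank ties and two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("at least three pairs are required")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def km_summary(records: Sequence[SurvivalRecord], confidence: float = 0.95) -> KmSummary:
    """Kaplan–Meier median survival with log-log CI, plus reverse-KM median
    follow-up.

    The median is the earliest time at which the product-limit survival
    estimate drops to 0.5 or below; with all subjects censored it is not
    reached and reported as None.
    """
    if not records:
        raise ValueError("at least one record is required")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)

    kmf = KaplanMeierFitter(alpha=1 - confidence)
    kmf.fit(times, events)
    median = kmf.median_survival_time_
    if np.isinf(median):
        median_os, ci_low, ci_high = None, None, None
    else:
        median_os = float(median)
        ci = median_survival_times(kmf.confidence_interval_)
        lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
        ci_low = None if np.isinf(lo) else lo
        ci_high = None if np.isinf(hi) else hi

    kmf_rev = KaplanMeierFitter()
    kmf_rev.fit(times, ~events)
    mfu = kmf_rev.median_survival_time_
    median_follow_up = None if np.isinf(mfu) else float(mfu)

    return KmSummary(
        median_os=median_os,
        ci_low=ci_low,
        ci_high=ci_high,
        median_follow_up=median_follow_up,
        n=len(records),
        n_events=int(events.sum()),
    )
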