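"""Baseline variant calling from a targeted amplicon panel.

Variants come annotated (exonic status, COSMIC membership, benign-SNP
status are inputs — there is no live database lookup here).  The calling
stage applies, in order: sample-level QC on mean depth, an amplicon
performance blacklist, and a per-variant annotation + allele-frequency
filter.  A variant is called when it is exonic, reported to COSMIC, not a
benign SNP, not on a blacklisted amplicon, and its allele frequency is at
or above the threshold (default 1%).

Allele frequency is computed as 100·allele_coverage/total_coverage, where
total_coverage is the full read depth at the position.  By default the AF
is rounded to one decimal before thresholding, so a raw 0.96% that prints
as 1.0% passes a 1.0% cut-off; set ``round_before_threshold=False`` to
compare the raw value instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantRecord",
    "SampleQC",
    "AmpliconStats",
    "FilterResult",
    "compute_af",
    "qc_sample",
    "evaluate_amplicons",
    "filter_variants",
    "summarize_mutations",
]

logger = logging.getLogger(__name__)

#: Minimum mean depth for a sample to qualify.
MIN_MEAN_DEPTH = 2000.0

#: Default allele-frequency threshold, percent.
DEFAULT_AF_THRESHOLD = 1.0


@dataclass(frozen=True)
class VariantRecord:
    """One candidate mutation from the panel."""

    patient_id: str
    gene: str
    cds: str
    protein: str
    allele_coverage: int
    total_coverage: int
    exonic: bool | None = None
    cosmic_reported: bool | None = None
    benign_snp: bool | None = None
    amplicon_id: str = ""
    af: float | None = None  # percent; computed from coverages when None

    def __post_init__(self) -> None:
        if self.total_coverage <= 0:
            raise ValueError("total_coverage must be positive")
        if not 0 <= self.allele_coverage <= self.total_coverage:
            raise ValueError("allele_coverage must lie in [0, total_coverage]")
        if self.af is None:
            object.__setattr__(
                self, "af", compute_af(self.allele_coverage, self.total_coverage)
            )

    @property
    def label(self) -> str:
        return f"{self.gene} {self.cds} {self.protein}".strip()


@dataclass(frozen=True)
class SampleQC:
    sample_id: str
    mean_depth: float
    qualified: bool


@dataclass(frozen=True)
class AmpliconStats:
    amplicon_id: str
    mean_coverage_across_samples: float
    blacklisted: bool


class FilterResult(NamedTuple):
    kept: list[VariantRecord]
    rejected: list[tuple[VariantRecord, str]]


def compute_af(allele_coverage: int, total_coverage: int) -> float:
    """Allele frequency in percent: 100·allele_coverage/total_coverage."""
    if total_coverage <= 0:
        raise ValueError("total_coverage must be positive")
    if not 0 <= allele_coverage <= total_coverage:
        raise ValueError("allele_coverage must lie in [0, total_coverage]")
    return 100.0 * allele_coverage / total_coverage


def qc_sample(
    per_amplicon_depths: Sequence[float],
    sample_id: str = "",
    min_mean_depth: float = MIN_MEAN_DEPTH,
) -> SampleQC:
    """Qualify a sample when its mean per-amplicon depth is ≥ the cut-off
    (inclusive boundary)."""
    depths = np.asarray(per_amplicon_depths, dtype=float)
    if depths.size == 0:
        raise ValueError("per_amplicon_depths must be non-empty")
    mean_depth = float(depths.mean())
    return SampleQC(sample_id=sample_id, mean_depth=mean_depth, qualified=mean_depth >= min_mean_depth)


def evaluate_amplicons(
    coverage: pd.DataFrame,
    threshold: float = MIN_MEAN_DEPTH,
) -> list[AmpliconStats]:
    """Blacklist amplicons whose mean coverage across samples falls below
    ``threshold``.

    ``coverage`` is samples × amplicons (rows = samples, columns =
    amplicon ids).  One rule is applied uniformly to every amplicon.
    """
    if coverage.shape[0] < 1:
        raise ValueError("at least one sample is required")
    means = coverage.mean(axis=0)
    stats = [
        AmpliconStats(
            amplicon_id=str(amp),
            mean_coverage_across_samples=float(m),
            blacklisted=bool(m < threshold),
        )
        for amp, m in means.items()
    ]
    n_black = sum(s.blacklisted for s in stats)
    logger.info("amplicon evaluation: %d/%d blacklisted at threshold %g", n_black, len(stats), threshold)
    return stats


def filter_variants(
    records: Iterable[VariantRecord],
    blacklist: frozenset[str] | set[str] = frozenset(),
    af_threshold: float = DEFAULT_AF_THRESHOLD,
    round_before_threshold: bool = True,
) -> FilterResult:
    """Apply the calling rule to annotated variant records.

    Kept ⇔ exonic ∧ cosmic_reported ∧ ¬benign_snp ∧ amplicon not
    blacklisted ∧ AF ≥ af_threshold.  Records with a missing annotation
    flag are rejected with reason ``missing_annotation``.  Input order is
    preserved in both outputs.
    """
    kept: list[VariantRecord] = []
    rejected: list[tuple[VariantRecord, str]] = []
    for rec in records:
        reason = None
        if rec.exonic is None or rec.cosmic_reported is None or rec.benign_snp is None:
            reason = "missing_annotation"
        elif not rec.exonic:
            reason = "not_exonic"
        elif not rec.cosmic_reported:
            reason = "not_in_cosmic"
        elif rec.benign_snp:
            reason = "benign_snp"
        elif rec.amplicon_id and rec.amplicon_id in blacklist:
            reason = "blacklisted_amplicon"
        else:
            af = round(rec.af, 1) if round_before_threshold else rec.af
            if af < af_threshold:
                reason = "below_af_threshold"
        if reason is None:
            kept.append(rec)
            logger.debug("variant kept: %s %s", rec.patient_id, rec.label)
        else:
            rejected.append((rec, reason))
            logger.debug("variant rejected (%s): %s %s", reason, rec.patient_id, rec.label)
    return FilterResult(kept=kept, rejected=rejected)


def summarize_mutations(called: Sequence[VariantRecord]) -> dict:
    """Cohort summary of called variants.

    Returns per-gene counts, per-patient mutation counts (median/min/max
    computed after grouping by patient), allele-frequency order statistics
    and totals.  On empty input all counts are zero and the order
    statistics are ``None`` (flagged undefined).
    """
    if not called:
        return {
            "n_variants": 0,
            "n_patients": 0,
            "gene_counts": {},
            "per_patient": {"median": None, "min": None, "max": None},
            "af_percent": {"median": None, "min": None, "max": None},
        }
    df = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in called],
            "gene": [r.gene for r in called],
            "af": [r.af for r in called],
        }
    )
    per_patient = df.groupby("patient_id").size()
    return {
        "n_variants": int(len(df)),
        "n_patients": int(df["patient_id"].nunique()),
        "gene_counts": df["gene"].value_counts().to_dict(),
        "per_patient": {
            "median": float(per_patient.median()),
            "min": int(per_patient.min()),
            "max": int(per_patient.max()),
        },
        "af_percent": {
            "median": float(df["af"].median()),
            "min": float(df["af"].min()),
            "max": float(df["af"].max()),
        },
    }
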