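"""NGS vs ddPCR method agreement.

Paired measurements of the same mutation — the sequencing allele frequency
and the ddPCR fractional abundance, both in percent — are compared on the
log scale, where the ratio structure of dilution-type data is additive.
Only *verified* pairs (ddPCR fractional abundance > 0) enter the agreement
statistics; a mutation the ddPCR assay could not re-detect carries no
ratio information.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedMeasurement",
    "RatioSummary",
    "BlandAltmanResult",
    "RegressionResult",
    "pairs_from_frame",
    "paired_ratio_summary",
    "bland_altman",
    "regression_fit",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairedMeasurement:
    """One mutation measured by both methods, in percent."""

    patient_id: str
    mutation: str
    ngs_af: float
    ddpcr_fa: float

    @property
    def verified(self) -> bool:
        return self.ddpcr_fa > 0


class RatioSummary(NamedTuple):
    median_ratio: float  # back-transformed median log-ratio
    loa_low: float  # back-transformed mean log-ratio - 1.96 SD
    loa_high: float  # back-transformed mean log-ratio + 1.96 SD
    min_ratio: float  # raw per-pair minimum
    max_ratio: float  # raw per-pair maximum
    n: int


class BlandAltmanResult(NamedTuple):
    bias: float  # mean log difference
    loa_low: float
    loa_high: float
    ratio_bias: float  # exp(bias): geometric mean ratio
    ratio_loa_low: float
    ratio_loa_high: float
    n: int


class RegressionResult(NamedTuple):
    slope: float
    intercept: float
    r: float


def pairs_from_frame(
    df: pd.DataFrame,
    ngs_col: str = "af_percent",
    ddpcr_col: str = "fractional_abundance_percent",
    mutation_cols: Sequence[str] = ("gene", "protein"),
) -> list[PairedMeasurement]:
    """Build paired measurements from a joined variants/quantification table."""
    pairs = []
    for _, row in df.iterrows():
        pairs.append(
            PairedMeasurement(
                patient_id=str(row["patient_id"]),
                mutation=" ".join(str(row[c]) for c in mutation_cols),
                ngs_af=float(row[ngs_col]),
                ddpcr_fa=float(row[ddpcr_col]),
            )
        )
    return pairs


def _verified_log_ratios(pairs: Iterable[PairedMeasurement]) -> np.ndarray:
    ratios = []
    for p in pairs:
        if not p.verified:
            continue
        if p.ngs_af <= 0:
            logger.warning(
                "excluding pair %s %s: non-positive NGS AF", p.patient_id, p.mutation
            )
            continue
        ratios.append(math.log(p.ngs_af / p.ddpcr_fa))
    return np.asarray(ratios)


def paired_ratio_summary(pairs: Sequence[PairedMeasurement]) -> RatioSummary:
    """Median NGS/ddPCR ratio with 95% limits of agreement.

    The median is computed on log-ratios and back-transformed (geometric
    handling of the right-skew typical of percent-scale data); the interval
    is the back-transformed mean log-ratio ± 1.96·SD.  The raw per-pair
    min–max is reported alongside.
    """
    lr = _verified_log_ratios(pairs)
    if lr.size < 2:
        raise ValueError("at least two verified pairs are required")
    mean, sd = float(lr.mean()), float(lr.std(ddof=1))
    return RatioSummary(
        median_ratio=float(np.exp(np.median(lr))),
        loa_low=float(np.exp(mean - 1.96 * sd)),
        loa_high=float(np.exp(mean + 1.96 * sd)),
        min_ratio=float(np.exp(lr.min())),
        max_ratio=float(np.exp(lr.max())),
        n=int(lr.size),
    )


def bland_altman(pairs: Sequence[PairedMeasurement]) -> BlandAltmanResult:
    """Bland–Altman agreement on the log scale.

    Differences are log(NGS AF) − log(ddPCR FA); bias is their mean and the
    limits of agreement bias ± 1.96·SD (sample SD).  Back-transformed
    values are ratios of NGS to ddPCR.
    """
    lr = _verified_log_ratios(pairs)
    if lr.size < 3:
        raise ValueError("at least three verified pairs are required")
    bias = float(lr.mean())
    sd = float(lr.std(ddof=1))
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    return BlandAltmanResult(
        bias=bias,
        loa_low=lo,
        loa_high=hi,
        ratio_bias=math.exp(bias),
        ratio_loa_low=math.exp(lo),
        ratio_loa_high=math.exp(hi),
        n=int(lr.size),
    )


def regression_fit(pairs: Sequence[PairedMeasurement]) -> RegressionResult:
    """Ordinary least squares of NGS AF on ddPCR FA over verified pairs."""
    verified = [p for p in pairs if p.verified]
    if len(verified) < 3:
        raise ValueError("at least three verified pairs are required")
    x = np.array([p.ddpcr_fa for p in verified])
    y = np.array([p.ngs_af for p in verified])
    if np.ptp(x) == 0:
        raise ValueError("degenerate regressor: ddPCR values have no variance")
    fit = stats.linregress(x, y)
    return RegressionResult(slope=float(fit.slope), intercept=float(fit.intercept), r=float(fit.rvalue))
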