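"""Droplet digital PCR quantification.

A ddPCR reaction partitions template molecules into ~20 000 nanolitre-scale
droplets.  Molecules distribute across droplets following a Poisson law, so
the concentration in the reaction can be recovered from the fraction of
droplets that light up in each fluorescence channel:

    c = -ln(1 - k/n) / v_droplet          [copies/µL reaction]

where ``k`` is the number of positive droplets, ``n`` the total accepted
droplets and ``v_droplet`` the single-droplet volume (0.85 nL on the QX200
platform).  Duplex assays read a mutant channel and a wild-type channel in
the same well; droplets positive in both channels count toward both.

This module covers the quantification chain: Poisson concentration,
fractional abundance (mutant fraction of mutant + wild type), conversion to
copies per millilitre of plasma through the extraction volume chain, well
merging, and empirical limit-of-blank / limit-of-detection estimation from
blank (healthy-donor) wells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DropletCounts",
    "QuantConfig",
    "QuantResult",
    "LodResult",
    "SaturationError",
    "poisson_concentration",
    "concentration_interval",
    "fractional_abundance",
    "copies_per_ml_plasma",
    "merge_wells",
    "quantify_sample",
    "estimate_lod",
]

#: QX200 droplet volume in µL (0.85 nL).
DEFAULT_DROPLET_VOLUME_UL = 0.00085


class SaturationError(ValueError):
    """All droplets positive: the Poisson estimate is unbounded."""


@dataclass(frozen=True)
class DropletCounts:
    """Thresholded droplet counts for one duplex well.

    ``mut_positive``, ``wt_positive`` and ``double_positive`` are exclusive
    categories (single-channel positives do not include double positives);
    channel totals are exposed as properties.
    """

    sample_id: str
    assay_id: str
    droplets_total: int
    mut_positive: int
    wt_positive: int
    double_positive: int

    def __post_init__(self) -> None:
        for name in ("droplets_total", "mut_positive", "wt_positive", "double_positive"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.mut_positive + self.wt_positive + self.double_positive > self.droplets_total:
            raise ValueError(
                "mut_positive + wt_positive + double_positive exceeds droplets_total"
            )

    @property
    def mut_channel_positive(self) -> int:
        """Droplets positive in the mutant channel (single + double)."""
        return self.mut_positive + self.double_positive

    @property
    def wt_channel_positive(self) -> int:
        """Droplets positive in the wild-type channel (single + double)."""
        return self.wt_positive + self.double_positive


@dataclass(frozen=True)
class QuantConfig:
    """Volume chain from droplet to plasma.

    Defaults follow a 20 µL reaction loading 8 µL of a 100 µL cfDNA eluate
    extracted from ``plasma_volume_ml`` millilitres of plasma.
    """

    droplet_volume_ul: float = DEFAULT_DROPLET_VOLUME_UL
    reaction_volume_ul: float = 20.0
    eluate_in_reaction_ul: float = 8.0
    elution_volume_ul: float = 100.0
    plasma_volume_ml: float = 2.0

    def __post_init__(self) -> None:
        for name in (
            "droplet_volume_ul",
            "reaction_volume_ul",
            "eluate_in_reaction_ul",
            "elution_volume_ul",
            "plasma_volume_ml",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.eluate_in_reaction_ul > self.elution_volume_ul:
            raise ValueError("eluate_in_reaction_ul cannot exceed elution_volume_ul")


@dataclass(frozen=True)
class QuantResult:
    """Quantification of one assay in one sample (wells merged)."""

    sample_id: str
    assay_id: str
    c_mut: float  # copies/µL reaction
    c_wt: float  # copies/µL reaction
    fractional_abundance: float  # percent; NaN when both channels are empty
    copies_per_ml_plasma: float
    below_lod: bool
    censored_above: bool = False
    n_wells: int = 1
    droplets_total: int = 0


@dataclass(frozen=True)
class LodResult:
    """Empirical limit of blank (droplets) and limit of detection (copies/µL)."""

    assay_id: str
    lob_droplets: int
    lod_concentration: float
    n_blanks: int


def poisson_concentration(
    positive: int,
    total: int,
    droplet_volume: float = DEFAULT_DROPLET_VOLUME_UL,
) -> float:
    """Poisson-corrected concentration in copies/µL of reaction.

    Raises
    ------
    SaturationError
        If every droplet is positive (the estimate diverges).
    """
    if total <= 0:
        raise ValueError("total droplets must be positive")
    if not 0 <= positive <= total:
        raise ValueError("positive count must lie in [0, total]")
    if droplet_volume <= 0:
        raise ValueError("droplet volume must be positive")
    if positive == total:
        raise SaturationError(
            f"{positive}/{total} droplets positive: concentration unbounded"
        )
    return -math.log1p(-positive / total) / droplet_volume


def concentration_interval(
    positive: int,
    total: int,
    droplet_volume: float = DEFAULT_DROPLET_VOLUME_UL,
    confidence: float = 0.95,
) -> tuple[float, float]:
    """Clopper–Pearson interval on droplet occupancy, propagated through the
    Poisson correction.  Returns (low, high) in copies/µL reaction."""
    if positive == total:
        raise SaturationError("saturated well has no finite upper bound")
    alpha = 1.0 - confidence
    if positive == 0:
        p_lo = 0.0
    else:
        p_lo = stats.beta.ppf(alpha / 2, positive, total - positive + 1)
    p_hi = stats.beta.ppf(1 - alpha / 2, positive + 1, total - positive)
    lo = -math.log1p(-p_lo) / droplet_volume
    hi = -math.log1p(-min(p_hi, 1 - 1e-15)) / droplet_volume
    return lo, hi


def fractional_abundance(c_mut: float, c_wt: float) -> float:
    """Mutant fraction of total target, in percent: 100·c_mut/(c_mut + c_wt)."""
    if c_mut < 0 or c_wt < 0:
        raise ValueError("concentrations must be non-negative")
    if c_mut == 0 and c_wt == 0:
        raise ValueError("fractional abundance undefined when both channels are zero")
    if math.isinf(c_mut):
        return 100.0
    if math.isinf(c_wt):
        return 0.0
    return 100.0 * c_mut / (c_mut + c_wt)


def copies_per_ml_plasma(c_mut: float, config: QuantConfig) -> float:
    """Convert a reaction concentration to copies per mL of source plasma.

    copies/reaction = c_mut · reaction_volume; dividing by the eluate volume
    loaded gives copies/µL eluate; multiplying by the elution volume gives
    total extracted copies; dividing by the plasma volume gives copies/mL.
    """
    if c_mut < 0:
        raise ValueError("concentration must be non-negative")
    copies_per_reaction = c_mut * config.reaction_volume_ul
    copies_per_ul_eluate = copies_per_reaction / config.eluate_in_reaction_ul
    total_copies = copies_per_ul_eluate * config.elution_volume_ul
    return total_copies / config.plasma_volume_ml


def merge_wells(wells: Sequence[DropletCounts]) -> DropletCounts:
    """Merge replicate wells of one assay by summing droplet counts.

    Counts are pooled *before* the Poisson step — equivalent to treating the
    replicates as one large partition set — rather than averaging per-well
    estimates, which would be biased at low counts.
    """
    if not wells:
        raise ValueError("no wells to merge")
    assay_ids = {w.assay_id for w in wells}
    if len(assay_ids) > 1:
        raise ValueError(f"cannot merge wells from different assays: {sorted(assay_ids)}")
    return DropletCounts(
        sample_id=wells[0].sample_id,
        assay_id=wells[0].assay_id,
        droplets_total=sum(w.droplets_total for w in wells),
        mut_positive=sum(w.mut_positive for w in wells),
        wt_positive=sum(w.wt_positive for w in wells),
        double_positive=sum(w.double_positive for w in wells),
    )


def quantify_sample(
    wells: Iterable[DropletCounts],
    config: QuantConfig,
    lod: Mapping[str, LodResult] | LodResult | None = None,
) -> dict[str, QuantResult]:
    """Quantify every assay present in ``wells`` for one sample.

    Wells sharing an assay_id are merged (summed) before the Poisson step.
    Double-positive droplets count toward both channels.  ``below_lod`` is
    set when the merged mutant-channel positive count does not exceed the
    assay's limit of blank (0 when no LoD is supplied).  A saturated channel
    is flagged ``censored_above`` with infinite concentration.
    """
    by_assay: dict[str, list[DropletCounts]] = {}
    for w in wells:
        by_assay.setdefault(w.assay_id, []).append(w)
    if not by_assay:
        raise ValueError("no wells supplied")

    results: dict[str, QuantResult] = {}
    for assay_id, assay_wells in sorted(by_assay.items()):
        merged = merge_wells(assay_wells)
        if isinstance(lod, LodResult):
            lob = lod.lob_droplets if lod.assay_id == assay_id else 0
        elif lod is not None and assay_id in lod:
            lob = lod[assay_id].lob_droplets
        else:
            lob = 0

        censored = False
        try:
            c_mut = poisson_concentration(
                merged.mut_channel_positive, merged.droplets_total, config.droplet_volume_ul
            )
        except SaturationError:
            c_mut, censored = math.inf, True
        try:
            c_wt = poisson_concentration(
                merged.wt_channel_positive, merged.droplets_total, config.droplet_volume_ul
            )
        except SaturationError:
            c_wt, censored = math.inf, True

        if c_mut == 0 and c_wt == 0:
            fa = math.nan
        else:
            fa = fractional_abundance(c_mut, c_wt)
        cpm = math.inf if math.isinf(c_mut) else copies_per_ml_plasma(c_mut, config)
        results[assay_id] = QuantResult(
            sample_id=merged.sample_id,
            assay_id=assay_id,
            c_mut=c_mut,
            c_wt=c_wt,
            fractional_abundance=fa,
            copies_per_ml_plasma=cpm,
            below_lod=merged.mut_channel_positive <= lob,
            censored_above=censored,
            n_wells=len(assay_wells),
            droplets_total=merged.droplets_total,
        )
    return results


def estimate_lod(
    blank_counts: Sequence[int],
    n_droplets: int,
    droplet_volume: float = DEFAULT_DROPLET_VOLUME_UL,
    confidence: float = 0.95,
    assay_id: str = "",
) -> LodResult:
    """Limit of blank and limit of detection from blank-well droplet counts.

    The limit of blank is the smallest integer at or above the
    ``confidence``-quantile of the blank positive-droplet counts.  The limit
    of detection is the lowest concentration whose Poisson-distributed
    droplet count exceeds the LoB with probability ≥ ``confidence``:

        LoD = min { c : P[Poisson(c·v·n) > LoB] ≥ confidence }.

    With all-blank wells at zero this reduces to -ln(1-confidence)/(v·n).
    """
    blank_counts = list(blank_counts)
    if not blank_counts:
        raise ValueError("at least one blank well is required")
    if any(b < 0 for b in blank_counts):
        raise ValueError("blank counts must be non-negative")
    if n_droplets <= 0 or droplet_volume <= 0:
        raise ValueError("n_droplets and droplet_volume must be positive")
    if not 0 < confidence < 1:
        raise ValueError("confidence must lie in (0, 1)")

    lob = int(math.ceil(float(np.quantile(blank_counts, confidence))))

    # Smallest Poisson mean lam with P[X > lob] >= confidence, then c = lam/(v n).
    def shortfall(lam: float) -> float:
        return stats.poisson.sf(lob, lam) - confidence

    lo, hi = 1e-12, 10.0
    while shortfall(hi) < 0:
        hi *= 2.0
    from scipy.optimize import brentq

    lam = brentq(shortfall, lo, hi, xtol=1e-12, rtol=1e-12)
    lod_c = lam / (droplet_volume * n_droplets)
    return LodResult(
        assay_id=assay_id,
        lob_droplets=lob,
        lod_concentration=float(lod_c),
        n_blanks=len(blank_counts),
    )
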