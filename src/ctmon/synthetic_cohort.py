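"""Synthetic ctDNA-monitoring cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes for an advanced NSCLC cohort monitored under treatment:

* baseline mutation profiles — 1–5 mutations per patient (median 2), a
  TP53/KRAS-dominated gene spectrum, and percent-scale allele frequencies
  drawn from a clipped log-normal with median ~2.5% and range ~1–71%;
* per-mutation exponential concentration kinetics with a shared patient
  rate (negative for responders, positive for non-responders) plus a small
  per-mutation jitter;
* monthly (28-day) blood draws from a baseline sample at day 0, a first
  radiological evaluation 9–11 weeks into treatment and further scans every
  12 weeks, with RECIST 1.1 outcomes derived from a power-law link between
  total ctDNA burden and the sum of target-lesion diameters;
* droplet-level measurement noise: duplex wells are simulated by Poisson
  partitioning of the reaction concentration over ~20 000 droplets, with an
  optional per-droplet false-positive rate, and NGS allele counts are
  binomial draws at the sequenced depth.

Every stochastic choice descends from one root seed through per-patient
child streams keyed by a stable hash of the patient id, so cohorts are
reproducible and invariant to patient reordering.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ddpcr_quant import DropletCounts, QuantConfig

__all__ = [
    "CohortConfig",
    "Mutation",
    "SimPatient",
    "Cohort",
    "PANEL_AMPLICONS",
    "POOR_AMPLICONS",
    "simulate_cohort",
    "simulate_droplet_counts",
    "simulate_ngs_reads",
    "tumour_burden_trajectory",
]

#: The five amplicons of the 92-amplicon lung–colon panel that perform
#: poorly and are excluded from analysis.
POOR_AMPLICONS: tuple[str, ...] = (
    "CHP2_ERBB4_1",
    "CHP2_PTEN_2",
    "ON_DDR2_3",
    "CHP2_AKT1_1",
    "CHP2_NOTCH1_1",
)

#: Full 92-amplicon panel: the five named poor performers plus synthetic ids.
PANEL_AMPLICONS: tuple[str, ...] = POOR_AMPLICONS + tuple(
    f"AMP_{i:03d}" for i in range(6, 93)
)

#: Genes outside TP53/KRAS seen on the panel, used for the 'OTHER' weight.
OTHER_GENES: tuple[str, ...] = (
    "MET",
    "EGFR",
    "SMAD4",
    "STK11",
    "PIK3CA",
    "ERBB4",
    "BRAF",
    "NRAS",
)


@dataclass
class CohortConfig:
    """Generator parameters; defaults reproduce the cohort structure the
    analysis targets (40 patients, 90% sequencing success, 58% with
    detectable ctDNA, TP53 20/41 / KRAS 13/41 gene spectrum, AF log-normal
    with median 2.5% clipped to [1, 75]%, monthly draws, first imaging at
    9–11 weeks then every 12 weeks)."""

    n_patients: int = 40
    seed: int = 0
    p_sequencing_success: float = 0.9
    p_detectable: float = 21 / 36
    mutations_per_patient_weights: tuple[float, ...] = (10 / 21, 5 / 21, 4 / 21, 1 / 21, 1 / 21)
    gene_weights: dict = field(
        default_factory=lambda: {"TP53": 20 / 41, "KRAS": 13 / 41, "OTHER": 8 / 41}
    )
    baseline_af_log_median: float = 2.5  # percent
    baseline_af_log_sd: float = 1.0  # sd of log(AF%)
    af_bounds: tuple[float, float] = (1.0, 75.0)  # percent
    responder_fraction: float = 3 / 21
    growth_rate_range_nonresponder: tuple[float, float] = (0.025, 0.06)  # per day
    decay_rate_range_responder: tuple[float, float] = (-0.06, -0.015)  # per day
    rate_jitter_sd: float = 0.1  # relative, per mutation
    sample_interval_days: float = 28.0
    first_imaging_window_days: tuple[float, float] = (63.0, 77.0)
    imaging_interval_days: float = 84.0
    max_followup_days: float = 308.0
    day_noise_sd: float = 0.0  # lognormal sd of per-sample biological noise
    droplets_per_well: int = 20000
    droplet_volume_ul: float = 0.00085
    false_positive_rate: float = 0.0  # per droplet
    n_blank_wells: int = 12
    cfdna_log_median: float = 6000.0  # wild-type background, copies/mL plasma
    cfdna_log_sd: float = 0.8
    tumour_size_range_mm: tuple[float, float] = (38.0, 231.0)
    size_exponent: float = 1.0 / 3.0
    os_log_median_days: float = 210.0
    os_log_sd: float = 0.6
    mean_ngs_depth: float = 4000.0
    ngs_depth_log_sd: float = 0.25

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        for name, p in (
            ("p_sequencing_success", self.p_sequencing_success),
            ("p_detectable", self.p_detectable),
            ("responder_fraction", self.responder_fraction),
        ):
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        w = np.asarray(self.mutations_per_patient_weights, dtype=float)
        if w.size != 5 or (w < 0).any() or abs(w.sum() - 1) > 1e-9:
            raise ValueError("mutations_per_patient_weights must be 5 non-negative weights summing to 1")
        g = np.asarray(list(self.gene_weights.values()), dtype=float)
        if (g < 0).any() or abs(g.sum() - 1) > 1e-9:
            raise ValueError("gene_weights must be non-negative and sum to 1")
        if self.af_bounds[0] <= 0 or self.af_bounds[0] >= self.af_bounds[1]:
            raise ValueError("af_bounds must be an increasing positive interval")
        if self.droplets_per_well <= 0 or self.droplet_volume_ul <= 0:
            raise ValueError("droplets_per_well and droplet_volume_ul must be positive")
        if not 0 <= self.false_positive_rate < 1:
            raise ValueError("false_positive_rate must lie in [0, 1)")
        lo, hi = self.growth_rate_range_nonresponder
        if not (0 < lo <= hi):
            raise ValueError("growth_rate_range_nonresponder must be positive and increasing")
        lo, hi = self.decay_rate_range_responder
        if not (lo <= hi < 0):
            raise ValueError("decay_rate_range_responder must be negative")

    @property
    def quant_config(self) -> QuantConfig:
        return QuantConfig(droplet_volume_ul=self.droplet_volume_ul)


@dataclass(frozen=True)
class Mutation:
    gene: str
    label: str
    cds: str
    protein: str
    amplicon_id: str
    baseline_af_percent: float
    baseline_copies_per_ml: float
    kinetic_rate: float  # per day


@dataclass
class SimPatient:
    patient_id: str
    sequenced: bool
    detectable: bool
    responder: bool
    mutations: list[Mutation]
    kinetic_rate: float  # shared patient rate, per day
    tumour_size_baseline_mm: float
    os_days: float
    plasma_volume_ml: float  # in [1, 2]
    cfdna_background_per_ml: float

    def __post_init__(self) -> None:
        if self.detectable and not self.mutations:
            raise ValueError("detectable patient must carry at least one mutation")
        if not 1.0 <= self.plasma_volume_ml <= 2.0:
            raise ValueError("plasma_volume_ml must lie in [1, 2]")
        for m in self.mutations:
            if self.responder and m.kinetic_rate >= 0:
                raise ValueError("responder mutations must have negative kinetic rates")
            if not self.responder and m.kinetic_rate <= 0:
                raise ValueError("non-responder mutations must have positive kinetic rates")


def _patient_rng(seed: int, patient_id: str) -> np.random.Generator:
    """Child stream keyed by a stable hash of the patient id; invariant to
    the order in which patients are generated."""
    child = zlib.crc32(patient_id.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed), child]))


def simulate_droplet_counts(
    true_concentration: float,
    n_droplets: int,
    droplet_volume: float,
    fp_rate: float,
    rng: np.random.Generator,
    wt_concentration: float = 0.0,
    sample_id: str = "",
    assay_id: str = "",
) -> DropletCounts:
    """Simulate one duplex well by Poisson partitioning.

    A droplet is mutant-positive with probability 1 − exp(−c·v), inflated
    by the per-droplet false-positive rate on otherwise-negative droplets;
    the wild-type channel is simulated analogously and the two channels
    partition independently into single- and double-positive categories.
    """
    if true_concentration < 0 or wt_concentration < 0:
        raise ValueError("concentrations must be non-negative")
    p_mut = -math.expm1(-true_concentration * droplet_volume)
    p_wt = -math.expm1(-wt_concentration * droplet_volume)
    p_mut = p_mut + fp_rate * (1 - p_mut)
    p_wt = p_wt + fp_rate * (1 - p_wt)
    probs = [
        p_mut * (1 - p_wt),  # mutant only
        (1 - p_mut) * p_wt,  # wild type only
        p_mut * p_wt,  # double
    ]
    probs.append(1.0 - sum(probs))
    mut_only, wt_only, double, _ = rng.multinomial(n_droplets, probs)
    return DropletCounts(
        sample_id=sample_id,
        assay_id=assay_id,
        droplets_total=n_droplets,
        mut_positive=int(mut_only),
        wt_positive=int(wt_only),
        double_positive=int(double),
    )


def simulate_ngs_reads(
    true_af: float, depth: int, rng: np.random.Generator
) -> tuple[int, int]:
    """Binomial allele counts at a sequenced position: returns
    (allele_coverage, total_coverage)."""
    if not 0 <= true_af <= 1:
        raise ValueError("true_af must lie in [0, 1]")
    if depth <= 0:
        raise ValueError("depth must be positive")
    return int(rng.binomial(depth, true_af)), int(depth)


def tumour_burden_trajectory(
    patient: SimPatient, t: float, exponent: float = 1.0 / 3.0
) -> float:
    """Sum of target-lesion diameters (mm) at day ``t``.

    The total true ctDNA burden B(t) = Σ c₀·exp(rate·t) is linked to size
    through a power law, size(t) = size₀ · (B(t)/B(0))^exponent, so size is
    a monotone transform of burden; the default exponent 1/3 treats burden
    as proportional to tumour volume and size as a linear dimension.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    if not patient.mutations:
        return patient.tumour_size_baseline_mm
    b0 = sum(m.baseline_copies_per_ml for m in patient.mutations)
    bt = sum(m.baseline_copies_per_ml * math.exp(m.kinetic_rate * t) for m in patient.mutations)
    return patient.tumour_size_baseline_mm * (bt / b0) ** exponent


def _recist_outcome(current: float, nadir: float, baseline: float) -> str:
    """RECIST 1.1 from sums of diameters: PD on a ≥20% and ≥5 mm increase
    from nadir; PR on a ≥30% decrease from baseline; CR at zero; else SD."""
    if current == 0:
        return "CR"
    if current >= 1.2 * nadir and current - nadir >= 5.0:
        return "PD"
    if current <= 0.7 * baseline:
        return "PR"
    return "SD"


@dataclass
class Cohort:
    """A generated cohort: ground truth plus every measurement table the
    pipeline stages consume."""

    config: CohortConfig
    patients: list[SimPatient]
    variants: pd.DataFrame  # baseline NGS candidate variants (with decoys)
    droplets: pd.DataFrame  # per-well duplex droplet counts
    blanks: pd.DataFrame  # blank wells for LoB/LoD estimation
    timeline: pd.DataFrame  # patient_id, sample_id, day, plasma_volume_ml
    imaging: pd.DataFrame  # patient_id, day, modality, outcome, sum_diameters_mm
    truth: pd.DataFrame  # per-patient ground-truth labels
    true_concentrations: pd.DataFrame  # per sample × mutation, copies/mL
    amplicon_coverage: pd.DataFrame  # samples × amplicons read depth
    assays: pd.DataFrame  # registry: assay_id ↔ (patient, gene, cds, protein)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        from . import io as ctio

        return ctio.write_cohort(self, Path(out_dir))


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full cohort under ``config``; deterministic given the seed."""
    config.validate()
    qc = config.quant_config
    genes = list(config.gene_weights)
    gene_p = np.asarray([config.gene_weights[g] for g in genes], dtype=float)

    patients: list[SimPatient] = []
    variant_rows: list[dict] = []
    droplet_rows: list[dict] = []
    blank_rows: list[dict] = []
    timeline_rows: list[dict] = []
    imaging_rows: list[dict] = []
    truth_rows: list[dict] = []
    conc_rows: list[dict] = []
    assay_rows: list[dict] = []
    coverage_rows: dict[str, np.ndarray] = {}

    for i in range(config.n_patients):
        pid = f"P{i + 1:04d}"
        rng = _patient_rng(config.seed, pid)

        sequenced = bool(rng.random() < config.p_sequencing_success)
        detectable = bool(sequenced and rng.random() < config.p_detectable)
        responder = bool(rng.random() < config.responder_fraction)
        plasma_ml = float(rng.uniform(1.0, 2.0))
        cfdna = float(rng.lognormal(math.log(config.cfdna_log_median), config.cfdna_log_sd))
        size0 = float(rng.uniform(*config.tumour_size_range_mm))
        os_days = float(rng.lognormal(math.log(config.os_log_median_days), config.os_log_sd))
        if responder:
            rate = float(rng.uniform(*config.decay_rate_range_responder))
        else:
            rate = float(rng.uniform(*config.growth_rate_range_nonresponder))

        mutations: list[Mutation] = []
        if detectable:
            k = int(rng.choice(np.arange(1, 6), p=np.asarray(config.mutations_per_patient_weights)))
            for j in range(k):
                g = str(rng.choice(genes, p=gene_p))
                if g == "OTHER":
                    g = str(rng.choice(OTHER_GENES))
                af = float(
                    np.clip(
                        rng.lognormal(math.log(config.baseline_af_log_median), config.baseline_af_log_sd),
                        config.af_bounds[0],
                        config.af_bounds[1],
                    )
                )
                jitter = float(np.clip(1.0 + rng.normal(0.0, config.rate_jitter_sd), 0.1, None))
                mutations.append(
                    Mutation(
                        gene=g,
                        label=f"{pid}_{g}_m{j + 1}",
                        cds=f"c.{101 + j}A>G",
                        protein=f"p.X{101 + j}Y",
                        amplicon_id=str(
                            rng.choice([a for a in PANEL_AMPLICONS if a not in POOR_AMPLICONS])
                        ),
                        baseline_af_percent=af,
                        baseline_copies_per_ml=af / 100.0 * cfdna,
                        kinetic_rate=rate * jitter,
                    )
                )
        for m in mutations:
            assay_rows.append(
                {
                    "assay_id": m.label,
                    "patient_id": pid,
                    "gene": m.gene,
                    "cds": m.cds,
                    "protein": m.protein,
                    "annealing_temp_c": 55.0,
                }
            )
        patient = SimPatient(
            patient_id=pid,
            sequenced=sequenced,
            detectable=detectable,
            responder=responder,
            mutations=mutations,
            kinetic_rate=rate,
            tumour_size_baseline_mm=size0,
            os_days=os_days,
            plasma_volume_ml=plasma_ml,
            cfdna_background_per_ml=cfdna,
        )
        patients.append(patient)

        # ---- imaging schedule and progression-driven stop ----------------
        horizon = min(os_days, config.max_followup_days)
        img_day = float(rng.uniform(*config.first_imaging_window_days))
        nadir = size0
        stop_day = horizon
        while img_day <= horizon:
            size = tumour_burden_trajectory(patient, img_day, config.size_exponent)
            outcome = _recist_outcome(size, nadir, size0)
            imaging_rows.append(
                {
                    "patient_id": pid,
                    "day": round(img_day, 1),
                    "modality": "CT",
                    "outcome": outcome,
                    "sum_diameters_mm": round(size, 1),
                }
            )
            if outcome == "PD":
                stop_day = img_day
                break
            nadir = min(nadir, size)
            img_day += config.imaging_interval_days

        # ---- blood draws: baseline then monthly until stop ---------------
        draw_days = np.arange(0.0, stop_day + 1e-9, config.sample_interval_days)
        sample_ids = [f"{pid}_S{k:02d}" for k in range(len(draw_days))]
        for sid, day in zip(sample_ids, draw_days):
            timeline_rows.append(
                {
                    "patient_id": pid,
                    "sample_id": sid,
                    "day": float(day),
                    "plasma_volume_ml": round(plasma_ml, 3),
                }
            )

        # ---- measurements -------------------------------------------------
        sample_qc = QuantConfig(
            droplet_volume_ul=config.droplet_volume_ul, plasma_volume_ml=plasma_ml
        )
        # copies/mL plasma -> copies/µL reaction
        to_reaction = (
            plasma_ml
            / sample_qc.elution_volume_ul
            * sample_qc.eluate_in_reaction_ul
            / sample_qc.reaction_volume_ul
        )
        for sid, day in zip(sample_ids, draw_days):
            noise = (
                float(rng.lognormal(0.0, config.day_noise_sd)) if config.day_noise_sd > 0 else 1.0
            )
            for m in mutations:
                kinetic = m.baseline_copies_per_ml * math.exp(m.kinetic_rate * day)
                true_c = kinetic * noise
                conc_rows.append(
                    {
                        "patient_id": pid,
                        "sample_id": sid,
                        "assay_id": m.label,
                        "day": float(day),
                        "kinetic_copies_per_ml": kinetic,
                        "true_copies_per_ml": true_c,
                    }
                )
                well = simulate_droplet_counts(
                    true_c * to_reaction,
                    config.droplets_per_well,
                    config.droplet_volume_ul,
                    config.false_positive_rate,
                    rng,
                    wt_concentration=cfdna * to_reaction,
                    sample_id=sid,
                    assay_id=m.label,
                )
                droplet_rows.append(asdict(well))
            # total cfDNA via the B2M reference assay
            b2m = simulate_droplet_counts(
                cfdna * to_reaction,
                config.droplets_per_well,
                config.droplet_volume_ul,
                config.false_positive_rate,
                rng,
                sample_id=sid,
                assay_id="B2M",
            )
            droplet_rows.append(asdict(b2m))

        # blank wells (healthy-donor plasma) for per-assay LoB/LoD
        for m in mutations:
            for b in range(config.n_blank_wells):
                well = simulate_droplet_counts(
                    0.0,
                    config.droplets_per_well,
                    config.droplet_volume_ul,
                    config.false_positive_rate,
                    rng,
                    sample_id=f"BLANK_{pid}_{b:02d}",
                    assay_id=m.label,
                )
                blank_rows.append(asdict(well))

        # ---- baseline NGS table (true mutations + decoy rows) -------------
        if sequenced:
            depths = rng.lognormal(math.log(3200.0), 0.3, size=len(PANEL_AMPLICONS))
        else:
            depths = rng.lognormal(math.log(600.0), 0.5, size=len(PANEL_AMPLICONS))
        poor_mask = np.isin(PANEL_AMPLICONS, POOR_AMPLICONS)
        depths[poor_mask] = rng.lognormal(math.log(250.0), 0.5, size=poor_mask.sum())
        coverage_rows[f"{pid}_S00"] = depths

        if sequenced:
            def ngs_row(gene, cds, protein, af_pct, exonic, cosmic, benign, amplicon):
                depth = int(rng.lognormal(math.log(config.mean_ngs_depth), config.ngs_depth_log_sd))
                depth = max(depth, 100)
                alt, tot = simulate_ngs_reads(af_pct / 100.0, depth, rng)
                return {
                    "patient_id": pid,
                    "gene": gene,
                    "cds": cds,
                    "protein": protein,
                    "allele_coverage": alt,
                    "total_coverage": tot,
                    "exonic": exonic,
                    "cosmic": cosmic,
                    "benign_snp": benign,
                    "amplicon_id": amplicon,
                }

            for m in mutations:
                variant_rows.append(
                    ngs_row(m.gene, m.cds, m.protein, m.baseline_af_percent, True, True, False, m.amplicon_id)
                )
            # germline benign SNPs near 50% AF
            for j in range(int(rng.integers(1, 4))):
                variant_rows.append(
                    ngs_row(
                        str(rng.choice(OTHER_GENES)),
                        f"c.{900 + j}G>A",
                        f"p.S{900 + j}N",
                        float(np.clip(rng.normal(50.0, 5.0), 30.0, 70.0)),
                        True,
                        False,
                        True,
                        str(rng.choice(PANEL_AMPLICONS)),
                    )
                )
            # sequencing artifacts: non-exonic, sub-threshold, blacklisted-amplicon
            if rng.random() < 0.5:
                variant_rows.append(
                    ngs_row(str(rng.choice(OTHER_GENES)), "c.-12C>T", "p.?", float(rng.uniform(1.0, 5.0)),
                            False, True, False, str(rng.choice(PANEL_AMPLICONS)))
                )
            if rng.random() < 0.5:
                variant_rows.append(
                    ngs_row(str(rng.choice(OTHER_GENES)), "c.555T>C", "p.F185L", float(rng.uniform(0.1, 0.7)),
                            True, True, False, str(rng.choice(PANEL_AMPLICONS)))
                )
            if rng.random() < 0.3:
                variant_rows.append(
                    ngs_row("PTEN", "c.800del", "p.K267fs", float(rng.uniform(1.0, 4.0)),
                            True, True, False, str(rng.choice(POOR_AMPLICONS)))
                )

        truth_rows.append(
            {
                "patient_id": pid,
                "sequenced": sequenced,
                "detectable": detectable,
                "responder": responder,
                "nonresponder": not responder,
                "n_mutations": len(mutations),
                "kinetic_rate_per_day": rate,
                "os_days": round(os_days, 1),
                "tumour_size_baseline_mm": round(size0, 1),
                "cfdna_background_per_ml": round(cfdna, 1),
            }
        )

    amplicon_coverage = pd.DataFrame.from_dict(
        coverage_rows, orient="index", columns=list(PANEL_AMPLICONS)
    )
    amplicon_coverage.index.name = "sample_id"

    empty = lambda cols: pd.DataFrame(columns=cols)
    return Cohort(
        config=config,
        patients=patients,
        variants=pd.DataFrame(variant_rows)
        if variant_rows
        else empty(
            ["patient_id", "gene", "cds", "protein", "allele_coverage", "total_coverage",
             "exonic", "cosmic", "benign_snp", "amplicon_id"]
        ),
        droplets=pd.DataFrame(droplet_rows),
        blanks=pd.DataFrame(blank_rows)
        if blank_rows
        else empty(
            ["sample_id", "assay_id", "droplets_total", "mut_positive", "wt_positive", "double_positive"]
        ),
        timeline=pd.DataFrame(timeline_rows),
        imaging=pd.DataFrame(imaging_rows)
        if imaging_rows
        else empty(["patient_id", "day", "modality", "outcome", "sum_diameters_mm"]),
        truth=pd.DataFrame(truth_rows),
        true_concentrations=pd.DataFrame(conc_rows)
        if conc_rows
        else empty(
            ["patient_id", "sample_id", "assay_id", "day", "kinetic_copies_per_ml", "true_copies_per_ml"]
        ),
        amplicon_coverage=amplicon_coverage,
        assays=pd.DataFrame(assay_rows)
        if assay_rows
        else empty(["assay_id", "patient_id", "gene", "cds", "protein", "annealing_temp_c"]),
    )
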