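"""End-to-end orchestration: simulate → call → quantify → concord →
monitor → report.

Each stage reads and writes flat files under the run directory, so stages
can also be run individually from the command line on externally supplied
data.  One seed governs every stochastic stage; a run manifest records
inputs, parameters and the package version.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import cohort_stats, concordance, io as ctio, monitoring, ngs_calling
from .ddpcr_quant import QuantConfig, estimate_lod, quantify_sample
from .synthetic_cohort import CohortConfig, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "run_pipeline",
    "stage_call",
    "stage_quantify",
    "stage_concord",
    "stage_monitor",
    "stage_report",
    "analyze_table2",
]


def _write_json(obj, path: Path) -> Path:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, Path):
            return str(o)
        if hasattr(o, "_asdict"):
            return o._asdict()
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        raise TypeError(f"not JSON serialisable: {type(o)}")

    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, default=default, allow_nan=True))
    return path


def stage_call(
    variants_path: Path,
    coverage_path: Path | None,
    out_dir: Path,
    af_threshold: float = 1.0,
    amplicon_threshold: float = 2000.0,
    round_before_threshold: bool = True,
) -> dict:
    """Sample QC, amplicon blacklist and variant filtering."""
    out_dir.mkdir(parents=True, exist_ok=True)
    records = ctio.read_variants(variants_path)

    blacklist: set[str] = set()
    qc_failed: list[str] = []
    if coverage_path is not None and Path(coverage_path).exists():
        coverage = pd.read_csv(coverage_path, index_col="sample_id")
        qcs = [ngs_calling.qc_sample(row.to_numpy(), sample_id=str(sid))
               for sid, row in coverage.iterrows()]
        qc_failed = [q.sample_id for q in qcs if not q.qualified]
        qualified = coverage.loc[[q.sample_id for q in qcs if q.qualified]]
        if len(qualified):
            amp_stats = ngs_calling.evaluate_amplicons(qualified, threshold=amplicon_threshold)
            blacklist = {a.amplicon_id for a in amp_stats if a.blacklisted}
        # variants from disqualified samples are dropped before filtering
        failed_patients = {sid.rsplit("_S", 1)[0] for sid in qc_failed}
        records = [r for r in records if r.patient_id not in failed_patients]

    result = ngs_calling.filter_variants(
        records, blacklist=blacklist, af_threshold=af_threshold,
        round_before_threshold=round_before_threshold,
    )
    summary = ngs_calling.summarize_mutations(result.kept)
    summary["n_rejected"] = len(result.rejected)
    summary["rejection_reasons"] = (
        pd.Series([reason for _, reason in result.rejected]).value_counts().to_dict()
        if result.rejected else {}
    )
    summary["blacklisted_amplicons"] = sorted(blacklist)
    summary["qc_failed_samples"] = qc_failed

    ctio.write_variants(result.kept, out_dir / "called_variants.tsv")
    _write_json(summary, out_dir / "calling_summary.json")
    return summary


def stage_quantify(
    droplets_path: Path,
    timeline_path: Path,
    out_dir: Path,
    blanks_path: Path | None = None,
    quant_config: QuantConfig | None = None,
    lod_confidence: float = 0.95,
) -> pd.DataFrame:
    """Per-assay LoD from blanks, then merged-well quantification of every
    sample with its own plasma volume."""
    out_dir.mkdir(parents=True, exist_ok=True)
    base_cfg = quant_config or QuantConfig()
    droplets = ctio.read_droplets(droplets_path)
    timeline = pd.read_csv(timeline_path)
    plasma_by_sample = dict(zip(timeline["sample_id"].astype(str), timeline["plasma_volume_ml"]))

    lods = {}
    if blanks_path is not None and Path(blanks_path).exists():
        blanks = pd.read_csv(blanks_path)
        if len(blanks):
            n_droplets = int(blanks["droplets_total"].median())
            for assay_id, grp in blanks.groupby("assay_id"):
                counts = (grp["mut_positive"] + grp["double_positive"]).tolist()
                lods[str(assay_id)] = estimate_lod(
                    counts, n_droplets, base_cfg.droplet_volume_ul,
                    confidence=lod_confidence, assay_id=str(assay_id),
                )
    if lods:
        lod_df = pd.DataFrame(
            [{"assay_id": l.assay_id, "lob_droplets": l.lob_droplets,
              "lod_copies_per_ul": l.lod_concentration, "n_blanks": l.n_blanks}
             for l in lods.values()]
        )
        lod_df.to_csv(out_dir / "lod.tsv", sep="\t", index=False)

    results = []
    for sid, grp in droplets.groupby("sample_id"):
        wells = ctio.droplet_counts_from_frame(grp)
        plasma = float(plasma_by_sample.get(str(sid), base_cfg.plasma_volume_ml))
        cfg = replace(base_cfg, plasma_volume_ml=plasma)
        results.extend(quantify_sample(wells, cfg, lod=lods or None).values())
    ctio.write_quant_results(results, out_dir / "quant.tsv")
    return pd.read_csv(out_dir / "quant.tsv", sep="\t")


def stage_concord(
    called_path: Path,
    quant_path: Path,
    assays_path: Path,
    timeline_path: Path,
    out_dir: Path,
) -> dict:
    """Join baseline NGS calls with baseline ddPCR fractional abundances and
    summarise agreement."""
    out_dir.mkdir(parents=True, exist_ok=True)
    called = pd.read_csv(called_path, sep="\t")
    quant = pd.read_csv(quant_path, sep="\t")
    assays = pd.read_csv(assays_path)
    timeline = pd.read_csv(timeline_path)

    baseline_samples = (
        timeline[timeline["day"] <= 0].sort_values("day").groupby("patient_id").tail(1)
    )
    base_map = dict(zip(baseline_samples["patient_id"].astype(str),
                        baseline_samples["sample_id"].astype(str)))

    called = called.copy()
    called["af_percent"] = 100.0 * called["allele_coverage"] / called["total_coverage"]
    joined = called.merge(assays, on=["patient_id", "gene", "cds", "protein"], how="inner")
    joined["sample_id"] = joined["patient_id"].astype(str).map(base_map)
    joined = joined.merge(
        quant[["sample_id", "assay_id", "fractional_abundance", "below_lod"]],
        on=["sample_id", "assay_id"], how="inner",
    )
    # a mutation is verified when ddPCR re-detects it above the limit of blank
    joined["fa_effective"] = joined["fractional_abundance"].where(~joined["below_lod"], 0.0)

    pairs = concordance.pairs_from_frame(
        joined, ngs_col="af_percent", ddpcr_col="fa_effective",
        mutation_cols=("gene", "cds", "protein"),
    )
    out = {"n_pairs": len(pairs), "n_verified": sum(p.verified for p in pairs)}
    if out["n_verified"] >= 3:
        out["ratio_summary"] = concordance.paired_ratio_summary(pairs)._asdict()
        out["bland_altman"] = concordance.bland_altman(pairs)._asdict()
        out["regression"] = concordance.regression_fit(pairs)._asdict()
    joined.to_csv(out_dir / "concordance_pairs.csv", index=False)
    _write_json(out, out_dir / "concordance.json")
    return out


def stage_monitor(
    quant_path: Path,
    timeline_path: Path,
    imaging_path: Path,
    out_dir: Path,
    fold_threshold: float = 2.0,
    pairing_window: float = 21.0,
    truth_path: Path | None = None,
) -> dict:
    """Sustained-increase classification and pairing with imaging."""
    out_dir.mkdir(parents=True, exist_ok=True)
    quant = pd.read_csv(quant_path, sep="\t")
    timeline = pd.read_csv(timeline_path)
    timelines = monitoring.build_timelines(quant, timeline)

    calls = [
        monitoring.classify_patient(pid, tl, fold_threshold=fold_threshold)
        for pid, tl in sorted(timelines.items())
    ]

    imaging_df = pd.read_csv(imaging_path)
    imaging = {
        str(pid): [
            monitoring.ImagingEvent(
                day=float(r.day), outcome=str(r.outcome), modality=str(r.modality),
                sum_diameters_mm=None if pd.isna(r.sum_diameters_mm) else float(r.sum_diameters_mm),
            )
            for r in grp.itertuples()
        ]
        for pid, grp in imaging_df.groupby("patient_id")
    }
    evaluation = monitoring.evaluate_against_imaging(
        calls, timelines, imaging, pairing_window=pairing_window
    )
    calls_df = pd.DataFrame([asdict(c) for c in evaluation["calls"]])
    calls_df.to_csv(out_dir / "monitoring_calls.tsv", sep="\t", index=False)

    out = {k: v for k, v in evaluation.items() if k != "calls"}
    if truth_path is not None and Path(truth_path).exists():
        truth = pd.read_csv(truth_path)
        truth_map = dict(zip(truth["patient_id"].astype(str), truth["nonresponder"].astype(bool)))
        out["classification_vs_truth"] = monitoring.classification_metrics(calls, truth_map)
    _write_json(out, out_dir / "evaluation.json")
    return out


def stage_report(
    quant_path: Path,
    timeline_path: Path,
    imaging_path: Path,
    truth_path: Path,
    out_dir: Path,
    pairing_window: float = 21.0,
    max_followup_days: float = 308.0,
) -> dict:
    """Cohort statistics: tumour size vs ctDNA Spearman correlation and
    survival summaries."""
    out_dir.mkdir(parents=True, exist_ok=True)
    quant = pd.read_csv(quant_path, sep="\t")
    timeline = pd.read_csv(timeline_path)
    imaging = pd.read_csv(imaging_path)
    truth = pd.read_csv(truth_path)
    timelines = monitoring.build_timelines(quant, timeline)

    sizes, concs = [], []
    for pid, tl in sorted(timelines.items()):
        scans = imaging[(imaging["patient_id"] == pid) & (imaging["modality"] == "CT")]
        if scans.empty or not tl:
            continue
        last = scans.sort_values("day").iloc[-1]
        label = monitoring.select_representative_mutation(tl, float(last["day"]), pairing_window)
        if label is None:
            continue
        in_window = [tp for tp in tl
                     if tp.day <= last["day"] and last["day"] - tp.day <= pairing_window]
        paired = max(in_window, key=lambda tp: tp.day)
        sizes.append(float(last["sum_diameters_mm"]))
        concs.append(paired.effective(label))

    out: dict = {"n_size_ctdna_pairs": len(sizes)}
    if len(sizes) >= 3 and len(set(concs)) > 1:
        rho, p = cohort_stats.spearman_correlation(sizes, concs)
        out["spearman"] = {"rho": rho, "p_value": p}

    records = [
        cohort_stats.SurvivalRecord(
            patient_id=str(r.patient_id),
            time=min(float(r.os_days), max_followup_days) / 30.44,  # months
            event=bool(float(r.os_days) <= max_followup_days),
        )
        for r in truth.itertuples()
    ]
    km = cohort_stats.km_summary(records)
    out["survival_months"] = km._asdict()
    _write_json(out, out_dir / "cohort_stats.json")
    return out


def run_pipeline(
    out_dir: str | Path,
    config: CohortConfig | None = None,
    seed: int | None = None,
    af_threshold: float = 1.0,
    fold_threshold: float = 2.0,
    pairing_window: float = 21.0,
) -> dict:
    """Run every stage on a freshly simulated cohort.

    A missing optional input skips the dependent stage with an explicit log
    entry; earlier stages still complete.  Returns the manifest dict.
    """
    out_dir = Path(out_dir)
    config = config or CohortConfig()
    if seed is not None:
        config = replace(config, seed=seed)

    cohort = simulate_cohort(config)
    paths = cohort.write(out_dir / "cohort")
    logger.info("simulate: %d patients written to %s", config.n_patients, out_dir / "cohort")

    report = ctio.validate_inputs(
        variants=paths["variants"], droplets=paths["droplets"],
        timeline=paths["timeline"], imaging=paths["imaging"],
    )
    if not report.ok:
        raise ValueError(f"generated inputs failed validation: {report.violations[:5]}")

    calling = stage_call(paths["variants"], paths["amplicon_coverage"], out_dir / "call",
                         af_threshold=af_threshold)
    stage_quantify(paths["droplets"], paths["timeline"], out_dir / "quant",
                   blanks_path=paths["blanks"], quant_config=config.quant_config)
    quant_path = out_dir / "quant" / "quant.tsv"
    concord = stage_concord(out_dir / "call" / "called_variants.tsv", quant_path,
                            paths["assays"], paths["timeline"], out_dir / "concord")

    if paths["imaging"].exists() and len(cohort.imaging):
        monitor = stage_monitor(quant_path, paths["timeline"], paths["imaging"],
                                out_dir / "monitor", fold_threshold=fold_threshold,
                                pairing_window=pairing_window, truth_path=paths["truth"])
        stats = stage_report(quant_path, paths["timeline"], paths["imaging"], paths["truth"],
                             out_dir / "report", pairing_window=pairing_window,
                             max_followup_days=config.max_followup_days)
    else:
        logger.warning("monitor/report skipped: no imaging data available")
        monitor, stats = None, None

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "stages": {
            "call": calling,
            "concord": concord,
            "monitor": monitor,
            "report": stats,
        },
        "paths": {k: str(v) for k, v in paths.items()},
    }
    _write_json(manifest, out_dir / "manifest.json")
    return manifest


def analyze_table2() -> dict:
    """Summarise the packaged fixture: calling summary, verification rate
    and NGS/ddPCR agreement from the printed values."""
    df = ctio.load_table2()
    records = ctio.table2_variant_records(df)
    summary = ngs_calling.summarize_mutations(records)

    unverified = df[df["copies_per_ml_plasma"] == 0]
    pairs = concordance.pairs_from_frame(df)
    ratio = concordance.paired_ratio_summary(pairs)
    ba = concordance.bland_altman(pairs)
    reg = concordance.regression_fit(pairs)
    return {
        "summary": summary,
        "n_verified": sum(p.verified for p in pairs),
        "verified_percent": 100.0 * sum(p.verified for p in pairs) / len(pairs),
        "unverified": [
            f"{r.patient_id} {r.gene} {r.protein}" for r in unverified.itertuples()
        ],
        "ratio_summary": ratio._asdict(),
        "bland_altman": ba._asdict(),
        "regression": reg._asdict(),
    }
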