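"""Shared readers/writers, the packaged NGS/ddPCR results fixture, and
input validation.

All interchange formats are flat, RFC-4180-style CSV/TSV with documented
headers (see the schema constants below).  The packaged fixture transcribes
the published per-mutation NGS and ddPCR results table of the cohort the
pipeline targets: 41 alterations across 21 patients, with printed allele
frequency, fractional abundance and plasma concentration per mutation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .ddpcr_quant import DropletCounts, QuantResult
from .ngs_calling import VariantRecord

__all__ = [
    "TABLE2_SHA256",
    "ValidationReport",
    "load_table2",
    "table2_variant_records",
    "read_variants",
    "write_variants",
    "read_droplets",
    "write_droplets",
    "droplet_counts_from_frame",
    "write_quant_results",
    "write_cohort",
    "validate_inputs",
]

logger = logging.getLogger(__name__)

TABLE2_SHA256 = "5d82dcede5ad954404255cc22ecc425d6524518644984d36b82a7d14ebc3841b"

VARIANT_COLUMNS = [
    "patient_id", "gene", "cds", "protein", "allele_coverage", "total_coverage",
    "exonic", "cosmic", "benign_snp", "amplicon_id",
]
DROPLET_COLUMNS = [
    "sample_id", "assay_id", "droplets_total", "mut_positive", "wt_positive", "double_positive",
]
TIMELINE_COLUMNS = ["patient_id", "sample_id", "day", "plasma_volume_ml"]
IMAGING_COLUMNS = ["patient_id", "day", "modality", "outcome", "sum_diameters_mm"]
QUANT_COLUMNS = [
    "sample_id", "assay_id", "c_mut", "c_wt", "fractional_abundance",
    "copies_per_ml_plasma", "below_lod", "censored_above", "n_wells", "droplets_total",
]


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, source: str, row: object, message: str) -> None:
        self.violations.append(f"{source}:{row}: {message}")


def load_table2(verify_checksum: bool = True) -> pd.DataFrame:
    """Load the packaged NGS/ddPCR results fixture.

    Returns a 41-row frame over 21 patients with columns patient_id, gene,
    cds, protein, allele_coverage, total_coverage, af_percent,
    fractional_abundance_percent, copies_per_ml_plasma.  Three rows carry
    zero target molecules (mutations not re-detected by ddPCR).
    """
    ref = resources.files("ctmon.data") / "table2_ngs_ddpcr.tsv"
    raw = ref.read_bytes()
    if verify_checksum:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != TABLE2_SHA256:
            raise ValueError(
                f"packaged fixture checksum mismatch: {digest} != {TABLE2_SHA256}"
            )
    import io as _io

    df = pd.read_csv(_io.BytesIO(raw), sep="\t")
    if len(df) != 41:
        raise ValueError(f"fixture must have 41 rows, found {len(df)}")
    if df["patient_id"].nunique() != 21:
        raise ValueError("fixture must cover 21 distinct patients")
    if int((df["copies_per_ml_plasma"] == 0).sum()) != 3:
        raise ValueError("fixture must contain exactly 3 unverified rows")
    return df


def table2_variant_records(df: pd.DataFrame | None = None) -> list[VariantRecord]:
    """Fixture rows as annotated variant records (all called variants were
    exonic, COSMIC-reported and not benign; the printed AF is preserved)."""
    if df is None:
        df = load_table2()
    return [
        VariantRecord(
            patient_id=str(r.patient_id),
            gene=r.gene,
            cds=r.cds,
            protein=r.protein,
            allele_coverage=int(r.allele_coverage),
            total_coverage=int(r.total_coverage),
            exonic=True,
            cosmic_reported=True,
            benign_snp=False,
            af=float(r.af_percent),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# flat-file round trips


def write_variants(records: Iterable[VariantRecord] | pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(
            {
                "patient_id": [r.patient_id for r in records],
                "gene": [r.gene for r in records],
                "cds": [r.cds for r in records],
                "protein": [r.protein for r in records],
                "allele_coverage": [r.allele_coverage for r in records],
                "total_coverage": [r.total_coverage for r in records],
                "exonic": [r.exonic for r in records],
                "cosmic": [r.cosmic_reported for r in records],
                "benign_snp": [r.benign_snp for r in records],
                "amplicon_id": [r.amplicon_id for r in records],
            }
        )
    df.to_csv(path, sep="\t", index=False)
    return path


def read_variants(path: str | Path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t")
    records = []
    for r in df.itertuples():
        records.append(
            VariantRecord(
                patient_id=str(r.patient_id),
                gene=str(r.gene),
                cds=str(r.cds),
                protein=str(r.protein),
                allele_coverage=int(r.allele_coverage),
                total_coverage=int(r.total_coverage),
                exonic=None if pd.isna(r.exonic) else bool(r.exonic),
                cosmic_reported=None if pd.isna(r.cosmic) else bool(r.cosmic),
                benign_snp=None if pd.isna(r.benign_snp) else bool(r.benign_snp),
                amplicon_id="" if pd.isna(r.amplicon_id) else str(r.amplicon_id),
            )
        )
    return records


def write_droplets(wells: Iterable[DropletCounts] | pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    if isinstance(wells, pd.DataFrame):
        df = wells
    else:
        df = pd.DataFrame(
            [
                {
                    "sample_id": w.sample_id,
                    "assay_id": w.assay_id,
                    "droplets_total": w.droplets_total,
                    "mut_positive": w.mut_positive,
                    "wt_positive": w.wt_positive,
                    "double_positive": w.double_positive,
                }
                for w in wells
            ]
        )
    df.to_csv(path, index=False)
    return path


def read_droplets(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def droplet_counts_from_frame(df: pd.DataFrame) -> list[DropletCounts]:
    return [
        DropletCounts(
            sample_id=str(r.sample_id),
            assay_id=str(r.assay_id),
            droplets_total=int(r.droplets_total),
            mut_positive=int(r.mut_positive),
            wt_positive=int(r.wt_positive),
            double_positive=int(r.double_positive),
        )
        for r in df.itertuples()
    ]


def write_quant_results(results: Iterable[QuantResult], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [
            {
                "sample_id": q.sample_id,
                "assay_id": q.assay_id,
                "c_mut": q.c_mut,
                "c_wt": q.c_wt,
                "fractional_abundance": q.fractional_abundance,
                "copies_per_ml_plasma": q.copies_per_ml_plasma,
                "below_lod": q.below_lod,
                "censored_above": q.censored_above,
                "n_wells": q.n_wells,
                "droplets_total": q.droplets_total,
            }
            for q in results
        ]
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def write_cohort(cohort, out_dir: Path) -> dict[str, Path]:
    """Write every cohort table to ``out_dir``; returns the path map."""
    import yaml
    from dataclasses import asdict

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "variants": out_dir / "variants.tsv",
        "droplets": out_dir / "droplets.csv",
        "blanks": out_dir / "blanks.csv",
        "timeline": out_dir / "timeline.csv",
        "imaging": out_dir / "imaging.csv",
        "truth": out_dir / "truth.csv",
        "true_concentrations": out_dir / "true_concentrations.csv",
        "amplicon_coverage": out_dir / "amplicon_coverage.csv",
        "assays": out_dir / "assays.csv",
        "config": out_dir / "config.yaml",
    }
    cohort.assays.to_csv(paths["assays"], index=False)
    cohort.variants.to_csv(paths["variants"], sep="\t", index=False)
    cohort.droplets.to_csv(paths["droplets"], index=False)
    cohort.blanks.to_csv(paths["blanks"], index=False)
    cohort.timeline.to_csv(paths["timeline"], index=False)
    cohort.imaging.to_csv(paths["imaging"], index=False)
    cohort.truth.to_csv(paths["truth"], index=False)
    cohort.true_concentrations.to_csv(paths["true_concentrations"], index=False)
    cohort.amplicon_coverage.to_csv(paths["amplicon_coverage"])
    cfg = asdict(cohort.config)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return paths


# ---------------------------------------------------------------------------
# validation


def validate_inputs(
    variants: str | Path | None = None,
    droplets: str | Path | None = None,
    timeline: str | Path | None = None,
    imaging: str | Path | None = None,
) -> ValidationReport:
    """Schema- and invariant-check the flat input files.

    Checks column presence and types, the droplet-count invariant
    (exclusive positives never exceed total droplets), coverage bounds on
    variants, and strictly increasing sample days within each patient.
    Violations are collected with file and row references; an unreadable
    file raises.
    """
    report = ValidationReport()

    if variants is not None:
        df = pd.read_csv(variants, sep="\t")
        missing = set(VARIANT_COLUMNS) - set(df.columns)
        if missing:
            report.add(str(variants), "-", f"missing columns {sorted(missing)}")
        else:
            for idx, r in df.iterrows():
                if r.total_coverage <= 0:
                    report.add(str(variants), idx, "total_coverage must be positive")
                elif not 0 <= r.allele_coverage <= r.total_coverage:
                    report.add(str(variants), idx, "allele_coverage outside [0, total_coverage]")

    if droplets is not None:
        df = pd.read_csv(droplets)
        missing = set(DROPLET_COLUMNS) - set(df.columns)
        if missing:
            report.add(str(droplets), "-", f"missing columns {sorted(missing)}")
        else:
            counts = df[["mut_positive", "wt_positive", "double_positive"]]
            if (counts < 0).any().any() or (df["droplets_total"] < 0).any():
                for idx in df.index[(counts < 0).any(axis=1) | (df["droplets_total"] < 0)]:
                    report.add(str(droplets), idx, "negative droplet count")
            over = counts.sum(axis=1) > df["droplets_total"]
            for idx in df.index[over]:
                report.add(str(droplets), idx, "positives exceed droplets_total")

    if timeline is not None:
        df = pd.read_csv(timeline)
        missing = set(TIMELINE_COLUMNS) - set(df.columns)
        if missing:
            report.add(str(timeline), "-", f"missing columns {sorted(missing)}")
        else:
            if (df["day"] < 0).any():
                for idx in df.index[df["day"] < 0]:
                    report.add(str(timeline), idx, "negative sample day")
            for pid, grp in df.groupby("patient_id"):
                days = grp["day"].to_numpy()
                if len(days) != len(set(days)):
                    report.add(str(timeline), pid, "duplicate sample day for patient")
                elif not (sorted(days) == list(days) or list(days) == sorted(days)):
                    pass  # order in file is free; monotonicity is per sorted days

    if imaging is not None:
        df = pd.read_csv(imaging)
        missing = set(IMAGING_COLUMNS) - set(df.columns)
        if missing:
            report.add(str(imaging), "-", f"missing columns {sorted(missing)}")
        else:
            bad = ~df["outcome"].isin(["PD", "SD", "PR", "CR"])
            for idx in df.index[bad]:
                report.add(str(imaging), idx, f"invalid RECIST outcome {df.loc[idx, 'outcome']!r}")

    if not report.ok:
        logger.warning("input validation found %d violation(s)", len(report.violations))
    return report
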