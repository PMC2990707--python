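"""Data model and TSV/BED I/O for expression matrices, sample metadata and probe annotations.

All genomic coordinates are held 1-based inclusive internally (the usual
``chr:start-end`` style); BED input/output converts at the boundary.  A probe is
positioned by its midpoint for every region/distance computation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

GENOTYPES: tuple[str, ...] = ("1n", "2n_trans", "2n_cis", "3n")
#: interval copy number carried by each genotype
INTERVAL_COPIES: dict[str, int] = {"1n": 1, "2n_trans": 2, "2n_cis": 2, "3n": 3}
WILDTYPE = "2n_trans"
REGION_CLASSES: tuple[str, ...] = ("interval", "flank_cnv_chr", "other")

SCHEMA_VERSION = 1


class FormatError(ValueError):
    """Raised when an input file violates the documented format contract."""


@dataclass(frozen=True)
class RegionConfig:
    """Definition of the rearranged interval on the CNV chromosome.

    Coordinates are 1-based inclusive.  Breakpoints default to the interval
    boundaries (the engineering insertion sites coincide with the interval ends
    unless stated otherwise).
    """

    cnv_chromosome: str
    interval_start: int
    interval_end: int
    breakpoint_left: int | None = None
    breakpoint_right: int | None = None

    def __post_init__(self) -> None:
        if self.interval_start >= self.interval_end:
            raise ValueError(
                f"interval_start ({self.interval_start}) must be < interval_end "
                f"({self.interval_end})"
            )

    @property
    def left(self) -> int:
        return self.breakpoint_left if self.breakpoint_left is not None else self.interval_start

    @property
    def right(self) -> int:
        return self.breakpoint_right if self.breakpoint_right is not None else self.interval_end

    def contains(self, chromosome: str, midpoint: int) -> bool:
        return (
            chromosome == self.cnv_chromosome
            and self.interval_start <= midpoint <= self.interval_end
        )


def load_region_config(path: str | Path) -> tuple[RegionConfig, dict[str, dict[str, int]]]:
    """Read a region-definition YAML document.

    Returns the :class:`RegionConfig` and the per-probe active-copy overrides
    (anchor genes).  The document must carry ``schema_version``.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "schema_version" not in doc:
        raise FormatError(f"{path}: missing schema_version key")
    if int(doc["schema_version"]) != SCHEMA_VERSION:
        raise FormatError(
            f"{path}: unsupported schema_version {doc['schema_version']} (expected {SCHEMA_VERSION})"
        )
    region = doc["region"]
    cfg = RegionConfig(
        cnv_chromosome=str(region["cnv_chromosome"]),
        interval_start=int(region["interval_start"]),
        interval_end=int(region["interval_end"]),
        breakpoint_left=region.get("breakpoint_left"),
        breakpoint_right=region.get("breakpoint_right"),
    )
    overrides = {
        str(probe): {str(g): int(c) for g, c in copies.items()}
        for probe, copies in (doc.get("active_copies_overrides") or {}).items()
    }
    for probe, copies in overrides.items():
        unknown = set(copies) - set(GENOTYPES)
        if unknown:
            raise FormatError(f"override for {probe}: unknown genotype(s) {sorted(unknown)}")
    return cfg, overrides


def write_region_config(
    path: str | Path,
    region: RegionConfig,
    overrides: Mapping[str, Mapping[str, int]] | None = None,
) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "region": {
            "cnv_chromosome": region.cnv_chromosome,
            "interval_start": region.interval_start,
            "interval_end": region.interval_end,
            "breakpoint_left": region.breakpoint_left,
            "breakpoint_right": region.breakpoint_right,
        },
        "active_copies_overrides": {p: dict(c) for p, c in (overrides or {}).items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# expression matrix


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a probes x samples matrix of log2 intensities from TSV.

    First column is ``probe_id``; every remaining column one sample.  Duplicate
    probe or sample ids and non-numeric / missing cells are format errors.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str}, index_col=0, na_values=["NA", "NaN", ""])
    df.index.name = "probe_id"
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise FormatError(f"{path}: duplicated probe id(s): {sorted(set(dup))[:5]}")
    dup_s = df.columns[df.columns.duplicated()]
    if len(dup_s):
        raise FormatError(f"{path}: duplicated sample id(s): {sorted(set(dup_s))[:5]}")
    try:
        values = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric cell: {exc}") from exc
    if not np.isfinite(values.to_numpy()).all():
        bad = np.argwhere(~np.isfinite(values.to_numpy()))[0]
        raise FormatError(
            f"{path}: missing/non-finite value at probe {values.index[bad[0]]!r}, "
            f"sample {values.columns[bad[1]]!r}"
        )
    return values


def write_expression_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    out = matrix.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", float_format="%.6f")


# ---------------------------------------------------------------------------
# sample metadata


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Read sample metadata (sample_id, genotype, tissue, replicate[, strain_label])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "tissue", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"{path}: duplicated sample_id {dup!r}")
    if "genotype" in df.columns:
        bad = set(df["genotype"]) - set(GENOTYPES)
        if bad:
            raise FormatError(f"{path}: unknown genotype(s) {sorted(bad)}")
    df["replicate"] = df["replicate"].astype(int)
    if (df["replicate"] <= 0).any():
        raise FormatError(f"{path}: replicate must be a positive integer")
    return df.set_index("sample_id", drop=False)


def write_sample_table(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# probe annotation

_COPY_COLUMNS = [f"copies_{g}" for g in GENOTYPES]


def default_active_copies(region_class: str) -> dict[str, int]:
    """Copy number per genotype implied by the region class alone."""
    if region_class == "interval":
        return dict(INTERVAL_COPIES)
    return {g: 2 for g in GENOTYPES}


def classify_region(chromosome: pd.Series, midpoint: pd.Series, region: RegionConfig) -> pd.Series:
    on_chr = chromosome == region.cnv_chromosome
    inside = on_chr & (midpoint >= region.interval_start) & (midpoint <= region.interval_end)
    out = pd.Series("other", index=chromosome.index, dtype=object)
    out[on_chr] = "flank_cnv_chr"
    out[inside] = "interval"
    return out


def build_probe_annotation(
    frame: pd.DataFrame,
    region: RegionConfig,
    overrides: Mapping[str, Mapping[str, int]] | None = None,
) -> pd.DataFrame:
    """Assemble a full annotation table from 1-based probe coordinates.

    ``frame`` must have columns probe_id, chromosome, start, end and may carry
    gene_id and cpg_neighbor.  Derives midpoint, region_class and per-genotype
    active copy numbers (anchor overrides applied verbatim).
    """
    annot = frame.copy()
    if annot["probe_id"].duplicated().any():
        dup = annot.loc[annot["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise FormatError(f"duplicated probe id {dup!r}")
    if "gene_id" not in annot.columns:
        annot["gene_id"] = annot["probe_id"]
    if "cpg_neighbor" not in annot.columns:
        annot["cpg_neighbor"] = False
    annot["cpg_neighbor"] = annot["cpg_neighbor"].astype(bool)
    annot["start"] = annot["start"].astype(int)
    annot["end"] = annot["end"].astype(int)
    if (annot["start"] > annot["end"]).any():
        bad = annot.loc[annot["start"] > annot["end"], "probe_id"].iloc[0]
        raise FormatError(f"probe {bad!r}: start > end")
    annot["midpoint"] = (annot["start"] + annot["end"]) // 2
    annot["region_class"] = classify_region(annot["chromosome"], annot["midpoint"], region)
    for g in GENOTYPES:
        annot[f"copies_{g}"] = np.where(
            annot["region_class"] == "interval", INTERVAL_COPIES[g], 2
        )
    annot = annot.set_index("probe_id", drop=False)
    for probe, copies in (overrides or {}).items():
        if probe not in annot.index:
            raise FormatError(f"active-copies override for unknown probe {probe!r}")
        for g, c in copies.items():
            annot.loc[probe, f"copies_{g}"] = int(c)
    annot[_COPY_COLUMNS] = annot[_COPY_COLUMNS].astype(int)
    cols = ["probe_id", "gene_id", "chromosome", "start", "end", "midpoint",
            "region_class", "cpg_neighbor", *_COPY_COLUMNS]
    return annot[cols]


def read_probe_annotation(
    path: str | Path,
    region: RegionConfig,
    overrides: Mapping[str, Mapping[str, int]] | None = None,
) -> pd.DataFrame:
    """Read probe positions from a BED6(+2) file and derive the annotation.

    BED is 0-based half-open; internal coordinates are 1-based inclusive, so a
    BED row ``(chrom, s, e)`` becomes ``start = s + 1, end = e``.  Optional
    columns 7 and 8 are gene_id and cpg_neighbor (0/1).
    """
    names = ["chromosome", "bed_start", "bed_end", "probe_id", "score", "strand",
             "gene_id", "cpg_neighbor"]
    raw = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if raw.shape[1] < 4:
        raise FormatError(f"{path}: need at least 4 BED columns")
    raw.columns = names[: raw.shape[1]]
    raw["bed_start"] = raw["bed_start"].astype(int)
    raw["bed_end"] = raw["bed_end"].astype(int)
    if (raw["bed_start"] >= raw["bed_end"]).any():
        bad = raw.loc[raw["bed_start"] >= raw["bed_end"], "probe_id"].iloc[0]
        raise FormatError(f"{path}: probe {bad!r} has start >= end in BED coordinates")
    frame = pd.DataFrame(
        {
            "probe_id": raw["probe_id"],
            "chromosome": raw["chromosome"],
            "start": raw["bed_start"] + 1,
            "end": raw["bed_end"],
        }
    )
    if "gene_id" in raw.columns:
        frame["gene_id"] = raw["gene_id"]
    if "cpg_neighbor" in raw.columns:
        frame["cpg_neighbor"] = raw["cpg_neighbor"].astype(int).astype(bool)
    return build_probe_annotation(frame, region, overrides)


def write_probe_annotation_bed(annot: pd.DataFrame, path: str | Path) -> None:
    """Export annotation back to BED6+2 (0-based half-open), inverse of ingestion."""
    bed = pd.DataFrame(
        {
            "chromosome": annot["chromosome"],
            "start": annot["start"] - 1,
            "end": annot["end"],
            "probe_id": annot["probe_id"],
            "score": 0,
            "strand": "+",
            "gene_id": annot["gene_id"],
            "cpg_neighbor": annot["cpg_neighbor"].astype(int),
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# validation


@dataclass
class Finding:
    level: str  # "error" | "warning"
    message: str


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not any(f.level == "error" for f in self.findings)

    def add(self, level: str, message: str) -> None:
        self.findings.append(Finding(level, message))

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "findings": [dataclasses.asdict(f) for f in self.findings],
        }


def validate_dataset(
    matrix: pd.DataFrame, samples: pd.DataFrame, annot: pd.DataFrame
) -> ValidationReport:
    """Cross-check matrix / metadata / annotation consistency.

    Errors: probes without annotation, annotated probes missing from the
    matrix, samples without metadata (and vice versa).  Warnings:
    genotype x tissue cells with fewer than two replicates.
    """
    report = ValidationReport()
    mprobes, aprobes = set(matrix.index), set(annot.index)
    for p in sorted(mprobes - aprobes)[:20]:
        report.add("error", f"unannotated probe {p!r} in matrix")
    for p in sorted(aprobes - mprobes)[:20]:
        report.add("error", f"annotated probe {p!r} missing from matrix")
    msamples, tsamples = set(matrix.columns), set(samples.index)
    for s in sorted(msamples - tsamples)[:20]:
        report.add("error", f"sample {s!r} lacks metadata")
    for s in sorted(tsamples - msamples)[:20]:
        report.add("error", f"sample {s!r} in metadata missing from matrix")
    group_cols = [c for c in ("genotype", "strain_label") if c in samples.columns]
    if group_cols:
        counts = samples.groupby(["tissue", *group_cols], observed=True).size()
        for key, n in counts.items():
            if n < 2:
                report.add("warning", f"insufficient replication ({n}) for {key}")
    return report
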