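"""Annotation-report metadata: the 23 per-species annotation metrics.

The NCBI eukaryotic annotation pipeline (EGAP) publishes, per annotated
assembly, a report describing (a) assembly contiguity (gap and
scaffold/contig statistics), (b) the molecular evidence that fed the
annotation (Entrez proteins/transcripts, RNA-seq reads, tissues, runs)
and (c) the annotated CDS output, split by evidence class (fully
supported, model-derived, known, >5% ab initio). This module defines a
canonical schema for those 23 metrics, parses report files (key/value or
one-row TSV), derives percentage metrics, filters NCBI assembly-summary
tables, and assembles the per-species analysis table that the
statistics pipeline consumes.

Missing values propagate as missing and are never imputed; records with
incomplete predictors are excluded listwise downstream.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationMetadata",
    "SpeciesRecord",
    "SpeciesTable",
    "METRIC_NAMES",
    "COUNT_METRICS",
    "PERCENT_METRICS",
    "TAXON_GROUPS",
    "parse_annotation_report",
    "derive_percentage_metrics",
    "filter_assembly_summary",
    "assemble_species_table",
    "read_species_table",
]

TAXON_GROUPS = ("mammals", "birds", "fish", "arthropods", "plants", "other")

# percentage metric -> the count metric it is derived from (over cds_total)
_PCT_OF_COUNT = {
    "cds_from_model_pct": "cds_from_model",
    "cds_known_pct": "cds_known",
    "cds_fully_supported_pct": "cds_fully_supported",
    "cds_gt5pct_abinitio_pct": "cds_gt5pct_abinitio",
}


@dataclass(slots=True)
class AnnotationMetadata:
    """The 23 annotation-report metrics for one species.

    Counts are non-negative integers, N50/gap lengths are in bp,
    percentages in [0, 100]. Any field may be ``None`` (missing).
    """

    # assembly block
    number_of_gaps: float | None = None
    scaffold_count: float | None = None
    scaffold_n50: float | None = None
    contig_count: float | None = None
    contig_n50: float | None = None
    gap_length: float | None = None
    gap_length_pct: float | None = None
    # evidence block
    n_proteins: float | None = None
    n_transcripts: float | None = None
    n_proteins_hsapiens: float | None = None
    n_transcripts_hsapiens: float | None = None
    n_rnaseq_reads: float | None = None
    n_tissues: float | None = None
    n_runs: float | None = None
    # CDS block
    cds_total: float | None = None
    cds_from_model: float | None = None
    cds_fully_supported: float | None = None
    cds_known: float | None = None
    cds_gt5pct_abinitio: float | None = None
    cds_from_model_pct: float | None = None
    cds_known_pct: float | None = None
    cds_fully_supported_pct: float | None = None
    cds_gt5pct_abinitio_pct: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}

    def missing_fields(self) -> list[str]:
        return [f.name for f in dc_fields(self) if getattr(self, f.name) is None]

    @property
    def complete(self) -> bool:
        return not self.missing_fields()


METRIC_NAMES: tuple[str, ...] = tuple(f.name for f in dc_fields(AnnotationMetadata))
PERCENT_METRICS: tuple[str, ...] = tuple(n for n in METRIC_NAMES if n.endswith("_pct"))
COUNT_METRICS: tuple[str, ...] = tuple(n for n in METRIC_NAMES if not n.endswith("_pct"))

# Aliases for metric names as phrased in NCBI-style reports. Keys are
# normalized (lowercased, punctuation stripped) before lookup.
_ALIASES = {
    "number of gaps": "number_of_gaps",
    "gaps count": "number_of_gaps",
    "scaffold count": "scaffold_count",
    "scaffolds": "scaffold_count",
    "scaffold n50": "scaffold_n50",
    "contig count": "contig_count",
    "contigs": "contig_count",
    "contig n50": "contig_n50",
    "gap length": "gap_length",
    "total gap length": "gap_length",
    "gap length percent": "gap_length_pct",
    "gaps percent of genome": "gap_length_pct",
    "number of proteins": "n_proteins",
    "proteins": "n_proteins",
    "number of transcripts": "n_transcripts",
    "transcripts": "n_transcripts",
    "number of proteins from homo sapiens": "n_proteins_hsapiens",
    "proteins from homo sapiens": "n_proteins_hsapiens",
    "number of transcripts from homo sapiens": "n_transcripts_hsapiens",
    "transcripts from homo sapiens": "n_transcripts_hsapiens",
    "number of rna seq reads": "n_rnaseq_reads",
    "rna seq reads": "n_rnaseq_reads",
    "number of tissues": "n_tissues",
    "tissues": "n_tissues",
    "number of runs": "n_runs",
    "runs": "n_runs",
    "cdss": "cds_total",
    "total cdss": "cds_total",
    "cdss from model": "cds_from_model",
    "fully supported cdss": "cds_fully_supported",
    "known cdss": "cds_known",
    "cdss with gt 5 ab initio": "cds_gt5pct_abinitio",
    "cdss with more than 5 ab initio": "cds_gt5pct_abinitio",
    "cdss from model percent": "cds_from_model_pct",
    "known cds percent": "cds_known_pct",
    "known cdss percent": "cds_known_pct",
    "fully supported cdss percent": "cds_fully_supported_pct",
    "cdss with gt 5 ab initio percent": "cds_gt5pct_abinitio_pct",
}
_ALIASES.update({name.replace("_", " "): name for name in METRIC_NAMES})


def _normalize_key(key: str) -> str:
    key = key.strip().lower()
    key = key.replace("%", " percent ").replace(">", " gt ").replace("-", " ")
    key = re.sub(r"[^a-z0-9 ]+", " ", key)
    return re.sub(r"\s+", " ", key).strip()


@dataclass(slots=True)
class SpeciesRecord:
    """One species: name, taxon group, ASR, and annotation metadata."""

    species_name: str
    taxon_group: str = "other"
    asr: float | None = None
    metadata: AnnotationMetadata = field(default_factory=AnnotationMetadata)
    metadata_missing: bool = False

    def __post_init__(self) -> None:
        if self.taxon_group not in TAXON_GROUPS:
            raise ValueError(
                f"unknown taxon group {self.taxon_group!r}; expected one of {TAXON_GROUPS}"
            )


@dataclass(slots=True)
class SpeciesTable:
    """Joined species records feeding the statistics pipeline."""

    records: list[SpeciesRecord] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [r.species_name for r in self.records]
        if len(names) != len(set(names)):
            raise ValueError("species names must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Flatten to a DataFrame: species_name, taxon_group, asr + 23 metrics."""
        rows = []
        for r in self.records:
            row: dict = {
                "species_name": r.species_name,
                "taxon_group": r.taxon_group,
                "asr": r.asr,
                "metadata_missing": r.metadata_missing,
            }
            row.update(r.metadata.as_dict())
            rows.append(row)
        cols = ["species_name", "taxon_group", "asr", "metadata_missing", *METRIC_NAMES]
        return pd.DataFrame(rows, columns=cols)

    def complete_frame(self, variables: Iterable[str] | None = None) -> pd.DataFrame:
        """Rows with no missing value in ``variables`` (default: asr + all metrics)."""
        df = self.to_frame()
        variables = list(variables) if variables is not None else ["asr", *METRIC_NAMES]
        return df.dropna(subset=variables).reset_index(drop=True)

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        return path


def read_species_table(path: str | Path) -> SpeciesTable:
    """Read a species table written by :meth:`SpeciesTable.write_tsv`."""
    df = pd.read_csv(path, sep="\t")
    records = []
    for _, row in df.iterrows():
        meta = AnnotationMetadata(
            **{
                n: (None if pd.isna(row[n]) else float(row[n]))
                for n in METRIC_NAMES
                if n in row
            }
        )
        records.append(
            SpeciesRecord(
                species_name=str(row["species_name"]),
                taxon_group=str(row.get("taxon_group", "other")),
                asr=None if pd.isna(row.get("asr")) else float(row["asr"]),
                metadata=meta,
                metadata_missing=bool(row.get("metadata_missing", False)),
            )
        )
    return SpeciesTable(records=records, provenance=[str(path)])


# ---------------------------------------------------------------------------
# parsing


def parse_annotation_report(path: str | Path, format: str = "keyvalue") -> AnnotationMetadata:
    """Parse one species' annotation report into :class:`AnnotationMetadata`.

    ``format="keyvalue"``: lines of ``metric<TAB or :>value``.
    ``format="tsv"``: a header row of metric names and one data row.
    Metric names may use canonical identifiers or NCBI-style phrasing
    (see the alias table). Unrecognized keys are logged; missing metrics
    stay ``None``. A reported percentage inconsistent with its count and
    ``cds_total`` (beyond 0.5 points) triggers a warning.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    if format == "keyvalue":
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "\t" in line:
                key, _, val = line.partition("\t")
            elif ":" in line:
                key, _, val = line.partition(":")
            else:
                continue
            pairs.append((key, val.strip()))
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t")
        if len(df) != 1:
            raise ValueError(f"expected exactly one data row in {path}, got {len(df)}")
        pairs = [(str(c), str(df.iloc[0][c])) for c in df.columns]
    else:
        raise ValueError(f"unknown report format {format!r}")

    meta = AnnotationMetadata()
    n_recognized = 0
    for key, val in pairs:
        canon = _ALIASES.get(_normalize_key(key))
        if canon is None:
            logger.info("unrecognized report key: %r", key)
            continue
        try:
            num = float(str(val).replace(",", ""))
        except ValueError:
            logger.info("non-numeric value for %r: %r", key, val)
            continue
        if canon in PERCENT_METRICS and not 0 <= num <= 100:
            raise ValueError(f"{canon} = {num} outside [0, 100]")
        if canon in COUNT_METRICS and num < 0:
            raise ValueError(f"{canon} = {num} negative")
        setattr(meta, canon, num)
        n_recognized += 1
    if n_recognized == 0:
        raise ValueError(f"{path}: not an annotation report (no recognized keys)")

    _check_percentage_consistency(meta, str(path))
    return meta


def _check_percentage_consistency(meta: AnnotationMetadata, source: str) -> None:
    if not meta.cds_total:
        return
    for pct_name, count_name in _PCT_OF_COUNT.items():
        pct = getattr(meta, pct_name)
        count = getattr(meta, count_name)
        if pct is None or count is None:
            continue
        expected = 100.0 * count / meta.cds_total
        if abs(pct - expected) > 0.5:
            warnings.warn(
                f"{source}: {pct_name}={pct} inconsistent with "
                f"100*{count_name}/cds_total={expected:.2f}",
                stacklevel=3,
            )


def derive_percentage_metrics(meta: AnnotationMetadata) -> AnnotationMetadata:
    """Fill missing percentage metrics as 100*count/cds_total.

    Reported percentages are never overwritten; the operation is
    idempotent. Requires ``cds_total > 0``.
    """
    if not meta.cds_total:
        raise ValueError("cds_total missing or zero; cannot derive percentages")
    out = AnnotationMetadata(**meta.as_dict())
    for pct_name, count_name in _PCT_OF_COUNT.items():
        if getattr(out, pct_name) is None and getattr(out, count_name) is not None:
            setattr(out, pct_name, 100.0 * getattr(out, count_name) / out.cds_total)
    return out


# ---------------------------------------------------------------------------
# assembly-summary filtering and table assembly

_RETAINED_LEVELS = {"Chromosome", "Complete Genome"}


def filter_assembly_summary(
    path: str | Path,
    taxon_map: Mapping[str, str],
) -> SpeciesTable:
    """Filter an NCBI assembly-summary-style TSV to the analysis species set.

    Retains rows that are (i) assembled at chromosome or complete-genome
    level, (ii) RefSeq/EGAP-annotated (the ``annotation_provider``
    column contains "NCBI"), and (iii) mapped by ``taxon_map`` (keyed by
    organism name) to one of the five taxon groups. Returns a skeleton
    :class:`SpeciesTable` (no ASR or metadata yet).
    """
    path = Path(path)
    # NCBI assembly_summary files prefix the header row with '#'.
    with open(path) as fh:
        lines = [ln for ln in fh if not ln.startswith("##")]
    if lines and lines[0].startswith("#"):
        lines[0] = lines[0].lstrip("#").lstrip()
    if not lines or not lines[0].strip():
        warnings.warn(f"{path}: empty assembly summary", stacklevel=2)
        return SpeciesTable(records=[], provenance=[str(path)])
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines)), sep="\t", dtype=str)
    for col in ("organism_name", "assembly_level", "annotation_provider"):
        if col not in df.columns:
            raise ValueError(f"{path}: required column {col!r} absent")
    if df.empty:
        warnings.warn(f"{path}: empty assembly summary", stacklevel=2)
        return SpeciesTable(records=[], provenance=[str(path)])

    keep = (
        df["assembly_level"].isin(_RETAINED_LEVELS)
        & df["annotation_provider"].fillna("").str.contains("NCBI")
        & df["organism_name"].isin(taxon_map)
    )
    records = []
    seen: set[str] = set()
    for _, row in df[keep].iterrows():
        name = row["organism_name"]
        if name in seen:
            continue  # one record per species; keep the first assembly
        seen.add(name)
        records.append(SpeciesRecord(species_name=name, taxon_group=taxon_map[name]))
    logger.info(
        "assembly summary %s: retained %d of %d rows", path, int(keep.sum()), len(df)
    )
    return SpeciesTable(records=records, provenance=[str(path)])


def assemble_species_table(
    asr_results: Mapping[str, float],
    reports: Mapping[str, AnnotationMetadata],
    taxon_map: Mapping[str, str] | None = None,
) -> SpeciesTable:
    """Join per-species ASR values with annotation reports by species name.

    Species without a report are retained but flagged
    ``metadata_missing`` (the statistics pipeline uses only complete
    records). Duplicate species names are an error upstream of this
    join; mappings enforce uniqueness by construction.
    """
    if not asr_results:
        raise ValueError("need at least one species with an ASR value")
    taxon_map = taxon_map or {}
    records = []
    n_flagged = 0
    for name in asr_results:
        meta = reports.get(name)
        missing = meta is None
        n_flagged += missing
        records.append(
            SpeciesRecord(
                species_name=name,
                taxon_group=taxon_map.get(name, "other"),
                asr=float(asr_results[name]),
                metadata=meta if meta is not None else AnnotationMetadata(),
                metadata_missing=missing,
            )
        )
    if n_flagged == len(records):
        warnings.warn("no species has annotation metadata; all records flagged", stacklevel=2)
    return SpeciesTable(records=records, provenance=["assemble_species_table"])
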