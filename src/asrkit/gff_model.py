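"""Gene models from GFF3/GTF annotations and the alternative splicing ratio.

The alternative splicing ratio (ASR) of a gene is the cumulative coding
length of all its transcript isoforms divided by the length of the
unique genomic coding footprint (the union of all CDS intervals). A gene
with a single isoform has ASR = 1; ASR grows with the reuse of coding
DNA across isoforms. At the genome level the ratio is aggregated as the
sum of per-gene numerators over the sum of per-gene denominators.

Parsing follows the RefSeq GFF3 parent-child convention
(gene -> mRNA -> CDS via ``ID``/``Parent`` attributes) and the
StringTie-style GTF convention (grouping via ``gene_id`` /
``transcript_id`` attributes). Pseudogenes and non-coding genes are
excluded; unresolvable records are counted with a reason, never silently
dropped.
"""

from __future__ import annotations

import json
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from gffutils.feature import feature_from_line

from .intervals import GenomicInterval, union_length

logger = logging.getLogger(__name__)

__all__ = [
    "CDSSegment",
    "TranscriptModel",
    "GeneModel",
    "AnnotationSet",
    "ASRResult",
    "parse_gff3",
    "parse_gtf",
    "coding_length",
    "gene_asr",
    "genome_asr",
    "write_gff3",
    "write_per_gene_tsv",
    "write_genome_summary",
]

# Feature types treated as transcript containers in GFF3. RefSeq uses
# "mRNA" for coding transcripts; "transcript" appears in some dialects.
_TRANSCRIPT_TYPES = {"mRNA", "transcript"}
_GENE_TYPES = {"gene"}
# Gene records of these feature types, or with a biotype containing
# "pseudogene", never enter ASR computation.
_PSEUDOGENE_TYPES = {"pseudogene", "processed_pseudogene", "unprocessed_pseudogene"}


@dataclass(slots=True)
class CDSSegment:
    """One CDS line: a coding interval attached to a parent transcript."""

    interval: GenomicInterval
    parent_transcript_id: str
    phase: int | None = None

    def __post_init__(self) -> None:
        if not self.parent_transcript_id:
            raise ValueError("CDS segment requires a nonempty parent transcript id")

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(slots=True)
class TranscriptModel:
    """A transcript isoform: an ordered collection of coding segments."""

    id: str
    gene_id: str
    segments: list[CDSSegment] = field(default_factory=list)

    @property
    def coding_length(self) -> int:
        return coding_length(self)


@dataclass(slots=True)
class GeneModel:
    """A gene and its transcript isoforms."""

    id: str
    biotype: str = "protein_coding"
    transcripts: list[TranscriptModel] = field(default_factory=list)

    @property
    def n_isoforms(self) -> int:
        return len(self.transcripts)

    def all_segments(self) -> list[CDSSegment]:
        return [seg for t in self.transcripts for seg in t.segments]


@dataclass(slots=True)
class AnnotationSet:
    """A parsed annotation: coding genes plus parse bookkeeping.

    ``skipped_records`` counts records that could not be placed in a
    gene -> transcript -> CDS chain, keyed by reason.
    """

    genes: list[GeneModel] = field(default_factory=list)
    source_path: str = ""
    dialect: str = "gff3"
    skipped_records: Counter = field(default_factory=Counter)
    notes: list[str] = field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_transcripts(self) -> int:
        return sum(g.n_isoforms for g in self.genes)

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass(slots=True)
class ASRResult:
    """Per-gene and genome-level ASR with numerator/denominator bookkeeping.

    ``per_gene`` maps gene_id -> (numerator, denominator, asr) where the
    numerator is the summed isoform coding length (bp) and the
    denominator the union coding footprint (bp). The genome-level ratio
    aggregates per-gene sums; ``mean_gene_asr`` (the unweighted mean of
    per-gene ratios) is exposed as an alternative summary.
    """

    per_gene: dict[str, tuple[int, int, float]]
    genome_numerator: int
    genome_denominator: int
    genome_asr: float
    n_genes: int
    n_transcripts: int

    @property
    def mean_gene_asr(self) -> float:
        return sum(v[2] for v in self.per_gene.values()) / len(self.per_gene)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_id": gid, "numerator_bp": num, "denominator_bp": den, "asr": asr}
            for gid, (num, den, asr) in self.per_gene.items()
        ]
        return pd.DataFrame(rows, columns=["gene_id", "numerator_bp", "denominator_bp", "asr"])


# ---------------------------------------------------------------------------
# parsing


def _is_pseudogene(featuretype: str, attrs: Mapping[str, list[str]]) -> bool:
    if featuretype in _PSEUDOGENE_TYPES:
        return True
    for key in ("gene_biotype", "biotype", "gene_type"):
        for val in attrs.get(key, []):
            if "pseudogene" in val.lower():
                return True
    return False


def _first(attrs: Mapping[str, list[str]], key: str) -> str | None:
    vals = attrs.get(key)
    return vals[0] if vals else None


def parse_gff3(
    path: str | Path,
    exclude_genes: Iterable[str] = (),
) -> AnnotationSet:
    """Parse a GFF3 file into an :class:`AnnotationSet` of coding genes.

    Only fully resolved gene -> mRNA -> CDS chains are retained.
    Pseudogenes (by feature type or biotype), genes listed in
    ``exclude_genes``, and genes whose transcripts all lack CDS are
    excluded. CDS rows whose ``Parent`` lists several transcripts are
    attached to every listed parent (RefSeq semantics); CDS rows sharing
    an ``ID`` are parts of one transcript's CDS and are summed.

    Parameters
    ----------
    path
        GFF3 file (9 tab-separated columns, ``ID=``/``Parent=`` attributes).
    exclude_genes
        Optional gene ids to drop (e.g. a user-curated duplicate list).
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"annotation file not found: {path}")
    exclude = set(exclude_genes)

    skipped: Counter = Counter()
    genes: dict[str, GeneModel] = {}
    pseudo_ids: set[str] = set()
    excluded_tx: set[str] = set()  # transcripts of excluded genes
    transcripts: dict[str, TranscriptModel] = {}

    # Pass 1: genes. Pass 2: transcripts. Pass 3: CDS. Three passes keep
    # the resolver independent of record order in the file.
    rows: list = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") != 8:
                skipped["malformed line"] += 1
                continue
            try:
                feat = feature_from_line(line, dialect=None)
            except Exception:
                skipped["unparseable line"] += 1
                continue
            rows.append(feat)

    for feat in rows:
        if feat.featuretype in _GENE_TYPES or feat.featuretype in _PSEUDOGENE_TYPES:
            gid = _first(feat.attributes, "ID")
            if gid is None:
                skipped["gene without ID"] += 1
                continue
            if _is_pseudogene(feat.featuretype, feat.attributes):
                pseudo_ids.add(gid)
                skipped["pseudogene"] += 1
                continue
            if gid in exclude:
                pseudo_ids.add(gid)
                skipped["excluded gene"] += 1
                continue
            if gid in genes:
                # Duplicate gene ids violate GFF3; drop both copies.
                del genes[gid]
                pseudo_ids.add(gid)
                skipped["duplicate gene id"] += 2
                continue
            biotype = _first(feat.attributes, "gene_biotype") or _first(
                feat.attributes, "biotype"
            ) or "protein_coding"
            genes[gid] = GeneModel(id=gid, biotype=biotype)

    for feat in rows:
        if feat.featuretype in _TRANSCRIPT_TYPES:
            tid = _first(feat.attributes, "ID")
            if tid is None:
                skipped["transcript without ID"] += 1
                continue
            parents = feat.attributes.get("Parent", [])
            placed = False
            for pid in parents:
                if pid in genes:
                    tx = TranscriptModel(id=tid, gene_id=pid)
                    transcripts[tid] = tx
                    genes[pid].transcripts.append(tx)
                    placed = True
                    break
            if not placed:
                if any(p in pseudo_ids for p in parents):
                    excluded_tx.add(tid)
                else:
                    skipped["orphan mRNA"] += 1

    for feat in rows:
        if feat.featuretype == "CDS":
            parents = feat.attributes.get("Parent", [])
            iv = GenomicInterval(feat.seqid, feat.start, feat.end, feat.strand or ".")
            phase = int(feat.frame) if feat.frame in ("0", "1", "2") else None
            placed = False
            for pid in parents:
                if pid in transcripts:
                    transcripts[pid].segments.append(
                        CDSSegment(interval=iv, parent_transcript_id=pid, phase=phase)
                    )
                    placed = True
            if not placed:
                if any(p in excluded_tx for p in parents):
                    pass  # child of an excluded (pseudo/duplicate) gene
                else:
                    skipped["orphan CDS"] += 1

    coding_genes: list[GeneModel] = []
    for g in genes.values():
        g.transcripts = [t for t in g.transcripts if t.segments]
        if g.transcripts:
            coding_genes.append(g)
        else:
            skipped["non-coding gene"] += 1

    aset = AnnotationSet(
        genes=coding_genes,
        source_path=str(path),
        dialect="gff3",
        skipped_records=skipped,
    )
    if not coding_genes:
        warnings.warn(f"no resolvable coding genes in {path}", stacklevel=2)
    _warn_mixed_strands(aset)
    return aset


def parse_gtf(path: str | Path) -> AnnotationSet:
    """Parse a GTF file (StringTie-style) into an :class:`AnnotationSet`.

    The hierarchy is inferred from shared ``gene_id``/``transcript_id``
    attributes. A transcript with CDS rows uses them as its coding
    segments; a transcript with only exon rows (typical of StringTie
    output, which carries no CDS) uses its exons as the splicing unit
    and the set's dialect is flagged accordingly.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"annotation file not found: {path}")

    skipped: Counter = Counter()
    # transcript_id -> (gene_id, cds segments, exon segments)
    cds_by_tx: dict[str, list[CDSSegment]] = {}
    exon_by_tx: dict[str, list[CDSSegment]] = {}
    gene_of_tx: dict[str, str] = {}

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") != 8:
                skipped["malformed line"] += 1
                continue
            ninth = line.split("\t")[8]
            if "=" in ninth.split(";")[0] and '"' not in ninth:
                raise ValueError(
                    f"{path}: attribute column looks like GFF3 (ID=/Parent=); "
                    "use parse_gff3 for this file"
                )
            try:
                feat = feature_from_line(line, dialect=None)
            except Exception:
                skipped["unparseable line"] += 1
                continue
            if feat.featuretype not in ("CDS", "exon"):
                continue
            tid = _first(feat.attributes, "transcript_id")
            gid = _first(feat.attributes, "gene_id")
            if not tid or not gid:
                skipped["missing transcript_id/gene_id"] += 1
                continue
            gene_of_tx.setdefault(tid, gid)
            iv = GenomicInterval(feat.seqid, feat.start, feat.end, feat.strand or ".")
            seg = CDSSegment(interval=iv, parent_transcript_id=tid)
            target = cds_by_tx if feat.featuretype == "CDS" else exon_by_tx
            target.setdefault(tid, []).append(seg)

    genes: dict[str, GeneModel] = {}
    n_exon_fallback = 0
    for tid, gid in gene_of_tx.items():
        segs = cds_by_tx.get(tid)
        if not segs:
            segs = exon_by_tx.get(tid)
            n_exon_fallback += 1
        if not segs:
            skipped["transcript without segments"] += 1
            continue
        gene = genes.setdefault(gid, GeneModel(id=gid))
        gene.transcripts.append(TranscriptModel(id=tid, gene_id=gid, segments=segs))

    aset = AnnotationSet(
        genes=list(genes.values()),
        source_path=str(path),
        dialect="gtf",
        skipped_records=skipped,
    )
    if n_exon_fallback:
        aset.notes.append(
            f"{n_exon_fallback} transcripts had no CDS rows; exon segments used as the splicing unit"
        )
    if not genes:
        warnings.warn(f"no resolvable transcripts in {path}", stacklevel=2)
    _warn_mixed_strands(aset)
    return aset


def _warn_mixed_strands(aset: AnnotationSet) -> None:
    for g in aset.genes:
        for t in g.transcripts:
            strands = {s.interval.strand for s in t.segments} - {"."}
            if len(strands) > 1:
                warnings.warn(
                    f"transcript {t.id} has segments on mixed strands; "
                    "lengths are strand-symmetric so ASR is unaffected",
                    stacklevel=3,
                )


# ---------------------------------------------------------------------------
# ASR computation


def coding_length(transcript: TranscriptModel) -> int:
    """Cumulative coding length of one isoform: sum of segment lengths (bp)."""
    if not transcript.segments:
        raise ValueError(f"non-coding transcript: {transcript.id} has no segments")
    return sum(seg.length for seg in transcript.segments)


def gene_asr(gene: GeneModel) -> tuple[int, int, float]:
    """Per-gene ASR: (numerator, denominator, ratio).

    numerator = sum of isoform coding lengths; denominator = union
    footprint of all CDS intervals of all isoforms. The ratio is >= 1
    because every footprint base is covered by at least one isoform.
    """
    if not gene.transcripts:
        raise ValueError(f"gene {gene.id} has no coding transcripts")
    numerator = sum(coding_length(t) for t in gene.transcripts)
    denominator = union_length(seg.interval for seg in gene.all_segments())
    return numerator, denominator, numerator / denominator


def genome_asr(annotation: AnnotationSet) -> ASRResult:
    """Genome-level ASR: aggregate of per-gene numerators and denominators."""
    if not annotation.genes:
        raise ValueError("no coding genes in annotation")
    per_gene: dict[str, tuple[int, int, float]] = {}
    num_total = den_total = 0
    for g in sorted(annotation.genes, key=lambda g: g.id):
        num, den, asr = gene_asr(g)
        per_gene[g.id] = (num, den, asr)
        num_total += num
        den_total += den
    return ASRResult(
        per_gene=per_gene,
        genome_numerator=num_total,
        genome_denominator=den_total,
        genome_asr=num_total / den_total,
        n_genes=annotation.n_genes,
        n_transcripts=annotation.n_transcripts,
    )


# ---------------------------------------------------------------------------
# writers


def write_gff3(annotation: AnnotationSet, path: str | Path) -> Path:
    """Write an AnnotationSet back to GFF3 (gene -> mRNA -> CDS chains)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(annotation.genes, key=lambda g: g.id):
            segs = g.all_segments()
            seqid = segs[0].interval.seqid
            strand = segs[0].interval.strand
            gstart = min(s.interval.start for s in segs)
            gend = max(s.interval.end for s in segs)
            fh.write(
                f"{seqid}\tasrkit\tgene\t{gstart}\t{gend}\t.\t{strand}\t.\t"
                f"ID={g.id};gene_biotype={g.biotype}\n"
            )
            for t in g.transcripts:
                tstart = min(s.interval.start for s in t.segments)
                tend = max(s.interval.end for s in t.segments)
                fh.write(
                    f"{seqid}\tasrkit\tmRNA\t{tstart}\t{tend}\t.\t{strand}\t.\t"
                    f"ID={t.id};Parent={g.id}\n"
                )
                for s in t.segments:
                    phase = s.phase if s.phase is not None else 0
                    fh.write(
                        f"{s.interval.seqid}\tasrkit\tCDS\t{s.interval.start}\t"
                        f"{s.interval.end}\t.\t{s.interval.strand}\t{phase}\t"
                        f"ID=cds-{t.id};Parent={t.id}\n"
                    )
    return path


def write_per_gene_tsv(result: ASRResult, annotation: AnnotationSet, path: str | Path) -> Path:
    """Per-gene ASR table: gene_id, n_isoforms, numerator_bp, denominator_bp, asr."""
    path = Path(path)
    iso = {g.id: g.n_isoforms for g in annotation.genes}
    df = result.to_frame()
    df.insert(1, "n_isoforms", df["gene_id"].map(iso))
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def write_genome_summary(result: ASRResult, path: str | Path) -> Path:
    path = Path(path)
    summary = {
        "genome_asr": result.genome_asr,
        "mean_gene_asr": result.mean_gene_asr,
        "genome_numerator_bp": result.genome_numerator,
        "genome_denominator_bp": result.genome_denominator,
        "n_genes": result.n_genes,
        "n_transcripts": result.n_transcripts,
    }
    path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return path
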