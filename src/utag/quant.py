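"""From 3'-end reads to a gene x U-stretch-length count matrix.

The tagging assay fuses an RNA-binding protein to a poly(U) polymerase, so
bound transcripts acquire a 3' poly(U) stretch after their poly(A) tail.  On
the sequenced second read (which covers the 3' end in reverse-complement
orientation) the tail appears, once re-oriented to the sense strand, as an
A-run (the poly(A) tail) followed immediately by a T-run (the poly(U) stretch,
U encoded as T in cDNA).  This module extracts that T-run length per read,
assigns reads to genes through a strand-aware window around each gene's
transcription termination site (TTS), collapses UMI duplicates, and tabulates
the result as a :class:`~utag.matrix.UCountMatrix`.

Coordinate conventions are 0-based half-open throughout.  The sense window is
300 nt upstream to 100 nt downstream of the TTS: on the plus strand the
genomic interval [TTS-300, TTS+100); on the minus strand the mirrored
interval [TTS-99, TTS+301).  Both have length 400.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from intervaltree import IntervalTree

from . import stats as _stats
from .errors import (
    AnnotationError,
    FormatError,
    NormalizationError,
    ParameterError,
    QCError,
)
from .matrix import MAX_U, RPM_TOTAL, U_COLUMNS, UCountMatrix

#: TTS window extent: upstream (sense 5' direction) and downstream of the TTS.
WINDOW_UPSTREAM = 300
WINDOW_DOWNSTREAM = 100

_DNA = frozenset("ACGTN")
_A_RUN = re.compile(r"A+")

# ---------------------------------------------------------------------------
# tail extraction
# ---------------------------------------------------------------------------


def orient_tail(read2_sequence: str) -> str:
    """Reverse-complement read 2 back to the sense strand.

    Composing the function with itself returns the input (involution).
    """
    if not read2_sequence:
        raise FormatError("empty read sequence")
    seq = read2_sequence.upper()
    if not _DNA.issuperset(seq):
        bad = sorted(set(seq) - _DNA)
        raise FormatError(f"non-DNA characters in read: {bad}")
    return str(Seq(seq).reverse_complement())


def count_post_polya_us(
    sense_sequence: str, min_polya_run: int = 5, cap: int = MAX_U
) -> int | None:
    """Count the uridines (T on the sense cDNA strand) after the poly(A) tail.

    Locates the last A-run of length >= ``min_polya_run`` and returns the
    length of the contiguous T-run starting immediately after it, capped at
    ``cap``.  Returns ``None`` ("no_polya" rejection) when no qualifying
    A-run exists.
    """
    if not sense_sequence:
        raise FormatError("empty sequence")
    if min_polya_run < 1:
        raise ParameterError("min_polya_run must be >= 1")
    seq = sense_sequence.upper()
    last = None
    for m in _A_RUN.finditer(seq):
        if m.end() - m.start() >= min_polya_run:
            last = m
    if last is None:
        return None
    i = last.end()
    n = 0
    while i + n < len(seq) and seq[i + n] == "T":
        n += 1
    return min(n, cap)


# ---------------------------------------------------------------------------
# gene annotation and read assignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene's TTS with its derived sense counting window."""

    gene_id: str
    chrom: str
    strand: str  # "+" or "-"
    tts: int  # 0-based genomic coordinate

    def window(self) -> tuple[int, int]:
        """Genomic half-open window covering 300 nt upstream / 100 nt downstream."""
        if self.strand == "+":
            return (self.tts - WINDOW_UPSTREAM, self.tts + WINDOW_DOWNSTREAM)
        return (self.tts - WINDOW_DOWNSTREAM + 1, self.tts + WINDOW_UPSTREAM + 1)


class AnnotationIndex:
    """Strand-aware interval lookup from genomic position to gene.

    Overlapping windows are resolved to the gene with the nearest TTS;
    exact ties go to the lexicographically smaller gene_id.
    """

    def __init__(self, annotations: Iterable[GeneAnnotation]):
        self.annotations = list(annotations)
        if len({a.gene_id for a in self.annotations}) != len(self.annotations):
            raise AnnotationError("duplicate gene_id in annotation set")
        self.gene_ids = [a.gene_id for a in self.annotations]
        self._chroms = {a.chrom for a in self.annotations}
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for a in self.annotations:
            start, end = a.window()
            self._trees.setdefault((a.chrom, a.strand), IntervalTree()).addi(
                start, end, a
            )

    def assign(self, chrom: str, position: int, strand: str) -> str | None:
        """Gene whose sense window contains ``position``, or None."""
        if chrom not in self._chroms:
            raise AnnotationError(f"unknown chromosome {chrom!r}")
        tree = self._trees.get((chrom, strand))
        if tree is None:
            return None
        hits = tree[position]
        if not hits:
            return None
        best = min(hits, key=lambda iv: (abs(position - iv.data.tts), iv.data.gene_id))
        return best.data.gene_id

    # -- constructors from standard annotation formats ---------------------
    @classmethod
    def from_bed(cls, path: str | Path) -> "AnnotationIndex":
        """BED6; the TTS is the strand-aware 3' end of each feature."""
        rows = []
        for line in Path(path).read_text().splitlines():
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise FormatError(f"BED6 line with {len(f)} fields: {line!r}")
            chrom, start, end, name, _score, strand = f[:6]
            tts = int(end) - 1 if strand == "+" else int(start)
            rows.append(GeneAnnotation(name, chrom, strand, tts))
        return cls(rows)

    @classmethod
    def from_gff3(cls, path: str | Path, feature: str = "gene") -> "AnnotationIndex":
        """GFF3; keeps ``feature`` rows, gene_id from the ID attribute."""
        rows = []
        for line in Path(path).read_text().splitlines():
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9 or f[2] != feature:
                continue
            chrom, _src, _typ, start, end, _score, strand = f[:7]
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID") or attrs.get("gene_id")
            if gene_id is None:
                raise FormatError(f"GFF3 row without ID attribute: {line!r}")
            # GFF3 is 1-based inclusive; convert to 0-based.
            tts = int(end) - 1 if strand == "+" else int(start) - 1
            rows.append(GeneAnnotation(gene_id, chrom, strand, tts))
        return cls(rows)


def assign_to_gene(
    chrom: str, position: int, strand: str, annotations: "AnnotationIndex | Iterable[GeneAnnotation]"
) -> str | None:
    """Functional wrapper around :meth:`AnnotationIndex.assign`."""
    index = (
        annotations
        if isinstance(annotations, AnnotationIndex)
        else AnnotationIndex(annotations)
    )
    return index.assign(chrom, position, strand)


# ---------------------------------------------------------------------------
# record-level processing
# ---------------------------------------------------------------------------


def dedup_umis(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate molecules: one record per (gene_id, UMI).

    The record with the largest u_count wins; among equals, the first
    encountered.  Records without a gene assignment pass through untouched.
    """
    if records.empty:
        return records
    assigned = records[records["gene_id"].notna()]
    unassigned = records[records["gene_id"].isna()]
    kept = (
        assigned.sort_values("u_count", ascending=False, kind="stable")
        .drop_duplicates(subset=["gene_id", "umi"], keep="first")
    )
    return pd.concat([kept, unassigned]).sort_index()


def build_matrix(
    records: pd.DataFrame,
    annotations: "AnnotationIndex | Iterable[GeneAnnotation]",
    **meta,
) -> UCountMatrix:
    """Tabulate deduplicated, assigned records into a raw count matrix.

    Every annotated gene appears as a row even with zero reads.
    """
    index = (
        annotations
        if isinstance(annotations, AnnotationIndex)
        else AnnotationIndex(annotations)
    )
    gene_ids = index.gene_ids
    counts = pd.DataFrame(
        np.zeros((len(gene_ids), len(U_COLUMNS)), dtype=np.int64),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=U_COLUMNS,
    )
    if not records.empty:
        valid = records[records["gene_id"].notna() & records["u_count"].notna()]
        tab = (
            valid.assign(u=lambda d: d["u_count"].astype(int).clip(0, MAX_U))
            .groupby(["gene_id", "u"])
            .size()
        )
        for (gene, u), n in tab.items():
            counts.at[gene, u] = n
    return UCountMatrix(counts=counts, normalized=False, **meta)


def extract_records(
    read_table: pd.DataFrame,
    annotations: "AnnotationIndex | Iterable[GeneAnnotation]",
    min_polya_run: int = 5,
    cap: int = MAX_U,
) -> pd.DataFrame:
    """Orient, extract and assign every read of a read table.

    ``read_table`` columns: read_id, umi, chrom, pos, strand, tail_seq
    (tail_seq is the raw read-2 sequence).  Returns a record frame with
    gene_id, u_count and a rejection ``reason`` ("" for accepted reads).
    """
    index = (
        annotations
        if isinstance(annotations, AnnotationIndex)
        else AnnotationIndex(annotations)
    )
    genes: list[str | None] = []
    u_counts: list[float] = []
    reasons: list[str] = []
    for row in read_table.itertuples(index=False):
        sense = orient_tail(row.tail_seq)
        u = count_post_polya_us(sense, min_polya_run=min_polya_run, cap=cap)
        gene = index.assign(row.chrom, int(row.pos), row.strand)
        if u is None:
            genes.append(gene)
            u_counts.append(np.nan)
            reasons.append("no_polya")
        elif gene is None:
            genes.append(None)
            u_counts.append(u)
            reasons.append("unassigned")
        else:
            genes.append(gene)
            u_counts.append(u)
            reasons.append("")
    out = read_table[["read_id", "umi"]].copy()
    out["gene_id"] = genes
    out["u_count"] = u_counts
    out["reason"] = reasons
    return out


def process_read_table(
    read_table: pd.DataFrame,
    annotations: "AnnotationIndex | Iterable[GeneAnnotation]",
    min_polya_run: int = 5,
    cap: int = MAX_U,
    dedup: bool = True,
    **meta,
) -> UCountMatrix:
    """Full read pipeline: orient -> count -> assign -> dedup -> tabulate."""
    index = (
        annotations
        if isinstance(annotations, AnnotationIndex)
        else AnnotationIndex(annotations)
    )
    rec = extract_records(read_table, index, min_polya_run=min_polya_run, cap=cap)
    rec = rec[rec["reason"] == ""]
    if dedup:
        rec = dedup_umis(rec)
    return build_matrix(rec, index, **meta)


def read_table_from_fastq(
    fastq2: str | Path, alignment_table: str | Path | pd.DataFrame
) -> pd.DataFrame:
    """Join read-2 FASTQ sequences with an alignment table on read_id.

    The alignment table (TSV or DataFrame) carries read_id, umi, chrom, pos,
    strand; the FASTQ supplies tail_seq.  Aligners themselves are out of
    scope — their output is an input here.
    """
    if not isinstance(alignment_table, pd.DataFrame):
        alignment_table = pd.read_csv(alignment_table, sep="\t")
    seqs = {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(fastq2), "fastq")
    }
    missing = set(alignment_table["read_id"]) - set(seqs)
    if missing:
        raise FormatError(f"{len(missing)} aligned reads absent from FASTQ")
    out = alignment_table.copy()
    out["tail_seq"] = out["read_id"].map(seqs)
    return out


# ---------------------------------------------------------------------------
# normalization and replicate merging
# ---------------------------------------------------------------------------


def normalize_rpm(matrix: UCountMatrix) -> UCountMatrix:
    """Scale the matrix to a grand total of one million counts (RPM).

    Idempotent: a normalized matrix is returned unchanged.
    """
    if matrix.normalized:
        return matrix.copy()
    total = matrix.total()
    if total <= 0:
        raise NormalizationError("cannot normalize a matrix with zero total")
    scaled = matrix.counts * (RPM_TOTAL / total)
    out = matrix.copy()
    out.counts = scaled
    out.normalized = True
    return out


def merge_replicates(
    matrices: Sequence[UCountMatrix],
    min_reads: int = 200_000,
    min_reliability: float | None = None,
) -> UCountMatrix:
    """QC-filter, RPM-normalize, average and re-normalize replicate matrices.

    A replicate passes when its raw read total exceeds ``min_reads`` OR its
    median binding reliability reaches ``min_reliability`` (when given).
    """
    if not matrices:
        raise ParameterError("no replicate matrices given")
    gene_sets = {tuple(m.gene_ids) for m in matrices}
    if len(gene_sets) != 1:
        raise ParameterError("replicates must share the same gene rows")
    passing = []
    report = []
    for i, m in enumerate(matrices):
        total = m.total_reads if m.total_reads is not None else int(m.total())
        rel = np.nan
        if min_reliability is not None:
            try:
                _, rel = _stats.median_reliability(
                    _stats.stretch_correlations(normalize_rpm(m))
                )
            except Exception:
                rel = np.nan
        ok = total > min_reads or (
            min_reliability is not None
            and np.isfinite(rel)
            and rel >= min_reliability
        )
        report.append(f"replicate {i}: total={total}, reliability={rel}")
        if ok:
            passing.append(m)
    if not passing:
        raise QCError("no replicate passed QC; " + "; ".join(report))
    norm = [normalize_rpm(m).counts for m in passing]
    mean = sum(norm) / len(norm)
    merged = UCountMatrix(
        counts=mean,
        sample_id=passing[0].sample_id,
        strain=passing[0].strain,
        enzyme_active=passing[0].enzyme_active,
        normalized=True,
        total_reads=sum(
            m.total_reads if m.total_reads is not None else int(m.total())
            for m in passing
        ),
    )
    # averaging preserves the total up to float error; re-normalize exactly
    merged.counts *= RPM_TOTAL / merged.total()
    return merged
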