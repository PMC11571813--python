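"""Synthetic tagging experiments and ortholog groups with known ground truth.

The generator emulates the generative structure of the tagging assay:

* transcript abundance is heavy-tailed (log-normal weights);
* a subset of genes are true targets; each target transcript molecule
  carries a bona fide poly(U) tail (length 4..16, concentrated in 4..13)
  with probability ``tailed_fraction``;
* every *untailed* molecule can instead acquire a spurious 1-3 U stretch
  (sequencing error) with probability ``error_stretch_rate``, independent of
  gene identity — so error counts scale with abundance;
* the catalytically dead enzyme control is the same molecule stream with
  tailing switched off: only error stretches remain.

The same seeded molecule stream drives both the count-level simulator and
the read-level simulator, so a read-level simulation pushed through the
quantification pipeline reproduces the count-level matrix exactly.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .architecture import Domain, ProteinArchitecture
from .errors import ContractError, ParameterError
from .matrix import MAX_U, UCountMatrix
from .quant import AnnotationIndex, GeneAnnotation, orient_tail

TAIL_SUPPORT = np.arange(4, MAX_U + 1)  # 4..16
ERROR_SUPPORT = np.arange(1, 4)  # 1..3

#: 3' sequencing-adapter stub appended after the tail on the sense strand.
#: Must not begin with T and must not contain an A-run that could be mistaken
#: for a poly(A) tail.
ADAPTER_STUB = "AGATCGGAAGAGC"


def uniform_tail_dist(lo: int = 4, hi: int = 13) -> np.ndarray:
    """Uniform tail-length distribution on lo..hi over the 4..16 support."""
    p = np.zeros(len(TAIL_SUPPORT))
    sel = (TAIL_SUPPORT >= lo) & (TAIL_SUPPORT <= hi)
    p[sel] = 1.0 / sel.sum()
    return p


def point_tail_dist(length: int) -> np.ndarray:
    """Point-mass tail-length distribution at ``length``."""
    p = np.zeros(len(TAIL_SUPPORT))
    p[TAIL_SUPPORT == length] = 1.0
    if p.sum() != 1.0:
        raise ParameterError(f"tail length {length} outside 4..{MAX_U}")
    return p


@dataclass
class SimulationParams:
    """Study conditions of one synthetic tagging experiment.

    Defaults are the reference experiment used throughout the test suite:
    2000 genes with log-normal abundance (scale 1.5), 200 targets with a
    20% tailed fraction and tails uniform on 4..13, a 5% per-molecule error
    rate with 1-3 U error stretches, and one million reads.
    """

    n_genes: int = 2000
    n_targets: int = 200
    tailed_fraction: float = 0.2
    tail_length_dist: np.ndarray = field(default_factory=uniform_tail_dist)
    error_stretch_rate: float = 0.05
    error_length_dist: np.ndarray = field(
        default_factory=lambda: np.full(3, 1.0 / 3.0)
    )
    total_reads: int = 1_000_000
    expression_mu: float = 0.0
    expression_sigma: float = 1.5
    enzyme_active: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.tail_length_dist = np.asarray(self.tail_length_dist, dtype=float)
        self.error_length_dist = np.asarray(self.error_length_dist, dtype=float)
        if self.n_genes < 1 or self.total_reads < 1:
            raise ParameterError("n_genes and total_reads must be positive")
        if self.n_targets > self.n_genes or self.n_targets < 0:
            raise ParameterError("need 0 <= n_targets <= n_genes")
        if not (0.0 <= self.tailed_fraction <= 1.0):
            raise ParameterError("tailed_fraction must be in [0, 1]")
        if not (0.0 <= self.error_stretch_rate <= 1.0):
            raise ParameterError("error_stretch_rate must be in [0, 1]")
        if len(self.tail_length_dist) != len(TAIL_SUPPORT) or not np.isclose(
            self.tail_length_dist.sum(), 1.0, atol=1e-8
        ):
            raise ParameterError("tail_length_dist must sum to 1 over lengths 4..16")
        if len(self.error_length_dist) != len(ERROR_SUPPORT) or not np.isclose(
            self.error_length_dist.sum(), 1.0, atol=1e-8
        ):
            raise ParameterError("error_length_dist must sum to 1 over lengths 1..3")
        if not self.enzyme_active:
            # dead enzyme cannot tail anything
            self.tailed_fraction = 0.0

    def dead_variant(self) -> "SimulationParams":
        """Same experiment with the catalytically dead enzyme."""
        return dataclasses.replace(self, enzyme_active=False)


@dataclass
class SimulationTruth:
    """Ground truth of one synthetic experiment."""

    gene_ids: list[str]
    expression_weights: np.ndarray
    target_flags: np.ndarray
    tailed_fraction: np.ndarray  # per gene (0 for non-targets)
    params: SimulationParams
    seed: int

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "expression_weight": self.expression_weights,
                "is_target": self.target_flags.astype(int),
                "tailed_fraction": self.tailed_fraction,
            }
        ).to_csv(path, sep="\t", index=False)


def _streams(seed: int) -> tuple[np.random.Generator, np.random.Generator, np.random.Generator]:
    """Independent deterministic streams: truth, molecules, read details."""
    children = np.random.SeedSequence(seed).spawn(3)
    return tuple(np.random.default_rng(c) for c in children)


def simulate_truth(params: SimulationParams) -> SimulationTruth:
    """Draw abundance weights and target flags for one experiment."""
    rng, _, _ = _streams(params.seed)
    x = rng.lognormal(params.expression_mu, params.expression_sigma, params.n_genes)
    weights = x / x.sum()
    flags = np.zeros(params.n_genes, dtype=bool)
    if params.n_targets:
        flags[rng.choice(params.n_genes, size=params.n_targets, replace=False)] = True
    width = max(4, len(str(params.n_genes - 1)))
    gene_ids = [f"g{i:0{width}d}" for i in range(params.n_genes)]
    return SimulationTruth(
        gene_ids=gene_ids,
        expression_weights=weights,
        target_flags=flags,
        tailed_fraction=np.where(flags, params.tailed_fraction, 0.0),
        params=params,
        seed=params.seed,
    )


def _molecule_stream(
    truth: SimulationTruth, params: SimulationParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-molecule (gene index, U-stretch length) for ``total_reads`` molecules.

    Draws are consumed identically whether or not the enzyme is active, so an
    active/dead pair with the same seed shares its molecule-to-gene
    assignment and error events.
    """
    n = params.total_reads
    gene_idx = rng.choice(truth.n_genes, size=n, p=truth.expression_weights)
    tail_draw = rng.random(n)
    tail_len = rng.choice(TAIL_SUPPORT, size=n, p=params.tail_length_dist)
    err_draw = rng.random(n)
    err_len = rng.choice(ERROR_SUPPORT, size=n, p=params.error_length_dist)
    if params.enzyme_active:
        tailed = tail_draw < truth.tailed_fraction[gene_idx]
    else:
        tailed = np.zeros(n, dtype=bool)
    u = np.where(tailed, tail_len, 0)
    error = ~tailed & (err_draw < params.error_stretch_rate)
    u = np.where(error, err_len, u)
    return gene_idx, np.minimum(u, MAX_U)


def simulate_ucount_matrix(
    truth: SimulationTruth, params: SimulationParams
) -> UCountMatrix:
    """Count-level simulation: raw gene x U-length matrix summing to total_reads."""
    if truth.n_genes != params.n_genes:
        raise ContractError("truth and params disagree on n_genes")
    _, rng, _ = _streams(params.seed)
    gene_idx, u = _molecule_stream(truth, params, rng)
    flat = np.bincount(
        gene_idx * (MAX_U + 1) + u, minlength=truth.n_genes * (MAX_U + 1)
    )
    counts = pd.DataFrame(
        flat.reshape(truth.n_genes, MAX_U + 1),
        index=pd.Index(truth.gene_ids, name="gene_id"),
        columns=list(range(MAX_U + 1)),
    )
    return UCountMatrix(
        counts=counts,
        sample_id=f"sim_seed{params.seed}",
        strain="active" if params.enzyme_active else "dead",
        enzyme_active=params.enzyme_active,
        normalized=False,
    )


def simulate_dead_control(
    truth: SimulationTruth, params: SimulationParams
) -> UCountMatrix:
    """The paired catalytically dead control: error stretches only."""
    return simulate_ucount_matrix(truth, params.dead_variant())


# ---------------------------------------------------------------------------
# read-level simulation
# ---------------------------------------------------------------------------


@dataclass
class ToyTranscriptome:
    """Per-gene 3'-end geometry and sequence for read simulation."""

    genes: pd.DataFrame  # gene_id, chrom, strand, tts, body

    def annotations(self) -> list[GeneAnnotation]:
        return [
            GeneAnnotation(row.gene_id, row.chrom, row.strand, int(row.tts))
            for row in self.genes.itertuples(index=False)
        ]

    def annotation_index(self) -> AnnotationIndex:
        return AnnotationIndex(self.annotations())

    def to_bed(self, path: str | Path) -> None:
        """BED6 with the TTS at the strand-aware 3' end of each feature."""
        with open(path, "w") as fh:
            for row in self.genes.itertuples(index=False):
                tts = int(row.tts)
                if row.strand == "+":
                    start, end = tts - 399, tts + 1
                else:
                    start, end = tts, tts + 400
                fh.write(
                    f"{row.chrom}\t{start}\t{end}\t{row.gene_id}\t0\t{row.strand}\n"
                )


def _break_runs(seq: str, base: str, max_run: int) -> str:
    """Interrupt runs of ``base`` longer than ``max_run`` (keeps alphabet)."""
    sub = {"A": "C", "C": "A", "G": "C", "T": "G"}[base]

    def repl(m: re.Match) -> str:
        run = m.group()
        return "".join(
            sub if (i + 1) % (max_run + 1) == 0 else ch for i, ch in enumerate(run)
        )

    return re.sub(base + "{" + str(max_run + 1) + ",}", repl, seq)


def make_toy_transcriptome(
    truth: SimulationTruth,
    seed: int | None = None,
    body_length: int = 400,
    spacing: int = 2000,
) -> ToyTranscriptome:
    """Lay genes along one synthetic chromosome with disjoint TTS windows.

    The body covers the 400-nt TTS window; internal A-runs longer than 4 are
    interrupted so the poly(A) tail is always the last qualifying A-run on a
    read's sense strand.
    """
    if body_length < 50:
        raise ParameterError("body length must be >= 50")
    rng = np.random.default_rng(truth.seed + 7 if seed is None else seed)
    rows = []
    pos = 500
    for gid in truth.gene_ids:
        strand = "+" if rng.random() < 0.5 else "-"
        body = "".join(rng.choice(list("ACGT"), size=body_length))
        body = _break_runs(body, "A", 4)
        body = _break_runs(body, "T", 4)
        tts = pos + 300 if strand == "+" else pos + 99
        rows.append(
            {"gene_id": gid, "chrom": "chrSim", "strand": strand, "tts": tts, "body": body}
        )
        pos += spacing
    return ToyTranscriptome(genes=pd.DataFrame(rows))


_BASES = np.array(list("ACGT"))


def simulate_reads(
    truth: SimulationTruth,
    params: SimulationParams,
    transcriptome: ToyTranscriptome,
    out_dir: str | Path | None = None,
    read_length: int = 60,
    unique_umis: bool = True,
) -> pd.DataFrame:
    """Read-level simulation of the same molecule stream as the count-level one.

    Returns a read table (read_id, umi, chrom, pos, strand, tail_seq) whose
    tail_seq is the raw read-2 sequence; pushing it through
    :func:`utag.quant.process_read_table` with the transcriptome's annotation
    index reproduces :func:`simulate_ucount_matrix` for the same seed.  When
    ``out_dir`` is given, paired FASTQ files, the read table and the truth
    table are written there.

    ``unique_umis`` redraws colliding UMIs within a gene so UMI collapse is a
    no-op on simulated data; set False to keep raw random 8-mers.
    """
    if truth.n_genes != len(transcriptome.genes):
        raise ContractError("transcriptome does not cover all simulated genes")
    _, rng_mol, rng = _streams(params.seed)
    gene_idx, u = _molecule_stream(truth, params, rng_mol)
    n = params.total_reads
    genes = transcriptome.genes
    body_len = len(genes["body"].iloc[0])
    if body_len < read_length:
        raise ParameterError("gene body shorter than the requested read length")

    polya = rng.integers(10, 31, size=n)
    offsets = rng.integers(0, body_len - read_length + 1, size=n)
    umi_mat = _BASES[rng.integers(0, 4, size=(n, 8))]
    umis = np.array(["".join(row) for row in umi_mat])
    if unique_umis:
        # redraw collisions within each gene so dedup is a no-op
        df = pd.DataFrame({"g": gene_idx, "umi": umis})
        dup = df.duplicated(["g", "umi"])
        while dup.any():
            idx = np.flatnonzero(dup.to_numpy())
            redraw = _BASES[rng.integers(0, 4, size=(len(idx), 8))]
            umis[idx] = ["".join(row) for row in redraw]
            df["umi"] = umis
            dup = df.duplicated(["g", "umi"])

    chroms = genes["chrom"].to_numpy()[gene_idx]
    strands = genes["strand"].to_numpy()[gene_idx]
    tts = genes["tts"].to_numpy()[gene_idx]
    bodies = genes["body"].to_numpy()[gene_idx]

    # leftmost genomic coordinate of read 1 (a sense fragment in the window)
    win_start = np.where(strands == "+", tts - 300, tts - 99)
    pos = win_start + offsets

    read_ids = np.array([f"r{i:07d}" for i in range(n)])
    tail_seqs = []
    read1_seqs = []
    for i in range(n):
        body = bodies[i]
        sense_tail = (
            body[-20:] + "A" * int(polya[i]) + "T" * int(u[i]) + ADAPTER_STUB
        )
        read2 = orient_tail(sense_tail)[:read_length]
        tail_seqs.append(read2)
        read1_seqs.append(body[offsets[i] : offsets[i] + read_length])

    table = pd.DataFrame(
        {
            "read_id": read_ids,
            "umi": umis,
            "chrom": chroms,
            "pos": pos,
            "strand": strands,
            "tail_seq": tail_seqs,
        }
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        qual = "I" * read_length
        with open(out_dir / "reads_R1.fastq", "w") as f1, open(
            out_dir / "reads_R2.fastq", "w"
        ) as f2:
            for i in range(n):
                f1.write(f"@{read_ids[i]}\n{read1_seqs[i]}\n+\n{qual[: len(read1_seqs[i])]}\n")
                f2.write(
                    f"@{read_ids[i]}\n{tail_seqs[i]}\n+\n{qual[: len(tail_seqs[i])]}\n"
                )
        table.drop(columns="tail_seq").to_csv(
            out_dir / "alignments.tsv", sep="\t", index=False
        )
        table.to_csv(out_dir / "read_table.tsv", sep="\t", index=False)
        truth.to_tsv(out_dir / "truth.tsv")
        transcriptome.to_bed(out_dir / "annotation.bed")
    return table


# ---------------------------------------------------------------------------
# synthetic ortholog groups
# ---------------------------------------------------------------------------


@dataclass
class SimulatedOrthologGroup:
    """An ortholog group derived from a template, with divergence ground truth."""

    members: list[ProteinArchitecture]
    retained_all_domains: list[bool]
    template: ProteinArchitecture
    seed: int


_AAS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_IDR_AAS = np.array(list("DEKRNQSPG"))  # disorder-promoting residues


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0 or not seq:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    arr[hit] = _AAS[rng.integers(0, len(_AAS), size=hit.sum())]
    return "".join(arr)


def simulate_ortholog_group(
    template: ProteinArchitecture,
    n_orthologs: int,
    substitution_rate: float = 0.05,
    idr_indel_rate: float = 0.02,
    domain_loss_prob: float = 0.0,
    seed: int = 0,
) -> SimulatedOrthologGroup:
    """Derive orthologs from a template by substitution, IDR indels and domain loss.

    Each domain is lost independently with ``domain_loss_prob``; linker/IDR
    segments undergo point substitutions and length-changing indels; the
    disorder profile is regenerated with low scores inside retained domains
    and scores mirroring the template's segment character outside.  The truth
    records which orthologs retained every template domain.
    """
    for rate in (substitution_rate, idr_indel_rate, domain_loss_prob):
        if not (0.0 <= rate <= 1.0):
            raise ParameterError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    # template pieces in order: alternating linker / domain
    dom_spans = [(fam, s, e) for fam, s, e in template.domains]
    pieces: list[tuple[str, Domain | None, str, np.ndarray]] = []
    cursor = 1
    for fam, s, e in dom_spans:
        if s > cursor:
            pieces.append(
                ("linker", None, template.sequence[cursor - 1 : s - 1],
                 template.disorder[cursor - 1 : s - 1])
            )
        pieces.append(
            ("domain", (fam, s, e), template.sequence[s - 1 : e],
             template.disorder[s - 1 : e])
        )
        cursor = e + 1
    if cursor <= template.length:
        pieces.append(
            ("linker", None, template.sequence[cursor - 1 :],
             template.disorder[cursor - 1 :])
        )

    members: list[ProteinArchitecture] = []
    retained_all: list[bool] = []
    n_dom = len(dom_spans)
    for k in range(n_orthologs):
        keep = rng.random(n_dom) >= domain_loss_prob
        seq_parts: list[str] = []
        dis_parts: list[np.ndarray] = []
        domains: list[Domain] = []
        di = 0
        for kind, dom, seq, dis in pieces:
            if kind == "domain":
                kept = keep[di]
                di += 1
                if not kept:
                    continue
                new_seq = _mutate(seq, substitution_rate, rng)
                start = sum(len(s) for s in seq_parts) + 1
                domains.append((dom[0], start, start + len(new_seq) - 1))
                seq_parts.append(new_seq)
                dis_parts.append(rng.uniform(0.05, 0.30, size=len(new_seq)))
            else:
                new_seq = _mutate(seq, substitution_rate, rng)
                # indels restricted to non-domain segments
                n_indel = rng.poisson(idr_indel_rate * max(len(new_seq), 1))
                for _ in range(n_indel):
                    if len(new_seq) > 1 and rng.random() < 0.5:
                        j = int(rng.integers(0, len(new_seq)))
                        new_seq = new_seq[:j] + new_seq[j + 1 :]
                    else:
                        j = int(rng.integers(0, len(new_seq) + 1))
                        ins = str(_IDR_AAS[rng.integers(0, len(_IDR_AAS))])
                        new_seq = new_seq[:j] + ins + new_seq[j:]
                disordered = bool(len(dis) and dis.mean() > 0.5)
                lo, hi = (0.70, 0.95) if disordered else (0.15, 0.45)
                seq_parts.append(new_seq)
                dis_parts.append(rng.uniform(lo, hi, size=len(new_seq)))
        members.append(
            ProteinArchitecture(
                protein_id=f"{template.protein_id}_orth{k:02d}",
                species=f"sp{k:02d}",
                sequence="".join(seq_parts),
                domains=domains,
                disorder=np.concatenate(dis_parts) if dis_parts else np.empty(0),
            )
        )
        retained_all.append(bool(keep.all()))
    return SimulatedOrthologGroup(
        members=members,
        retained_all_domains=retained_all,
        template=template,
        seed=seed,
    )


def make_template_protein(
    n_domains: int = 2,
    domain_length: int = 70,
    linker_length: int = 80,
    families: tuple[str, ...] = ("RRM", "KH", "PUM", "ZnF"),
    seed: int = 0,
) -> ProteinArchitecture:
    """A synthetic template protein: ordered domains separated by long IDR linkers."""
    rng = np.random.default_rng(seed)
    seq_parts = []
    dis_parts = []
    domains: list[Domain] = []
    pos = 1
    for i in range(n_domains + 1):
        L = linker_length
        seq_parts.append("".join(rng.choice(_IDR_AAS, size=L)))
        dis_parts.append(rng.uniform(0.70, 0.95, size=L))
        pos += L
        if i < n_domains:
            fam = families[i % len(families)]
            seq_parts.append("".join(rng.choice(_AAS, size=domain_length)))
            dis_parts.append(rng.uniform(0.05, 0.30, size=domain_length))
            domains.append((fam, pos, pos + domain_length - 1))
            pos += domain_length
    return ProteinArchitecture(
        protein_id="template",
        species="S.cerevisiae",
        sequence="".join(seq_parts),
        domains=domains,
        disorder=np.concatenate(dis_parts),
    )
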