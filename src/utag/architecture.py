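"""Domain/IDR architecture of RNA-binding proteins and its conservation.

An RNA-binding protein is modelled as a sequence with an ordered list of
annotated binding domains (Pfam-style, 1-based inclusive coordinates) and a
per-residue disorder score in [0, 1].  Residues outside all domains with
disorder strictly above 0.5 form the intrinsically disordered regions (IDRs).

Cross-species conservation works on ortholog groups.  Domains are matched
across orthologs by (family, rank-within-family) after sorting by position;
the *ancestral composition* is the set of (family, rank) pairs present in
strictly more than 30% of orthologs, in consensus order.  An ortholog has a
*conserved organization* when its domain-family sequence contains the
ancestral family list as an in-order subsequence.  IDR conservation is then
quantified per inter-domain segment (N-terminal, between consecutive
ancestral domains, C-terminal): a segment is an IDR segment when its average
disorder across orthologs exceeds 0.5 and its average length is at least 15
residues, and its variability is the ratio std/mean (sample std, n-1) of
disordered-residue counts over the conserved-organization orthologs.

Disorder scores and domain tables are *inputs* (produced upstream by
predictors such as IUPred and HMMER, which are out of scope here).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import ContractError, FormatError, UndefinedCompositionError

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

Domain = tuple[str, int, int]  # (family, start, end), 1-based inclusive


@dataclass
class ProteinArchitecture:
    """A protein's sequence, domain annotation and disorder profile."""

    protein_id: str
    species: str
    sequence: str
    domains: list[Domain]
    disorder: np.ndarray

    def __post_init__(self) -> None:
        self.disorder = np.asarray(self.disorder, dtype=float)
        L = len(self.sequence)
        if len(self.disorder) != L:
            raise ContractError(
                f"{self.protein_id}: disorder length {len(self.disorder)} != sequence length {L}"
            )
        for fam, start, end in self.domains:
            if not (1 <= start <= end <= L):
                raise ContractError(
                    f"{self.protein_id}: domain {fam} [{start},{end}] outside 1..{L}"
                )
        self.domains = sorted(self.domains, key=lambda d: (d[1], d[2], d[0]))

    @property
    def length(self) -> int:
        return len(self.sequence)


def merge_intervals(domains: Iterable[Domain]) -> list[tuple[int, int]]:
    """Union of domain spans as disjoint (start, end) intervals, 1-based inclusive."""
    spans = sorted((s, e) for _, s, e in domains)
    merged: list[tuple[int, int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def domain_mask(protein: ProteinArchitecture) -> np.ndarray:
    """Boolean per-residue mask of residues inside any annotated domain."""
    mask = np.zeros(protein.length, dtype=bool)
    for s, e in merge_intervals(protein.domains):
        mask[s - 1 : e] = True
    return mask


def idr_mask(protein: ProteinArchitecture, cutoff: float = 0.5) -> np.ndarray:
    """Residues outside all domains with disorder strictly above ``cutoff``."""
    return ~domain_mask(protein) & (protein.disorder > cutoff)


def region_fractions(
    protein: ProteinArchitecture, cutoff: float = 0.5
) -> tuple[float, float, float]:
    """(domain, IDR, other) residue fractions; they sum to 1.

    Overlapping domain annotations are merged so each residue counts once.
    """
    dom = domain_mask(protein)
    idr = idr_mask(protein, cutoff=cutoff)
    L = protein.length
    f_dom = dom.sum() / L
    f_idr = idr.sum() / L
    return float(f_dom), float(f_idr), float(1.0 - f_dom - f_idr)


def domain_span_fraction(protein: ProteinArchitecture) -> float | None:
    """Fraction of the sequence spanned from first domain start to last domain end.

    None (missing) when the protein has no annotated domain.
    """
    if not protein.domains:
        return None
    start = min(s for _, s, _ in protein.domains)
    end = max(e for _, _, e in protein.domains)
    return float((end - start + 1) / protein.length)


def aa_composition(
    protein: ProteinArchitecture, mask: np.ndarray | None = None
) -> pd.Series:
    """Frequency vector over the 20 canonical residues under ``mask``.

    Defaults to the IDR mask.  Non-canonical letters are dropped with a
    warning folded into normalization (frequencies sum to 1 over canonical).
    """
    if mask is None:
        mask = idr_mask(protein)
    if mask.sum() == 0:
        raise UndefinedCompositionError(f"{protein.protein_id}: empty residue mask")
    residues = [aa for aa, keep in zip(protein.sequence, mask) if keep]
    counts = pd.Series(0.0, index=list(AA_ALPHABET))
    for aa in residues:
        if aa in counts.index:
            counts[aa] += 1
    total = counts.sum()
    if total == 0:
        raise UndefinedCompositionError(
            f"{protein.protein_id}: no canonical residues under mask"
        )
    return counts / total


@dataclass
class CompositionMatrix:
    """IDR amino-acid compositions, their pairwise correlation, and ordering."""

    compositions: pd.DataFrame  # proteins x 20
    correlations: pd.DataFrame  # proteins x proteins
    order: list[str]  # descending similarity to the mean TF composition


def composition_correlation(
    proteins: Sequence[ProteinArchitecture],
    group_labels: Mapping[str, str] | None = None,
    reference_group: str = "TF",
) -> CompositionMatrix:
    """Pairwise Pearson correlation of IDR compositions.

    Rows are ordered by descending correlation with the average composition
    of proteins labelled ``reference_group`` (transcription factors in the
    original analysis); without such labels the input order is kept.
    """
    comps = {}
    for p in proteins:
        comps[p.protein_id] = aa_composition(p)
    if len(comps) < 2:
        raise ContractError("need at least 2 proteins with non-empty IDRs")
    comp_df = pd.DataFrame(comps).T
    corr = comp_df.T.corr(method="pearson")
    order = list(comp_df.index)
    ref_ids = [
        pid for pid in order
        if group_labels is not None and group_labels.get(pid) == reference_group
    ]
    if ref_ids:
        ref = comp_df.loc[ref_ids].mean(axis=0)
        sim = comp_df.T.corrwith(ref)
        order = list(sim.sort_values(ascending=False, kind="stable").index)
    comp_df = comp_df.loc[order]
    corr = corr.loc[order, order]
    return CompositionMatrix(compositions=comp_df, correlations=corr, order=order)


# ---------------------------------------------------------------------------
# ortholog groups
# ---------------------------------------------------------------------------

RankedDomain = tuple[str, int]  # (family, rank within family, 1-based)


def _ranked_domains(protein: ProteinArchitecture) -> list[RankedDomain]:
    """Domains sorted by position, each labelled with its rank within its family."""
    seen: dict[str, int] = {}
    out = []
    for fam, _s, _e in protein.domains:
        seen[fam] = seen.get(fam, 0) + 1
        out.append((fam, seen[fam]))
    return out


def ancestral_composition(
    members: Sequence[ProteinArchitecture], presence_fraction: float = 0.30
) -> list[RankedDomain]:
    """(family, rank) pairs present in strictly more than ``presence_fraction``
    of orthologs, in consensus order (median relative position)."""
    if not members:
        raise ContractError("empty ortholog group")
    n = len(members)
    presence: dict[RankedDomain, int] = {}
    positions: dict[RankedDomain, list[float]] = {}
    for p in members:
        ranked = _ranked_domains(p)
        for (fam, rank), (f2, s, _e) in zip(ranked, p.domains):
            assert fam == f2
            presence[(fam, rank)] = presence.get((fam, rank), 0) + 1
            positions.setdefault((fam, rank), []).append(s / max(p.length, 1))
    kept = [rd for rd, c in presence.items() if c / n > presence_fraction]
    kept.sort(key=lambda rd: (float(np.median(positions[rd])), rd[0], rd[1]))
    return kept


def _is_subsequence(needle: Sequence[str], haystack: Sequence[str]) -> bool:
    it = iter(haystack)
    return all(any(x == y for y in it) for x in needle)


def has_conserved_organization(
    protein: ProteinArchitecture, ancestral: Sequence[RankedDomain]
) -> bool:
    """Does the protein contain all ancestral domain families in the right order?"""
    families = [fam for fam, _s, _e in protein.domains]
    return _is_subsequence([fam for fam, _r in ancestral], families)


def conserved_fraction(
    members: Sequence[ProteinArchitecture],
    ancestral: Sequence[RankedDomain] | None = None,
) -> tuple[float, list[bool]]:
    """Fraction of orthologs with conserved domain organization, plus per-member flags."""
    if not members:
        raise ContractError("empty ortholog group")
    if ancestral is None:
        ancestral = ancestral_composition(members)
    flags = [has_conserved_organization(p, ancestral) for p in members]
    return float(np.mean(flags)), flags


def _match_ancestral_spans(
    protein: ProteinArchitecture, ancestral: Sequence[RankedDomain]
) -> list[tuple[int, int]] | None:
    """Greedy in-order match of ancestral families to the protein's domains.

    Returns the matched (start, end) spans, or None when the organization is
    not conserved.
    """
    spans: list[tuple[int, int]] = []
    i = 0
    domains = protein.domains
    for fam, _rank in ancestral:
        while i < len(domains) and domains[i][0] != fam:
            i += 1
        if i == len(domains):
            return None
        spans.append((domains[i][1], domains[i][2]))
        i += 1
    return spans


@dataclass
class IDRSegment:
    """One qualifying inter-domain segment across an ortholog group."""

    key: str  # "N-term", "between_1_2", ..., "C-term"
    mean_length: float
    mean_disorder: float
    mean_count: float  # disordered residues, averaged over conserved orthologs
    std_count: float  # sample std (n-1)
    ratio: float  # std/mean


@dataclass
class OrthologGroup:
    """Conservation summary of one protein across species."""

    group_id: str
    members: list[ProteinArchitecture]
    ancestral: list[RankedDomain]
    conserved_fraction: float
    conserved_flags: list[bool]
    idr_segments: list[IDRSegment] = field(default_factory=list)
    mean_ratio: float | None = None


def idr_segment_conservation(
    members: Sequence[ProteinArchitecture],
    ancestral: Sequence[RankedDomain],
    conserved_flags: Sequence[bool],
    disorder_cutoff: float = 0.5,
    min_avg_length: float = 15.0,
) -> tuple[list[IDRSegment], float | None]:
    """IDR segment variability over the conserved-organization orthologs.

    Segments are the residue spans outside the matched ancestral domains,
    keyed by position (N-terminal, between ancestral domains i and i+1,
    C-terminal).  A segment qualifies when its across-ortholog average
    disorder exceeds ``disorder_cutoff`` and its average length is at least
    ``min_avg_length``.  Per qualifying segment: mean and sample std of the
    disordered-residue count, and their ratio; ``mean_ratio`` averages the
    ratios (None when no segment qualifies).
    """
    conserved = [p for p, ok in zip(members, conserved_flags) if ok]
    if len(conserved) < 2:
        return [], None
    n_seg = len(ancestral) + 1
    keys = (
        ["N-term"]
        + [f"between_{i}_{i + 1}" for i in range(1, len(ancestral))]
        + ["C-term"]
        if ancestral
        else ["full"]
    )
    lengths = np.zeros((len(conserved), n_seg))
    dis_sums = np.zeros((len(conserved), n_seg))
    dis_counts = np.zeros((len(conserved), n_seg))
    for pi, p in enumerate(conserved):
        spans = _match_ancestral_spans(p, ancestral) if ancestral else []
        bounds = [0] + [b for s, e in (spans or []) for b in (s - 1, e)] + [p.length]
        # segments are the even-indexed gaps: [b0,b1), [b2,b3), ...
        for si in range(n_seg):
            a, b = bounds[2 * si], bounds[2 * si + 1]
            a, b = max(a, 0), max(b, a)
            seg = p.disorder[a:b]
            lengths[pi, si] = len(seg)
            dis_sums[pi, si] = seg.sum()
            dis_counts[pi, si] = int((seg > disorder_cutoff).sum())
    segments: list[IDRSegment] = []
    for si in range(n_seg):
        mean_len = lengths[:, si].mean()
        total_len = lengths[:, si].sum()
        mean_dis = dis_sums[:, si].sum() / total_len if total_len > 0 else 0.0
        if mean_dis <= disorder_cutoff or mean_len < min_avg_length:
            continue
        counts = dis_counts[:, si]
        mean_c = counts.mean()
        std_c = counts.std(ddof=1)
        ratio = std_c / mean_c if mean_c > 0 else 0.0
        segments.append(
            IDRSegment(
                key=keys[si],
                mean_length=float(mean_len),
                mean_disorder=float(mean_dis),
                mean_count=float(mean_c),
                std_count=float(std_c),
                ratio=float(ratio),
            )
        )
    mean_ratio = float(np.mean([s.ratio for s in segments])) if segments else None
    return segments, mean_ratio


def analyze_ortholog_group(
    members: Sequence[ProteinArchitecture],
    group_id: str = "",
    presence_fraction: float = 0.30,
) -> OrthologGroup:
    """Full conservation analysis: ancestral composition, conserved fraction,
    IDR segment variability."""
    ancestral = ancestral_composition(members, presence_fraction=presence_fraction)
    frac, flags = conserved_fraction(members, ancestral)
    segments, mean_ratio = idr_segment_conservation(members, ancestral, flags)
    return OrthologGroup(
        group_id=group_id,
        members=list(members),
        ancestral=ancestral,
        conserved_fraction=frac,
        conserved_flags=flags,
        idr_segments=segments,
        mean_ratio=mean_ratio,
    )


# ---------------------------------------------------------------------------
# input tables
# ---------------------------------------------------------------------------


def read_domain_table(path: str | Path) -> dict[str, list[Domain]]:
    """TSV: protein_id, family, start, end (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[Domain]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.protein_id), []).append(
            (str(row.family), int(row.start), int(row.end))
        )
    return out


def read_disorder_table(path: str | Path) -> dict[str, np.ndarray]:
    """TSV: protein_id, position (1-based), score."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for pid, sub in df.groupby("protein_id"):
        sub = sub.sort_values("position")
        if list(sub["position"]) != list(range(1, len(sub) + 1)):
            raise FormatError(f"{pid}: disorder positions are not 1..L")
        out[str(pid)] = sub["score"].to_numpy(dtype=float)
    return out


def load_architectures(
    fasta: str | Path,
    domain_table: str | Path,
    disorder_table: str | Path,
    species: Mapping[str, str] | None = None,
) -> dict[str, ProteinArchitecture]:
    """Assemble ProteinArchitectures from a FASTA plus domain/disorder TSVs."""
    domains = read_domain_table(domain_table)
    disorder = read_disorder_table(disorder_table)
    out = {}
    for rec in SeqIO.parse(str(fasta), "fasta"):
        pid = rec.id
        if pid not in disorder:
            raise FormatError(f"no disorder scores for {pid}")
        out[pid] = ProteinArchitecture(
            protein_id=pid,
            species=(species or {}).get(pid, ""),
            sequence=str(rec.seq),
            domains=domains.get(pid, []),
            disorder=disorder[pid],
        )
    return out


def read_ortholog_groups(path: str | Path) -> dict[str, list[str]]:
    """TSV: group_id, protein_id, species."""
    df = pd.read_csv(path, sep="\t")
    return {
        str(gid): [str(p) for p in sub["protein_id"]]
        for gid, sub in df.groupby("group_id")
    }


def synthetic_disorder_score(sequence: str, window: int = 21) -> np.ndarray:
    """Sliding-window hydrophilicity score in [0, 1] — a synthetic stand-in.

    This is NOT a disorder predictor; it exists only so fixtures can carry a
    plausible-looking per-residue profile when real predictor output is not
    part of the input.  Charged/polar-rich windows score high, hydrophobic
    windows low.
    """
    hydrophilic = set("DEKRNQSPGH")
    x = np.array([1.0 if aa in hydrophilic else 0.0 for aa in sequence])
    if len(x) == 0:
        return x
    k = min(window, len(x))
    kernel = np.ones(k) / k
    smooth = np.convolve(x, kernel, mode="same")
    return np.clip(smooth, 0.0, 1.0)
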