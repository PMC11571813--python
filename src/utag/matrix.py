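"""The gene x U-stretch-length count matrix, the central object of the pipeline.

Rows are genes, columns are the number of post-poly(A) uridines observed on a
read (0..16; longer stretches are binned at 16).  A matrix is either *raw*
(integer read counts summing to the number of assigned reads) or *RPM
normalized* (scaled so the grand total is one million).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError

MAX_U = 16
#: Column labels of every U-count matrix: number of uridines 0..16.
U_COLUMNS = list(range(MAX_U + 1))
#: Inclusive U-stretch range entering the binding score (true tagging signal).
BS_U_RANGE = (4, 13)
#: Grand total of an RPM-normalized matrix.
RPM_TOTAL = 1_000_000.0


@dataclass
class UCountMatrix:
    """Gene x U-stretch-length counts plus sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by gene_id with integer columns 0..16 (``u0..u16``
        headers are accepted and renamed).
    sample_id, strain
        Free-text identifiers carried through the pipeline.
    enzyme_active
        False for the catalytically dead poly(U)-polymerase control.
    normalized
        True once the matrix has been scaled to a one-million total.
    total_reads
        Raw read total; preserved through normalization so replicate QC can
        still see the original library size.
    """

    counts: pd.DataFrame
    sample_id: str = ""
    strain: str = ""
    enzyme_active: bool = True
    normalized: bool = False
    total_reads: int | None = None

    def __post_init__(self) -> None:
        cols = list(self.counts.columns)
        if cols == [f"u{u}" for u in U_COLUMNS]:
            self.counts = self.counts.set_axis(U_COLUMNS, axis=1)
        elif [int(c) for c in cols] == U_COLUMNS:
            self.counts = self.counts.set_axis(U_COLUMNS, axis=1)
        else:
            raise FormatError(
                f"expected 17 columns u0..u16, got {cols!r}"
            )
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("U-count matrix entries must be non-negative")
        if self.total_reads is None and not self.normalized:
            self.total_reads = int(round(float(self.counts.to_numpy().sum())))

    # -- basic accessors ----------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def n_genes(self) -> int:
        return len(self.counts)

    def total(self) -> float:
        """Grand total of all matrix entries."""
        return float(self.counts.to_numpy().sum())

    def copy(self) -> "UCountMatrix":
        return replace(self, counts=self.counts.copy())

    # -- I/O ----------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write the matrix as TSV (gene_id, u0..u16) plus a JSON metadata sidecar."""
        path = Path(path)
        out = self.counts.copy()
        out.columns = [f"u{u}" for u in U_COLUMNS]
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")
        meta = {
            "sample_id": self.sample_id,
            "strain": self.strain,
            "enzyme_active": self.enzyme_active,
            "normalized": self.normalized,
            "total_reads": self.total_reads,
        }
        Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "UCountMatrix":
        """Read a matrix written by :meth:`to_tsv`; the sidecar is optional."""
        path = Path(path)
        counts = pd.read_csv(path, sep="\t", index_col=0)
        meta_path = Path(str(path) + ".meta.json")
        meta: dict = {}
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
        return cls(
            counts=counts,
            sample_id=meta.get("sample_id", ""),
            strain=meta.get("strain", ""),
            enzyme_active=meta.get("enzyme_active", True),
            normalized=meta.get("normalized", False),
            total_reads=meta.get("total_reads"),
        )


def as_frame(matrix: "UCountMatrix | pd.DataFrame") -> pd.DataFrame:
    """Accept either a UCountMatrix or a bare DataFrame with columns 0..16."""
    if isinstance(matrix, UCountMatrix):
        return matrix.counts
    return UCountMatrix(counts=matrix).counts
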