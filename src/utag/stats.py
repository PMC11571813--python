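"""Binding statistics on a U-count matrix.

Definitions (per gene, on the RPM-normalized matrix):

* expression        exp(gene) = sum_{u=0..16} RPM(u, gene)
* binding score     bs(gene)  = sum_{u=4..13} u * RPM(u, gene)
* modification level m(gene)  = bs(gene) / exp(gene)

Short U stretches (1-3) arise from sequencing errors and scale with
transcript abundance; only stretches of 4-13 uridines carry tagging signal,
hence the weighted sum over that range.  Targets are genes whose modification
level exceeds the background of the catalytically dead enzyme control:
log2(m) > -2.7, i.e. m > 2^-2.7 ~ 0.154 (printed as 0.15).

Binding reliability is a QC statistic: the Pearson correlation structure of
the 4-13 columns across genes.  True tagging makes those columns co-vary
(they mark the same target genes); sequencing error does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError, InsufficientDataError, UndefinedReliabilityError
from .matrix import BS_U_RANGE, U_COLUMNS, UCountMatrix, as_frame

#: Default target-calling threshold on log2 modification level (dead-enzyme background).
DEFAULT_THRESHOLD_LOG2 = -2.7

_RELIABILITY_US = list(range(BS_U_RANGE[0], BS_U_RANGE[1] + 1))  # 4..13


# ---------------------------------------------------------------------------
# correlations / reliability
# ---------------------------------------------------------------------------


def stretch_correlations(
    matrix: "UCountMatrix | pd.DataFrame", log_transform: bool = False
) -> pd.DataFrame:
    """Pairwise Pearson correlation across genes between the 17 U columns.

    Zero-variance columns yield NaN entries.  ``log_transform`` applies
    log2(x+1) first; correlations default to untransformed RPM values.
    """
    df = as_frame(matrix)
    if len(df) < 3:
        raise InsufficientDataError("need at least 3 genes for correlations")
    if log_transform:
        df = np.log2(df + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return df.corr(method="pearson")


def median_reliability(corr: pd.DataFrame) -> tuple[pd.Series, float]:
    """Median binding reliability from a 17x17 stretch-correlation matrix.

    For each U stretch in 4..13 take its best correlation with any *other*
    stretch in 4..13 (missing entries skipped); return the ten per-stretch
    values and their median.  Raises when the whole block is missing, as it
    is for a dead-enzyme control whose 4..16 columns are identically zero.
    """
    block = corr.loc[_RELIABILITY_US, _RELIABILITY_US].copy()
    np.fill_diagonal(block.values, np.nan)
    best = block.max(axis=1, skipna=True)
    if best.isna().all():
        raise UndefinedReliabilityError(
            "no defined correlation among U stretches 4..13"
        )
    return best, float(best.median(skipna=True))


@dataclass
class ReliabilityReport:
    """QC bundle: full correlation matrix, per-stretch best values, median."""

    correlations: pd.DataFrame
    best_per_stretch: pd.Series
    median: float
    expression_correlation: pd.Series


def reliability_report(matrix: "UCountMatrix | pd.DataFrame") -> ReliabilityReport:
    corr = stretch_correlations(matrix)
    best, med = median_reliability(corr)
    return ReliabilityReport(
        correlations=corr,
        best_per_stretch=best,
        median=med,
        expression_correlation=expression_correlation(matrix),
    )


def expression_correlation(matrix: "UCountMatrix | pd.DataFrame") -> pd.Series:
    """Per-U-stretch Pearson correlation with expression across genes.

    Error stretches (1-3) track abundance, so they correlate strongly with
    expression even in the dead-enzyme control; genuine tagging stretches
    need not.
    """
    df = as_frame(matrix)
    if len(df) < 3:
        raise InsufficientDataError("need at least 3 genes")
    exp = df.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return df.corrwith(exp, method="pearson")


# ---------------------------------------------------------------------------
# expression / binding score / modification level
# ---------------------------------------------------------------------------


def expression_vector(matrix: "UCountMatrix | pd.DataFrame") -> pd.Series:
    """exp(gene): row sums over all 17 U columns."""
    return as_frame(matrix).sum(axis=1)


def binding_score(matrix: "UCountMatrix | pd.DataFrame") -> pd.Series:
    """bs(gene): weighted sum u * RPM(u, gene) over u = 4..13 only."""
    df = as_frame(matrix)
    lo, hi = BS_U_RANGE
    weights = pd.Series(
        {u: (u if lo <= u <= hi else 0) for u in U_COLUMNS}, dtype=float
    )
    return df.mul(weights, axis=1).sum(axis=1)


def modification_level(bs: pd.Series, exp: pd.Series) -> pd.Series:
    """m(gene) = bs/exp; genes with zero expression come out NaN (undefined)."""
    if len(bs) != len(exp) or not bs.index.equals(exp.index):
        raise ContractError("bs and exp must be aligned on the same genes")
    m = bs / exp
    return m.where(exp > 0)


def compute_profile(matrix: "UCountMatrix | pd.DataFrame") -> pd.DataFrame:
    """Per-gene profile table: exp, bs, m, log2_m (NaN where undefined)."""
    exp = expression_vector(matrix)
    bs = binding_score(matrix)
    m = modification_level(bs, exp)
    with np.errstate(divide="ignore"):
        log2_m = np.log2(m.where(m > 0))
    return pd.DataFrame({"exp": exp, "bs": bs, "m": m, "log2_m": log2_m})


# ---------------------------------------------------------------------------
# target calling
# ---------------------------------------------------------------------------


@dataclass
class TargetSet:
    """Genes whose modification level exceeds the dead-enzyme background."""

    sample_id: str
    threshold_log2: float
    members: list[str]
    m: pd.Series = field(repr=False)

    @property
    def threshold_linear(self) -> float:
        return float(2.0 ** self.threshold_log2)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in set(self.members)

    def __len__(self) -> int:
        return len(self.members)


def call_targets(
    m: pd.Series,
    threshold_log2: float = DEFAULT_THRESHOLD_LOG2,
    sample_id: str = "",
) -> TargetSet:
    """Targets: genes with log2(m) strictly above ``threshold_log2``.

    Genes with m = 0 or undefined (NaN) are never targets.  The comparison is
    strict in log2 space; the linear threshold 2^-2.7 is its exact equivalent.
    """
    if m.notna().sum() < 1:
        raise InsufficientDataError("modification level defined for no gene")
    defined = m.dropna()
    positive = defined[defined > 0]
    hits = positive[np.log2(positive) > threshold_log2]
    members = sorted(hits.index)
    return TargetSet(
        sample_id=sample_id,
        threshold_log2=threshold_log2,
        members=members,
        m=hits.loc[members],
    )
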