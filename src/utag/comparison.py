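"""Mutant-vs-wild-type comparison of binding profiles.

A deletion strain is compared to the wild type through (i) the Pearson
correlation of log2 modification levels across genes where the level is
defined in both samples, and (ii) the set algebra of their target sets:
*old* targets (kept from WT), *new* targets (gained by the mutant) and
*lost* targets (WT-only).  Overlaps between target sets are scored with the
same hypergeometric upper tail used for GO enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .enrichment import hyper_pvalue
from .errors import ContractError, InsufficientDataError


def profile_correlation(
    m_mut: pd.Series, m_wt: pd.Series, pseudocount: float | None = None
) -> tuple[float, int]:
    """Pearson correlation of log2 modification levels, and the gene count used.

    Without a pseudocount, only genes with m > 0 in both samples enter (log2
    of zero is undefined); with one, all genes where m is defined enter on
    log2(m + pseudocount).
    """
    shared = m_mut.index.intersection(m_wt.index)
    a, b = m_mut.loc[shared], m_wt.loc[shared]
    if pseudocount is None:
        ok = (a > 0) & (b > 0)
        x, y = np.log2(a[ok]), np.log2(b[ok])
    else:
        ok = a.notna() & b.notna()
        x, y = np.log2(a[ok] + pseudocount), np.log2(b[ok] + pseudocount)
    n = int(ok.sum())
    if n < 3:
        raise InsufficientDataError(f"only {n} co-defined genes")
    r = pearsonr(x, y).statistic
    return float(r), n


def classify_old_new(
    targets_mut: Iterable[str], targets_wt: Iterable[str]
) -> tuple[int, int, int]:
    """(n_old, n_new, n_lost) relative to the WT target set.

    old = mutant ∩ WT, new = mutant \\ WT, lost = WT \\ mutant;
    n_old + n_new is the mutant target count, n_old + n_lost the WT count.
    """
    mut, wt = set(targets_mut), set(targets_wt)
    return len(mut & wt), len(mut - wt), len(wt - mut)


def overlap_significance(
    set_a: Iterable[str], set_b: Iterable[str], background: Iterable[str]
) -> float:
    """Hypergeometric p-value for the overlap of two gene sets."""
    a, b, bg = set(set_a), set(set_b), set(background)
    if not (a <= bg and b <= bg):
        raise ContractError("both sets must be subsets of the background")
    return hyper_pvalue(len(a & b), len(a), len(b), len(bg))


@dataclass
class ComparisonReport:
    """One mutant-vs-WT comparison."""

    pair_id: str
    correlation: float
    n_genes: int
    n_old: int
    n_new: int
    n_lost: int
    overlap_p: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def compare_profiles(
    profile_mut: pd.DataFrame,
    profile_wt: pd.DataFrame,
    targets_mut: Iterable[str],
    targets_wt: Iterable[str],
    pair_id: str = "",
    pseudocount: float | None = None,
    background: Iterable[str] | None = None,
) -> ComparisonReport:
    """Convenience driver: correlation plus old/new/lost classification.

    ``profile_*`` are tables from :func:`utag.stats.compute_profile` with an
    ``m`` column.  When ``background`` is given, the target-set overlap
    p-value is included.
    """
    r, n = profile_correlation(
        profile_mut["m"], profile_wt["m"], pseudocount=pseudocount
    )
    n_old, n_new, n_lost = classify_old_new(targets_mut, targets_wt)
    p = None
    if background is not None:
        p = overlap_significance(set(targets_mut), set(targets_wt), background)
    return ComparisonReport(
        pair_id=pair_id,
        correlation=r,
        n_genes=n,
        n_old=n_old,
        n_new=n_new,
        n_lost=n_lost,
        overlap_p=p,
    )
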