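"""Hypergeometric GO-term enrichment of target sets.

The background is the set of expressed genes (exp > 0).  For a term with K
members in the background, n targets in the background and k targets in the
term, the enrichment p-value is the upper tail P(X >= k) of a hypergeometric
draw of n from N with K successes — the ``hygecdf`` construction.  Raw
p-values are reported by default (significance at p < alpha); an optional
Benjamini-Hochberg column is available behind a flag.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import false_discovery_control, hypergeom

from .errors import ContractError


def hyper_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k).

    X counts term members among n draws without replacement from a
    background of N genes containing K term members.
    """
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ContractError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    targets: Iterable[str],
    background: Iterable[str],
    collection: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Test every gene set for over-representation among the targets.

    Returns a frame (term, k, K, n, N, p, significant[, q]) sorted by
    (p, term).  Terms with no member in the background are dropped; targets
    outside the background are dropped with a warning.
    """
    bg = set(background)
    if not bg:
        raise ContractError("empty background")
    tg = set(targets)
    outside = tg - bg
    if outside:
        warnings.warn(
            f"{len(outside)} target gene(s) outside the background were dropped"
        )
        tg &= bg
    N, n = len(bg), len(tg)
    rows = []
    for term, members in collection.items():
        in_bg = set(members) & bg
        K = len(in_bg)
        if K == 0:
            continue
        k = len(in_bg & tg)
        rows.append(
            {"term": term, "k": k, "K": K, "n": n, "N": N,
             "p": hyper_pvalue(k, K, n, N)}
        )
    out = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    if not out.empty:
        out = out.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
        out["significant"] = out["p"] < alpha
        if fdr:
            out["q"] = false_discovery_control(out["p"], method="bh")
    else:
        out["significant"] = pd.Series(dtype=bool)
    return out


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene-set file: term <tab> description <tab> gene1 <tab> gene2 ..."""
    collection: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            continue
        collection[fields[0]] = set(g for g in fields[2:] if g)
    return collection


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines and '#' comments skipped."""
    return [
        ln.strip()
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
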