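"""Gene-set enrichment of the called targets.

Builds a synthetic gene-set collection over the expressed background — one
set equal to the true target genes plus random decoy sets — and runs the
hypergeometric enrichment. The true-target set should dominate the ranking;
decoys should sit near p = 1.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import utag.enrichment as enr

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    profile = pd.read_csv(OUT / "binding_profile_active.tsv", sep="\t", index_col=0)
    truth = pd.read_csv(OUT / "truth.tsv", sep="\t")
    targets = [
        ln.strip()
        for ln in (OUT / "targets_active.txt").read_text().splitlines()
        if ln.strip()
    ]

    background = list(profile.index[profile["exp"] > 0])
    true_ids = set(truth.loc[truth["is_target"] == 1, "gene_id"])

    rng = np.random.default_rng(SEED)
    collection = {"true_target_set": true_ids}
    for i in range(8):
        collection[f"decoy_set_{i}"] = set(
            rng.choice(background, size=150, replace=False)
        )
    # write the collection as GMT and go through the file interface
    gmt = OUT / "gene_sets.gmt"
    with open(gmt, "w") as fh:
        for term, members in collection.items():
            fh.write(term + "\tsynthetic\t" + "\t".join(sorted(members)) + "\n")

    res = enr.enrich(targets, background, enr.read_gmt(gmt), alpha=0.05)
    res.to_csv(OUT / "enrichment.tsv", sep="\t", index=False)

    top = res.iloc[0]
    print(f"background (expressed genes): {len(background)}; targets: {len(targets)}")
    print(
        f"top term: {top['term']} with k={top['k']}/K={top['K']}, p={top['p']:.3g}"
    )
    print(
        f"significant terms at p<0.05: "
        f"{', '.join(res.loc[res['significant'], 'term']) or 'none'}"
    )


if __name__ == "__main__":
    main()
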