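"""Cluster comparisons from the published per-cluster counts.

The four 2x2 cluster comparisons whose inputs are fully determined by the
published prevalences (n = 25 per cluster) are recomputed with the
two-sided Fisher exact test: DDR-pathway mutation (6 vs 15), any (likely)
pathogenic mutation (20 vs 22), any amplification (4 vs 21) and MYC
amplification (4 vs 17).  Writes results/printed_contingency_stats.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from angiomics.stats import ContingencyTable, fisher_exact_two_sided

COMPARISONS = [
    ("ddr_mutation", 6, 15),
    ("pathogenic_mutation", 20, 22),
    ("any_amplification", 4, 21),
    ("myc_amplification", 4, 17),
]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="results/printed_contingency_stats.tsv")
    args = ap.parse_args()

    rows = []
    for feature, k_prim, k_sec in COMPARISONS:
        p = fisher_exact_two_sided(
            ContingencyTable(k_prim, 25 - k_prim, k_sec, 25 - k_sec)
        )
        rows.append({
            "feature": feature,
            "primary": f"{k_prim}/25 ({4 * k_prim}%)",
            "secondary": f"{k_sec}/25 ({4 * k_sec}%)",
            "fisher_p": float(f"{p:.3g}"),
        })
    df = pd.DataFrame(rows)
    Path(args.out).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, sep="\t", index=False)
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
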