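"""Run the genomic analysis stages over the synthetic study.

Filter cascade -> total TMB -> amplification calls -> allelic state ->
signature refitting -> cohort statistics -> integration table, writing every
stage's table under results/analysis/.  Narrates the headline findings:
per-rule filter removals, TMB-high tumors, and amplification burden by
cluster.
"""

import argparse

import pandas as pd

from angiomics import pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--input", default="results/synthetic")
    ap.add_argument("--out", default="results/analysis")
    args = ap.parse_args()

    cfg = pipeline.RunConfig(out_dir=args.out)
    paths = pipeline.cmd_analyze(cfg, args.input)

    removals = pd.read_csv(paths["removal_counts"], sep="\t")
    print("filter cascade removals:")
    print(removals.to_string(index=False))

    tmb = pd.read_csv(paths["tmb"], sep="\t")
    high = tmb[tmb.tmb_high]
    print(f"\nTMB-high (>= 10 mut/Mb): {len(high)}/{len(tmb)} tumors")
    if len(high):
        print(high[["sample_id", "tmb"]].to_string(index=False))

    amps = pd.read_csv(paths["amplification_calls"], sep="\t")
    called = amps[amps.amplified]
    print(f"\namplification calls (relative coverage >= 3): {len(called)}")
    print(called.groupby("gene").size().to_string())


if __name__ == "__main__":
    main()
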