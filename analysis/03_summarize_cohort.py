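"""Render the cohort report: immune-density tables (cluster and subgroup),
TMB summaries, genomic feature prevalences with Fisher p-values, and the
filter bookkeeping, from the tables written by 02_analyze_genomic_arm.py."""

import argparse

from angiomics import pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", default="results/analysis")
    args = ap.parse_args()
    print(pipeline.cmd_report(args.results), end="")


if __name__ == "__main__":
    main()
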