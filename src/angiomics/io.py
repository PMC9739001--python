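"""Readers and writers shared across the pipeline.

On-disk formats: VCF 4.2 for small variants (INFO keys GENE, CSQ, POP_AF,
CLASS; FORMAT DP, AD), BED4 for the panel, TSV for coverage / densities /
metadata, FASTA for the synthetic reference, JSON for ground truth and YAML
for run configuration.  VCF reading goes through cyvcf2 and decomposes
multi-allelic records into one :class:`VariantRecord` per alt allele.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from .copy_number import CoverageMatrix
from .filters import VariantRecord
from .panel import SampleMeta

_INFO_KEYS = {"gene": "GENE", "consequence": "CSQ", "pop_af": "POP_AF",
              "pathogenicity_class": "CLASS"}


# ----------------------------------------------------------------------
# VCF

def write_vcf(
    variants: list[VariantRecord],
    path: str | Path,
    contig_lengths: dict[str, int],
    sample_ids: list[str] | None = None,
    info_keys: dict[str, str] = _INFO_KEYS,
) -> None:
    """Write a multi-sample VCF 4.2; each record carries DP/AD for its
    carrier sample and missing values for the rest."""
    if sample_ids is None:
        sample_ids = sorted({v.sample_id for v in variants})
    col = {s: i for i, s in enumerate(sample_ids)}
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=%s,Number=1,Type=String,Description="Gene symbol">' % info_keys["gene"],
        '##INFO=<ID=%s,Number=1,Type=String,Description="Consequence">' % info_keys["consequence"],
        '##INFO=<ID=%s,Number=1,Type=Float,Description="Population allele frequency">' % info_keys["pop_af"],
        '##INFO=<ID=%s,Number=1,Type=String,Description="Pathogenicity class 1-5 or unknown">' % info_keys["pathogenicity_class"],
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">',
    ]
    for contig, length in contig_lengths.items():
        lines.append(f"##contig=<ID={contig},length={length}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids)
    )
    for v in sorted(variants, key=lambda v: (v.contig, v.pos_1based, v.sample_id, v.alt)):
        info = (
            f"{info_keys['gene']}={v.gene or '.'};"
            f"{info_keys['consequence']}={v.consequence};"
            f"{info_keys['pop_af']}={v.pop_af:.6g};"
            f"{info_keys['pathogenicity_class']}={v.pathogenicity_class}"
        )
        cells = ["."] * len(sample_ids)
        cells[col[v.sample_id]] = f"{v.depth}:{v.depth - v.alt_depth},{v.alt_depth}"
        lines.append(
            f"{v.contig}\t{v.pos_1based}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\tDP:AD\t"
            + "\t".join(cells)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path, info_keys: dict[str, str] = _INFO_KEYS) -> list[VariantRecord]:
    """Read a VCF into VariantRecords (one per alt allele per carrier sample)."""
    vcf = VCF(str(path))
    samples = vcf.samples
    out: list[VariantRecord] = []
    for rec in vcf:
        gene = rec.INFO.get(info_keys["gene"]) or ""
        csq = rec.INFO.get(info_keys["consequence"]) or "other"
        pop_af = rec.INFO.get(info_keys["pop_af"])
        # htslib stores INFO floats in single precision; re-parse at writer precision
        pop_af = float(f"{float(pop_af):.6g}") if pop_af is not None else 0.0
        cls_raw = rec.INFO.get(info_keys["pathogenicity_class"])
        try:
            cls: int | str = int(cls_raw)
        except (TypeError, ValueError):
            cls = "unknown"
        try:
            ad = rec.format("AD")
        except KeyError:  # pragma: no cover - AD always written by this package
            ad = None
        dp = rec.format("DP")
        for si, sid in enumerate(samples):
            if ad is None or np.any(ad[si] < 0):
                continue
            depth = int(dp[si][0]) if dp is not None and dp[si][0] >= 0 else int(ad[si].sum())
            for ai, alt in enumerate(rec.ALT):
                alt_depth = int(ad[si][ai + 1])
                if len(rec.ALT) > 1 and alt_depth == 0:
                    continue  # decomposition: skip alts absent from this carrier
                out.append(
                    VariantRecord(
                        contig=rec.CHROM,
                        pos_1based=rec.POS,
                        ref=rec.REF,
                        alt=alt,
                        gene=(gene or "").upper(),
                        consequence=csq,
                        pop_af=pop_af,
                        depth=depth,
                        alt_depth=alt_depth,
                        sample_id=sid,
                        pathogenicity_class=cls,
                    )
                )
    return out


# ----------------------------------------------------------------------
# TSV tables

def write_metadata_tsv(meta: list[SampleMeta], arms: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in meta],
            "arm": [arms[m.sample_id] for m in meta],
            "cluster": [m.cluster for m in meta],
            "subgroup": [m.subgroup for m in meta],
            "purity": [m.purity for m in meta],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_metadata_tsv(path: str | Path) -> tuple[list[SampleMeta], dict[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    meta = [
        SampleMeta(sample_id=r.sample_id, subgroup=r.subgroup, purity=float(r.purity))
        for r in df.itertuples()
    ]
    return meta, dict(zip(df["sample_id"], df["arm"]))


def write_coverage_tsv(matrix: CoverageMatrix, path: str | Path) -> None:
    matrix.coverage.to_csv(path, sep="\t", index_label="sample_id",
                           float_format="%.3f")


def read_coverage_tsv(path: str | Path, weights: pd.Series | None = None) -> CoverageMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return CoverageMatrix(coverage=df, weights=weights)


def write_density_tsv(densities: pd.DataFrame, path: str | Path) -> None:
    densities.to_csv(path, sep="\t", index_label="sample_id", float_format="%.2f")


def read_density_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


# ----------------------------------------------------------------------
# FASTA / JSON / YAML

def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def write_yaml(obj, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def read_yaml(path: str | Path):
    return yaml.safe_load(Path(path).read_text())
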