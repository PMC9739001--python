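"""Mono- vs biallelic classification of pathogenic tumor-suppressor variants.

Therapeutically relevant inactivation of a tumor-suppressor gene (TSG)
requires both copies to be hit.  With tumor purity p and a diploid
background, a heterozygous somatic variant is expected at VAF p/2, while a
variant rendered hemizygous by loss of the wild-type allele (LOH) is
expected at VAF p/(2-p).  Germline heterozygous SNPs near the gene shift
away from 0.5 under LOH by p/(2*(2-p)).

The decision rule is a three-tier evidence hierarchy:

1. *second_hit* — two or more distinct class-4/5 variants in the gene;
2. *loh_vaf* — a binomial test rejects the heterozygous model upward while
   the LOH model is not rejected;
3. *loh_snp* — the median absolute shift of >= 3 nearby heterozygous SNP
   allele fractions from 0.5 exceeds half the expected LOH shift.

Otherwise the call is monoallelic.  Calls are indeterminate at depth < 50,
unknown purity, or when the gene itself is amplified (the diploid VAF model
no longer applies).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest

from .filters import VariantRecord

MIN_DEPTH = 50
MIN_NEARBY_SNPS = 3
DEFAULT_SNP_WINDOW_BP = 1_000_000  # "nearby" = within 1 Mb of the gene


@dataclass(frozen=True)
class AllelicCall:
    sample_id: str
    gene: str
    state: str      # monoallelic | biallelic | indeterminate
    mechanism: str  # second_hit | loh_vaf | loh_snp | none
    observed_vaf: float
    expected_het_vaf: float
    expected_loh_vaf: float
    snp_deviation: float  # median |snp_af - 0.5|; NaN if too few SNPs


def expected_het_vaf(purity: float) -> float:
    return purity / 2.0


def expected_loh_vaf(purity: float) -> float:
    return purity / (2.0 - purity)


def expected_snp_shift(purity: float) -> float:
    """Expected |AF - 0.5| of a germline het SNP under LOH."""
    return purity / (2.0 * (2.0 - purity))


def assess_allelic_state(
    variants: list[VariantRecord],
    purity: float | None,
    nearby_snp_afs: list[float] | None = None,
    alpha: float = 0.05,
    gene_amplified: bool = False,
) -> AllelicCall:
    """Classify the allelic state of class-4/5 variants within one gene.

    ``variants`` must be non-empty and all from one gene and one sample.
    ``nearby_snp_afs`` are allele fractions of heterozygous SNPs within the
    configured window around the gene (may be empty/None).
    """
    if not variants:
        raise ValueError("assess_allelic_state requires at least one variant")
    genes = {v.gene for v in variants}
    samples = {v.sample_id for v in variants}
    if len(genes) > 1 or len(samples) > 1:
        raise ValueError("variants must come from one gene in one sample")
    gene, sample_id = genes.pop(), samples.pop()

    top = max(variants, key=lambda v: v.vaf)
    snp_afs = np.asarray(nearby_snp_afs if nearby_snp_afs else [], dtype=float)
    snp_dev = (
        float(np.median(np.abs(snp_afs - 0.5)))
        if len(snp_afs) >= MIN_NEARBY_SNPS
        else float("nan")
    )

    def call(state: str, mechanism: str) -> AllelicCall:
        return AllelicCall(
            sample_id=sample_id,
            gene=gene,
            state=state,
            mechanism=mechanism,
            observed_vaf=top.vaf,
            expected_het_vaf=expected_het_vaf(purity) if purity else float("nan"),
            expected_loh_vaf=expected_loh_vaf(purity) if purity else float("nan"),
            snp_deviation=snp_dev,
        )

    # distinct loci count as independent hits
    distinct = {(v.contig, v.pos_1based, v.ref, v.alt) for v in variants}
    if len(distinct) >= 2:
        return call("biallelic", "second_hit")

    if purity is None or top.depth < MIN_DEPTH:
        return call("indeterminate", "none")
    if gene_amplified:
        # copy number at the locus is not 2; VAF expectations do not apply
        return call("indeterminate", "none")

    p_het_up = binomtest(
        top.alt_depth, top.depth, expected_het_vaf(purity), alternative="greater"
    ).pvalue
    p_loh = binomtest(
        top.alt_depth, top.depth, expected_loh_vaf(purity), alternative="two-sided"
    ).pvalue
    if p_het_up < alpha and p_loh >= alpha:
        return call("biallelic", "loh_vaf")

    if not np.isnan(snp_dev) and snp_dev > expected_snp_shift(purity) / 2.0:
        return call("biallelic", "loh_snp")

    return call("monoallelic", "none")


def nearby_het_snp_afs(
    raw_variants: list[VariantRecord],
    contig: str,
    gene_start_1based: int,
    gene_end_1based: int,
    window_bp: int = DEFAULT_SNP_WINDOW_BP,
    pop_af_min: float = 0.001,
) -> list[float]:
    """Allele fractions of common (germline het candidate) SNPs near a gene.

    Common variants (population AF above the somatic-filter threshold) with
    intermediate allele fractions are taken as heterozygous germline SNPs;
    they are exactly the records the somatic filter removes, re-used here as
    LOH probes.
    """
    lo = gene_start_1based - window_bp
    hi = gene_end_1based + window_bp
    return [
        v.vaf
        for v in raw_variants
        if v.contig == contig
        and lo <= v.pos_1based <= hi
        and v.pop_af > pop_af_min
        and v.depth > 0
        and 0.05 < v.vaf < 0.95
    ]
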