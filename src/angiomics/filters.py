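"""Four-rule somatic variant filter cascade for tumor-only panel data.

Variants are excluded when they (R1) fall outside exons and splice-site
regions, unless in the TERT promoter; (R2) are synonymous, unless located in
a splice-site region; (R3) are common in the reference population
(population allele frequency strictly above 0.1%); or (R4) have a variant
allele fraction strictly below 5%.

All four rules are evaluated exhaustively for every variant (no
short-circuiting), so per-rule removal counts are complete.  The reportable
set keeps variants failing no rule; the TMB-eligible set re-admits variants
failing only the synonymous rule, because total TMB counts synonymous and
non-synonymous mutations alike.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .panel import PanelDefinition, TerritoryCategory

POP_AF_MAX = 0.001  # R3: exclude strictly above
VAF_MIN = 0.05      # R4: exclude strictly below

CONSEQUENCES = (
    "missense", "nonsense", "synonymous", "splice",
    "frameshift", "inframe_indel", "promoter", "other",
)

RULES = ("R1_territory", "R2_synonymous", "R3_population", "R4_vaf")


@dataclass(frozen=True)
class VariantRecord:
    """One annotated small variant for one sample.

    ``pathogenicity_class`` follows the 5-tier scheme (1 = not pathogenic …
    5 = pathogenic; class 4/5 = (likely) pathogenic); it is an input
    annotation, never recomputed here.  A missing population AF is treated
    as 0 (absence from a population database is not evidence of commonness).
    """

    contig: str
    pos_1based: int
    ref: str
    alt: str
    gene: str
    consequence: str
    pop_af: float
    depth: int
    alt_depth: int
    sample_id: str
    pathogenicity_class: int | str = "unknown"

    def __post_init__(self) -> None:
        if self.pos_1based < 1:
            raise ValueError("pos_1based must be >= 1")
        if not 0 <= self.alt_depth <= self.depth:
            raise ValueError(
                f"require 0 <= alt_depth <= depth, got {self.alt_depth}/{self.depth}"
            )
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")

    @property
    def vaf(self) -> float:
        """Variant allele fraction, alt reads / total reads."""
        return self.alt_depth / self.depth if self.depth > 0 else float("nan")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 == len(self.alt) and self.ref != self.alt


@dataclass
class FilterOutcome:
    variant: VariantRecord
    failed_rules: frozenset[str]
    malformed: bool = False
    category: TerritoryCategory = TerritoryCategory.OUTSIDE

    @property
    def kept(self) -> bool:
        return not self.failed_rules and not self.malformed


def apply_filters(
    variants: list[VariantRecord],
    panel: PanelDefinition,
    pop_af_max: float = POP_AF_MAX,
    vaf_min: float = VAF_MIN,
) -> list[FilterOutcome]:
    """Evaluate every rule on every variant; order-preserving.

    Zero-depth records are flagged malformed (a distinct state, not an R4
    failure).  Boundary values survive: pop_af == 0.1% and vaf == 5% are
    both kept, mirroring the strict inequalities of the exclusion rules.
    """
    outcomes: list[FilterOutcome] = []
    for v in variants:
        if v.depth == 0:
            outcomes.append(
                FilterOutcome(v, frozenset(), malformed=True,
                              category=panel.in_territory(v.contig, v.pos_1based))
            )
            continue
        cat = panel.in_territory(v.contig, v.pos_1based)
        failed = set()
        if cat is TerritoryCategory.OUTSIDE:
            failed.add("R1_territory")
        if v.consequence == "synonymous" and cat is not TerritoryCategory.SPLICE:
            failed.add("R2_synonymous")
        if v.pop_af > pop_af_max:
            failed.add("R3_population")
        if v.vaf < vaf_min:
            failed.add("R4_vaf")
        outcomes.append(FilterOutcome(v, frozenset(failed), category=cat))
    return outcomes


def reportable_set(outcomes: list[FilterOutcome]) -> list[VariantRecord]:
    """Variants failing no rule (order-preserving subset)."""
    return [o.variant for o in outcomes if o.kept]


def tmb_eligible_set(outcomes: list[FilterOutcome]) -> list[VariantRecord]:
    """Variants failing no rule except possibly the synonymous rule (R2)."""
    return [
        o.variant
        for o in outcomes
        if not o.malformed and not (o.failed_rules - {"R2_synonymous"})
    ]


def removal_counts(outcomes: list[FilterOutcome]) -> pd.DataFrame:
    """Per-rule removal counts (a variant can fail several rules)."""
    rows = [
        {
            "rule": rule,
            "n_removed": sum(rule in o.failed_rules for o in outcomes),
        }
        for rule in RULES
    ]
    rows.append({"rule": "malformed", "n_removed": sum(o.malformed for o in outcomes)})
    rows.append({"rule": "kept", "n_removed": sum(o.kept for o in outcomes)})
    return pd.DataFrame(rows)
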