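"""Targeted-panel model: gene territory, splice flanks, TERT promoter, gene sets.

The panel is the callable territory of a tumor-only targeted assay: the union
of gene exons, a configurable number of flanking intronic (splice-site) bases
on each exon edge, and the TERT promoter hotspot region.  Every downstream
stage (variant filtering, TMB denominator) consults this territory, so the
megabase size reported here must describe exactly the positions that
``in_territory`` does not classify as ``outside``.

Coordinates are BED-style 0-based half-open on disk and 1-based (VCF
convention) for all in-memory queries; conversion happens only at the reader
boundary.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

logger = logging.getLogger(__name__)

#: Genes of the DNA-damage-response (DDR) pathway whose mutation defines the
#: DDR-positive feature in cohort comparisons.
DDR_GENES: frozenset[str] = frozenset(
    {
        "ATM", "ATRX", "BRIP1", "CHEK2", "ERCC2", "ERCC3", "ERCC4",
        "ERCC5", "FANCF", "FANCI", "MSH2", "MSH3", "TP53", "XRCC2",
    }
)

#: Genes recurrently amplified in secondary angiosarcoma.
AMPLIFICATION_GENES: frozenset[str] = frozenset({"MYC", "FLT4", "CRKL"})

#: Tumor-suppressor genes for which biallelic inactivation is assessed.
TSG_GENES: frozenset[str] = DDR_GENES | {"RASA1", "SETD2", "POT1"}

#: Clinical subgroup -> cluster. The first five arise de novo (primary AS);
#: the last three follow radiotherapy, UV exposure or chronic lymphedema
#: (secondary AS).
SUBGROUP_CLUSTER: dict[str, str] = {
    "soft_tissue": "primary",
    "breast": "primary",
    "skin_not_uv": "primary",
    "visceral": "primary",
    "heart": "primary",
    "rt": "secondary",
    "uv": "secondary",
    "stewart_treves": "secondary",
}

SUBGROUPS: tuple[str, ...] = tuple(SUBGROUP_CLUSTER)

MIN_PURITY = 0.30


class TerritoryCategory(str, Enum):
    EXONIC = "exonic"
    SPLICE = "splice"
    TERT_PROMOTER = "tert_promoter"
    OUTSIDE = "outside"


Interval = tuple[str, int, int]  # contig, start (0-based), end (half-open)


class PanelError(ValueError):
    """Malformed panel definition or BED input."""


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent [start, end) intervals."""
    if not intervals:
        return []
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


@dataclass
class GeneSets:
    """Fixed gene lists consulted by the cohort statistics.

    Gene names are case-normalized to upper case.
    """

    ddr_genes: frozenset[str] = DDR_GENES
    amplification_genes: frozenset[str] = AMPLIFICATION_GENES
    tsg_genes: frozenset[str] = TSG_GENES

    def __post_init__(self) -> None:
        self.ddr_genes = frozenset(g.upper() for g in self.ddr_genes)
        self.amplification_genes = frozenset(g.upper() for g in self.amplification_genes)
        self.tsg_genes = frozenset(g.upper() for g in self.tsg_genes)


@dataclass(frozen=True)
class SampleMeta:
    """One tumor sample: cluster membership, clinical subgroup, purity.

    ``purity`` is the estimated fraction of tumor cells in the specimen,
    in (0, 1]; it scales both expected VAF and coverage ratios.  Samples
    entering genomic analysis require purity >= 0.30.
    """

    sample_id: str
    subgroup: str
    purity: float = 1.0

    def __post_init__(self) -> None:
        if self.subgroup not in SUBGROUP_CLUSTER:
            raise ValueError(f"unknown subgroup {self.subgroup!r}")
        if not 0.0 < self.purity <= 1.0:
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")

    @property
    def cluster(self) -> str:
        return SUBGROUP_CLUSTER[self.subgroup]


@dataclass
class PanelDefinition:
    """Merged per-gene exon intervals plus splice flanks and TERT promoter.

    ``effective_size_mb`` is the merged territory (exons expanded by
    ``splice_flank_bp`` on each side, union'ed with the TERT promoter)
    in megabases — the TMB denominator.
    """

    genes: dict[str, list[Interval]]
    splice_flank_bp: int = 2
    tert_promoter: Interval | None = None
    effective_size_mb: float = field(init=False)

    # per-contig sorted interval arrays for queries
    _exons: dict[str, list[tuple[int, int]]] = field(init=False, repr=False)
    _territory: dict[str, list[tuple[int, int]]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.splice_flank_bp < 0:
            raise PanelError("splice_flank_bp must be >= 0")
        merged: dict[str, list[Interval]] = {}
        by_contig_exon: dict[str, list[tuple[int, int]]] = {}
        by_contig_terr: dict[str, list[tuple[int, int]]] = {}
        for gene, ivs in self.genes.items():
            per_contig: dict[str, list[tuple[int, int]]] = {}
            for contig, s, e in ivs:
                if s < 0 or e <= s:
                    raise PanelError(f"invalid interval for {gene}: [{s}, {e})")
                per_contig.setdefault(contig, []).append((s, e))
            merged[gene.upper()] = [
                (c, s, e) for c, lst in per_contig.items() for s, e in _merge(lst)
            ]
            for c, lst in per_contig.items():
                m = _merge(lst)
                by_contig_exon.setdefault(c, []).extend(m)
                f = self.splice_flank_bp
                by_contig_terr.setdefault(c, []).extend(
                    (max(0, s - f), e + f) for s, e in m
                )
        if self.tert_promoter is not None:
            c, s, e = self.tert_promoter
            if s < 0 or e <= s:
                raise PanelError(f"invalid TERT promoter interval [{s}, {e})")
            by_contig_terr.setdefault(c, []).append((s, e))
        self.genes = merged
        self._exons = {c: _merge(lst) for c, lst in by_contig_exon.items()}
        self._territory = {c: _merge(lst) for c, lst in by_contig_terr.items()}
        total = sum(e - s for lst in self._territory.values() for s, e in lst)
        self.effective_size_mb = total / 1e6
        if self.effective_size_mb <= 0:
            raise PanelError("panel has zero callable territory")

    # ------------------------------------------------------------------
    @staticmethod
    def _contains(intervals: list[tuple[int, int]], pos0: int) -> bool:
        i = bisect_right(intervals, (pos0, float("inf"))) - 1
        return i >= 0 and intervals[i][0] <= pos0 < intervals[i][1]

    def in_territory(self, contig: str, pos_1based: int) -> TerritoryCategory:
        """Classify a 1-based position as exonic / splice / tert_promoter / outside.

        Splice means within ``splice_flank_bp`` bases outside an exon
        boundary.  Unknown contigs map to ``outside`` (logged, not an error).
        """
        if pos_1based < 1:
            raise ValueError("pos_1based must be >= 1")
        pos0 = pos_1based - 1
        exons = self._exons.get(contig)
        if exons is None and (
            self.tert_promoter is None or contig != self.tert_promoter[0]
        ):
            logger.debug("unknown contig %s: treating position as outside", contig)
            return TerritoryCategory.OUTSIDE
        if exons and self._contains(exons, pos0):
            return TerritoryCategory.EXONIC
        if exons and self.splice_flank_bp > 0:
            f = self.splice_flank_bp
            flanks = [(max(0, s - f), s) for s, e in exons] + [
                (e, e + f) for s, e in exons
            ]
            if any(s <= pos0 < e for s, e in flanks):
                return TerritoryCategory.SPLICE
        if self.tert_promoter is not None:
            c, s, e = self.tert_promoter
            if contig == c and s <= pos0 < e:
                return TerritoryCategory.TERT_PROMOTER
        return TerritoryCategory.OUTSIDE

    def gene_at(self, contig: str, pos_1based: int) -> str | None:
        """Gene whose (flank-expanded) territory covers the position, if any."""
        pos0 = pos_1based - 1
        f = self.splice_flank_bp
        for gene, ivs in self.genes.items():
            for c, s, e in ivs:
                if c == contig and s - f <= pos0 < e + f:
                    return gene
        return None

    def territory_intervals(self) -> dict[str, list[tuple[int, int]]]:
        """Per-contig merged 0-based half-open intervals of callable territory."""
        return {c: list(lst) for c, lst in self._territory.items()}

    def dump_bed(self, path: str | Path) -> None:
        """Write merged exons as BED4 (one line per gene interval)."""
        with open(path, "w") as fh:
            for gene in sorted(self.genes):
                for contig, s, e in sorted(self.genes[gene]):
                    fh.write(f"{contig}\t{s}\t{e}\t{gene}\n")


def load_panel(
    bed_path: str | Path,
    splice_flank_bp: int = 2,
    tert_interval: Interval | None = None,
) -> PanelDefinition:
    """Load a BED4 panel file (0-based half-open; 4th column = gene name).

    Raises :class:`PanelError` naming the offending line number on malformed
    input, and on an empty file.
    """
    genes: dict[str, list[Interval]] = {}
    with open(bed_path) as fh:
        n = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise PanelError(
                    f"{bed_path}: line {lineno}: expected >=4 tab-separated "
                    f"columns, got {len(fields)}"
                )
            contig, s_str, e_str, gene = fields[:4]
            try:
                s, e = int(s_str), int(e_str)
            except ValueError as exc:
                raise PanelError(
                    f"{bed_path}: line {lineno}: non-integer coordinates"
                ) from exc
            if s < 0 or e <= s:
                raise PanelError(
                    f"{bed_path}: line {lineno}: invalid interval [{s}, {e})"
                )
            genes.setdefault(gene.upper(), []).append((contig, s, e))
            n += 1
    if n == 0:
        raise PanelError(f"{bed_path}: no BED records")
    return PanelDefinition(
        genes=genes, splice_flank_bp=splice_flank_bp, tert_promoter=tert_interval
    )
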