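"""Pipeline orchestration: simulate, analyze, report.

``cmd_simulate`` writes a complete synthetic study to disk; ``cmd_analyze``
runs the analysis stages in order (filter -> TMB -> copy number -> allelic
state -> signatures -> statistics -> integration), each stage's output
written before the next consumes it; ``cmd_report`` renders the result
tables into a plain-text summary.  All three are deterministic for fixed
inputs and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from pyfaidx import Fasta

from . import allelic, copy_number, filters, io, signatures, simulate, stats, tmb
from .panel import MIN_PURITY, GeneSets, PanelDefinition, SampleMeta, load_panel

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and thresholds of one pipeline run (YAML-serializable)."""

    seed: int = 0
    out_dir: str = "results"
    panel_bed: str = "panel.bed"
    reference_fasta: str = "reference.fa"
    vcf: str = "variants.vcf"
    coverage_tsv: str = "coverage.tsv"
    density_tsv: str = "densities.tsv"
    metadata_tsv: str = "metadata.tsv"
    signature_tsv: str | None = None  # None -> bundled synthetic set
    pop_af_max: float = 0.001
    vaf_min: float = 0.05
    tmb_high_cutoff: float = 10.0
    amp_ratio_threshold: float = 3.0
    min_purity: float = MIN_PURITY
    splice_flank_bp: int = 2
    min_snvs_for_fit: int = 20
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


SIMULATED_FILES = (
    "variants.vcf", "coverage.tsv", "densities.tsv", "metadata.tsv",
    "ground_truth.json", "reference.fa",
)


def cmd_simulate(
    out_dir: str | Path,
    sim_config: simulate.SimulationConfig | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Generate and write a full synthetic study.

    Emits the panel BED plus: VCF, coverage TSV, density TSV, metadata TSV,
    ground-truth JSON and the synthetic reference FASTA.
    """
    cfg = sim_config or simulate.SimulationConfig()
    if seed is not None:
        cfg.seed = seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("simulating synthetic study with seed %d", cfg.seed)

    panel = simulate.build_default_panel()
    genomic_meta, truth = simulate.generate_cohort(cfg, arm="genomic")
    immune_meta, _ = simulate.generate_cohort(cfg, arm="immune")

    reference = simulate.generate_reference(panel, cfg.seed)
    contexts = simulate.ReferenceContexts(reference, panel)
    variants = simulate.generate_variants(genomic_meta, panel, cfg, contexts, truth)
    simulate.generate_amplifications(genomic_meta, cfg, truth)
    coverage = simulate.generate_coverage(
        genomic_meta, list(panel.genes), cfg, truth
    )
    densities = simulate.generate_densities(immune_meta + genomic_meta, cfg)

    paths = {
        "panel_bed": out / "panel.bed",
        "vcf": out / "variants.vcf",
        "coverage": out / "coverage.tsv",
        "densities": out / "densities.tsv",
        "metadata": out / "metadata.tsv",
        "truth": out / "ground_truth.json",
        "reference": out / "reference.fa",
    }
    panel.dump_bed(paths["panel_bed"])
    io.write_vcf(
        variants, paths["vcf"],
        contig_lengths=simulate.panel_contig_length(panel),
        sample_ids=[m.sample_id for m in genomic_meta],
    )
    io.write_coverage_tsv(coverage, paths["coverage"])
    io.write_density_tsv(densities, paths["densities"])
    all_meta = immune_meta + genomic_meta
    arms = {m.sample_id: ("genomic" if m in genomic_meta else "immune")
            for m in all_meta}
    io.write_metadata_tsv(all_meta, arms, paths["metadata"])
    io.write_json(truth.to_json(), paths["truth"])
    io.write_fasta(reference, paths["reference"])
    return paths


def cmd_analyze(config: RunConfig, input_dir: str | Path) -> dict[str, Path]:
    """Run every analysis stage over a simulated (or equivalent) study."""
    ind = Path(input_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("panel.bed", config.vcf, config.coverage_tsv,
                 config.density_tsv, config.metadata_tsv):
        if not (ind / name).exists():
            raise FileNotFoundError(f"missing input file: {ind / name}")

    # panel: recover the TERT promoter interval (300 bp upstream of TERT)
    panel_plain = load_panel(ind / "panel.bed", splice_flank_bp=config.splice_flank_bp)
    tert = None
    if "TERT" in panel_plain.genes:
        ivs = sorted(panel_plain.genes["TERT"])
        contig, start, _ = ivs[0]
        tert = (contig, max(0, start - 300), start)
    panel = load_panel(
        ind / "panel.bed", splice_flank_bp=config.splice_flank_bp, tert_interval=tert
    )

    meta_all, arms = io.read_metadata_tsv(ind / config.metadata_tsv)
    genomic_meta = [m for m in meta_all if arms[m.sample_id] == "genomic"]
    excluded = [m for m in genomic_meta if m.purity < config.min_purity]
    for m in excluded:
        logger.info("sample %s excluded: purity %.2f below %.2f",
                    m.sample_id, m.purity, config.min_purity)
    genomic_meta = [m for m in genomic_meta if m.purity >= config.min_purity]
    immune_meta = [m for m in meta_all if arms[m.sample_id] == "immune"]

    raw = io.read_vcf(ind / config.vcf)
    known = {m.sample_id for m in meta_all}
    orphans = sorted({v.sample_id for v in raw} - known)
    if orphans:
        raise ValueError(f"VCF samples absent from metadata: {orphans[:5]}")
    genomic_ids = {m.sample_id for m in genomic_meta}
    raw = [v for v in raw if v.sample_id in genomic_ids]

    # stage 1: filter cascade
    outcomes = filters.apply_filters(
        raw, panel, pop_af_max=config.pop_af_max, vaf_min=config.vaf_min
    )
    kept = filters.reportable_set(outcomes)
    eligible = filters.tmb_eligible_set(outcomes)
    paths: dict[str, Path] = {}
    paths["filtered_vcf"] = out / "filtered.vcf"
    io.write_vcf(
        kept, paths["filtered_vcf"],
        contig_lengths=simulate.panel_contig_length(panel),
        sample_ids=sorted(genomic_ids),
    )
    paths["removal_counts"] = out / "filter_removal_counts.tsv"
    filters.removal_counts(outcomes).to_csv(paths["removal_counts"], sep="\t", index=False)

    # stage 2: TMB
    by_sample_eligible: dict[str, list] = {m.sample_id: [] for m in genomic_meta}
    for v in eligible:
        by_sample_eligible[v.sample_id].append(v)
    tmb_results = [
        tmb.compute_tmb(by_sample_eligible[m.sample_id], panel,
                        sample_id=m.sample_id, cutoff=config.tmb_high_cutoff)
        for m in genomic_meta
    ]
    tmb_df = tmb.tmb_table(tmb_results)
    paths["tmb"] = out / "tmb.tsv"
    tmb_df.to_csv(paths["tmb"], sep="\t", index=False, float_format="%.6g")
    paths["tmb_summary"] = out / "tmb_summary.tsv"
    tmb.summarize_tmb(tmb_results, genomic_meta).to_csv(
        paths["tmb_summary"], sep="\t", index=False, float_format="%.6g"
    )

    # stage 3: copy number
    coverage = io.read_coverage_tsv(ind / config.coverage_tsv)
    amp_calls = []
    for m in genomic_meta:
        if m.sample_id not in coverage.coverage.index:
            logger.warning("no coverage for %s; copy-number stage skipped", m.sample_id)
            continue
        ratios = copy_number.relative_coverage(coverage, m.sample_id)
        amp_calls.extend(
            copy_number.call_amplifications(
                ratios, m.sample_id, m.purity, threshold=config.amp_ratio_threshold
            )
        )
    amp_df = copy_number.calls_table(amp_calls)
    paths["amplification_calls"] = out / "amplification_calls.tsv"
    amp_df.to_csv(paths["amplification_calls"], sep="\t", index=False,
                  float_format="%.6g")

    # stage 4: allelic state of class-4/5 TSG variants
    gene_sets = GeneSets()
    amplified_pairs = {
        (r.sample_id, r.gene) for r in amp_df.itertuples() if r.amplified
    } if len(amp_df) else set()
    by_sample_kept: dict[str, list] = {m.sample_id: [] for m in genomic_meta}
    for v in kept:
        by_sample_kept[v.sample_id].append(v)
    allelic_rows = []
    for m in genomic_meta:
        tsg_hits: dict[str, list] = {}
        for v in by_sample_kept[m.sample_id]:
            if v.pathogenicity_class in (4, 5) and v.gene in gene_sets.tsg_genes:
                tsg_hits.setdefault(v.gene, []).append(v)
        for gene, hits in sorted(tsg_hits.items()):
            ivs = sorted(panel.genes.get(gene, []))
            if ivs:
                contig = ivs[0][0]
                snps = allelic.nearby_het_snp_afs(
                    [v for v in raw if v.sample_id == m.sample_id],
                    contig, ivs[0][1] + 1, ivs[-1][2],
                )
            else:  # pragma: no cover - kept variants always map to panel genes
                snps = []
            call = allelic.assess_allelic_state(
                hits, m.purity, snps,
                gene_amplified=(m.sample_id, gene) in amplified_pairs,
            )
            allelic_rows.append({
                "sample_id": call.sample_id, "gene": call.gene,
                "state": call.state, "mechanism": call.mechanism,
                "observed_vaf": call.observed_vaf,
                "expected_het_vaf": call.expected_het_vaf,
                "expected_loh_vaf": call.expected_loh_vaf,
                "snp_deviation": call.snp_deviation,
            })
    allelic_df = pd.DataFrame(
        allelic_rows,
        columns=["sample_id", "gene", "state", "mechanism", "observed_vaf",
                 "expected_het_vaf", "expected_loh_vaf", "snp_deviation"],
    )
    paths["allelic_calls"] = out / "allelic_calls.tsv"
    allelic_df.to_csv(paths["allelic_calls"], sep="\t", index=False,
                      float_format="%.6g")

    # stage 5: signatures for TMB-high samples
    sig_set = (
        signatures.read_signature_tsv(config.signature_tsv)
        if config.signature_tsv
        else signatures.load_bundled_signatures()
    )
    ref = Fasta(str(ind / config.reference_fasta)) \
        if (ind / config.reference_fasta).exists() else None

    def context_lookup(contig: str, pos: int) -> str | None:
        if ref is None or contig not in ref:
            return None
        s = ref[contig][pos - 2 : pos + 1].seq.upper()
        return s if len(s) == 3 else None

    exposure_rows = []
    for sid in signatures.select_signature_samples(tmb_results):
        snvs = [v for v in by_sample_eligible[sid] if v.is_snv]
        catalog = signatures.build_catalog(snvs, context_lookup, sample_id=sid)
        if catalog.total == 0:
            logger.warning("TMB-high sample %s has empty catalog; skipped", sid)
            continue
        exp = signatures.fit_exposures(catalog, sig_set,
                                       min_snvs=config.min_snvs_for_fit)
        row = {"sample_id": sid, "n_snvs": catalog.total,
               "cosine": exp.cosine, "indeterminate": exp.indeterminate}
        for name in sig_set.names:
            row[f"exposure_{name}"] = exp.exposures.get(name, float("nan"))
        exposure_rows.append(row)
    exposures_df = pd.DataFrame(
        exposure_rows,
        columns=["sample_id", "n_snvs", "cosine", "indeterminate"]
        + [f"exposure_{n}" for n in sig_set.names],
    )
    paths["exposures"] = out / "signature_exposures.tsv"
    exposures_df.to_csv(paths["exposures"], sep="\t", index=False,
                        float_format="%.6g")

    # stage 6: cohort statistics
    densities = io.read_density_tsv(ind / config.density_tsv)
    for level, fname in (("cluster", "density_summary_cluster.tsv"),
                         ("subgroup", "density_summary_subgroup.tsv")):
        comps = stats.summarize_densities(
            densities.loc[[m.sample_id for m in immune_meta
                           if m.sample_id in densities.index]],
            immune_meta, grouping=level,
        )
        paths[f"density_{level}"] = out / fname
        stats.density_summary_table(comps).to_csv(
            paths[f"density_{level}"], sep="\t", index=False, float_format="%.6g"
        )
    features = stats.sample_features(
        genomic_meta, by_sample_kept, amp_df, tmb_df, gene_sets
    )
    paths["prevalence"] = out / "prevalence.tsv"
    stats.feature_prevalence(features, genomic_meta).to_csv(
        paths["prevalence"], sep="\t", index=False, float_format="%.6g"
    )

    # stage 7: integration table
    integration = stats.build_integration_table(
        genomic_meta, tmb_df, amp_df, allelic_df, by_sample_kept, densities
    )
    paths["integration"] = out / "integration.tsv"
    integration.to_csv(paths["integration"], sep="\t", float_format="%.6g")
    return paths


def cmd_report(results_dir: str | Path) -> str:
    """Render analyze outputs into a deterministic plain-text report."""
    res = Path(results_dir)
    needed = ["tmb_summary.tsv", "filter_removal_counts.tsv", "prevalence.tsv",
              "density_summary_cluster.tsv", "density_summary_subgroup.tsv"]
    for name in needed:
        if not (res / name).exists():
            raise FileNotFoundError(f"missing analyze output: {res / name}")
    lines = ["# Cohort analysis report", ""]

    lines.append("## Filter cascade removals")
    rem = pd.read_csv(res / "filter_removal_counts.tsv", sep="\t")
    for r in rem.itertuples():
        lines.append(f"  {r.rule}: {r.n_removed}")
    lines.append("")

    lines.append("## TMB by group (median [min-max], n TMB-high)")
    ts = pd.read_csv(res / "tmb_summary.tsv", sep="\t")
    for r in ts.itertuples():
        lines.append(
            f"  {r.level}/{r.group} (n={r.n}): {r.median_tmb:.1f} "
            f"[{r.min_tmb:.1f}-{r.max_tmb:.1f}] mut/Mb, TMB-high {r.n_tmb_high}"
        )
    lines.append("")

    lines.append("## Immune densities (cells/mm², median (IQR))")
    for level in ("cluster", "subgroup"):
        df = pd.read_csv(res / f"density_summary_{level}.tsv", sep="\t")
        for r in df.itertuples():
            p = f", p={r.p_value:.3g}" if level == "cluster" else ""
            lines.append(
                f"  {r.marker} {r.group} (n={r.n}): {r.median:.0f} ({r.iqr:.0f}){p}"
            )
    lines.append("")

    lines.append("## Genomic feature prevalence (cluster level)")
    prev = pd.read_csv(res / "prevalence.tsv", sep="\t")
    for r in prev[prev["level"] == "cluster"].itertuples():
        lines.append(
            f"  {r.feature} {r.group}: {r.n_present}/{r.n_total} "
            f"({r.percent:.0f}%), Fisher p={r.fisher_p:.3g}"
        )
    report = "\n".join(lines) + "\n"
    (res / "report.txt").write_text(report)
    return report
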