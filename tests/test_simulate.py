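"""Generator contracts: seed determinism, cohort sizes, density calibration,
spectrum-faithful SNVs, VAF model, nuisance injection, coverage model, and
round-trips through the readers."""

import math

import numpy as np
import pandas as pd
import pytest

from angiomics import io
from angiomics.copy_number import relative_coverage
from angiomics.panel import SampleMeta
from angiomics.simulate import (
    GENOMIC_N,
    IMMUNE_N,
    GroundTruth,
    ReferenceContexts,
    SimulationConfig,
    generate_amplifications,
    generate_cohort,
    generate_coverage,
    generate_densities,
    generate_variants,
)


class TestCohort:
    def test_arm_sizes_match_study_design(self):
        cfg = SimulationConfig(seed=0)
        immune, _ = generate_cohort(cfg, arm="immune")
        clusters = [m.cluster for m in immune]
        assert clusters.count("primary") == 79
        assert clusters.count("secondary") == 178
        genomic, _ = generate_cohort(cfg, arm="genomic")
        assert len(genomic) == 50
        assert sum(m.cluster == "primary" for m in genomic) == 25
        assert all(m.purity >= 0.30 for m in genomic)
        assert sum(GENOMIC_N.values()) == 50 and sum(IMMUNE_N.values()) == 257

    def test_seed_determinism(self):
        a, _ = generate_cohort(SimulationConfig(seed=42), arm="genomic")
        b, _ = generate_cohort(SimulationConfig(seed=42), arm="genomic")
        assert a == b
        c, _ = generate_cohort(SimulationConfig(seed=43), arm="genomic")
        assert a != c

    def test_zero_samples_rejected(self):
        cfg = SimulationConfig(genomic_n={s: 0 for s in GENOMIC_N})
        with pytest.raises(ValueError):
            generate_cohort(cfg, arm="genomic")

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(ddr_mutation_probability={"primary": 1.2,
                                                       "secondary": 0.5})
        with pytest.raises(ValueError):
            SimulationConfig(signature_mix={"uv": {"SBS7a": 0.8}})
        with pytest.raises(ValueError):
            SimulationConfig(purity_bounds=(0.1, 0.9))


class TestDensities:
    def test_lognormal_median_calibration(self):
        """At large n the sample median of UV CD3 densities approaches the
        configured 817 cells/mm²."""
        cfg = SimulationConfig(seed=1)
        meta = [SampleMeta(f"m{i:04d}", "uv") for i in range(4000)]
        dens = generate_densities(meta, cfg)
        assert np.median(dens["CD3"]) == pytest.approx(817, rel=0.15)
        # IQR calibration, same tolerance
        q1, q3 = np.percentile(dens["CD3"], [25, 75])
        assert q3 - q1 == pytest.approx(862, rel=0.15)

    def test_zero_iqr_degenerates_to_constant(self):
        cfg = SimulationConfig(seed=1)
        cfg.density_params["uv"]["CD3"] = (500.0, 0.0)
        meta = [SampleMeta(f"m{i}", "uv") for i in range(50)]
        dens = generate_densities(meta, cfg)
        assert np.allclose(dens["CD3"], 500.0)

    def test_nk_cells_rare_and_bounded(self):
        cfg = SimulationConfig(seed=2)
        meta = [SampleMeta(f"m{i:04d}", "rt") for i in range(1000)]
        dens = generate_densities(meta, cfg)
        assert dens["CD56"].max() <= 30
        assert np.median(dens["CD56"]) == 0.0

    def test_non_positive_median_rejected(self):
        with pytest.raises(ValueError):
            cfg = SimulationConfig()
            cfg.density_params["uv"]["CD3"] = (0.0, 10.0)
            SimulationConfig(density_params=cfg.density_params)


class TestVariants:
    @pytest.fixture()
    def uv_spectrum_sample(self, default_panel, reference_contexts):
        cfg = SimulationConfig(seed=3)
        cfg.signature_mix["uv"] = {"SBS7b": 1.0}
        cfg.burden_rate["uv"] = 80.0
        meta = [SampleMeta("g001_uv", "uv", purity=0.5)]
        truth = GroundTruth()
        return (
            generate_variants(meta, default_panel, cfg, reference_contexts, truth),
            reference_contexts,
            truth,
        )

    def test_pure_sbs7b_yields_dipyrimidine_ct(self, uv_spectrum_sample):
        variants, contexts, truth = uv_spectrum_sample
        somatic = [v for v in variants if v.pop_af == 0.0 and v.vaf >= 0.05]
        assert len(somatic) >= 50
        def is_dipyr_ct(v):
            ctx = contexts.context_at(v.contig, v.pos_1based)
            if v.ref == "C" and v.alt == "T":
                return ctx[0] in "CT"
            if v.ref == "G" and v.alt == "A":  # pyrimidine strand is reverse
                return ctx[2] in "GA"
            return False
        frac = sum(map(is_dipyr_ct, somatic)) / len(somatic)
        assert frac >= 0.6

    def test_artifact_and_germline_counts_exact(
        self, default_panel, reference_contexts
    ):
        cfg = SimulationConfig(seed=4)
        meta = [SampleMeta("g001_heart", "heart", purity=0.5)]
        truth = GroundTruth()
        variants = generate_variants(meta, default_panel, cfg,
                                     reference_contexts, truth)
        artifacts = [v for v in variants if v.vaf < 0.05]
        assert len(artifacts) == cfg.n_low_vaf_artifacts
        common = [v for v in variants if v.pop_af > 0.001]
        entry = truth.samples["g001_heart"]
        assert len(common) == entry["n_common_germline"] + entry["n_tsg_snps"]

    def test_vaf_centers_on_half_purity(self, default_panel, reference_contexts):
        cfg = SimulationConfig(seed=5, depth_mean=1000.0)
        cfg.burden_rate["heart"] = 100.0
        meta = [SampleMeta("g001_heart", "heart", purity=0.5)]
        truth = GroundTruth()
        variants = generate_variants(meta, default_panel, cfg,
                                     reference_contexts, truth)
        somatic = [v for v in variants
                   if v.pop_af == 0.0 and v.pathogenicity_class == "unknown"
                   and v.vaf >= 0.05]
        assert np.mean([v.vaf for v in somatic]) == pytest.approx(0.25, abs=0.03)

    def test_empty_panel_rejected(self, reference_contexts):
        from angiomics.panel import PanelDefinition
        cfg = SimulationConfig()
        meta = [SampleMeta("g1", "uv", purity=0.5)]
        panel = PanelDefinition(genes={"G": [("panel1", 0, 10)]})
        panel.genes = {}
        with pytest.raises(ValueError):
            generate_variants(meta, panel, cfg, reference_contexts, GroundTruth())

    def test_synonymous_fraction(self, default_panel, reference_contexts):
        cfg = SimulationConfig(seed=6)
        cfg.burden_rate["heart"] = 100.0
        meta = [SampleMeta("g001_heart", "heart", purity=0.5)]
        variants = generate_variants(meta, default_panel, cfg,
                                     reference_contexts, GroundTruth())
        somatic = [v for v in variants
                   if v.pop_af == 0.0 and v.pathogenicity_class == "unknown"
                   and v.vaf >= 0.05]
        frac = np.mean([v.consequence == "synonymous" for v in somatic])
        assert frac == pytest.approx(cfg.synonymous_fraction, abs=0.1)


class TestCoverage:
    def _one_sample(self, purity, copies, gene="MYC"):
        cfg = SimulationConfig(seed=7, coverage_noise_sd=0.0)
        meta = [SampleMeta("s1", "rt", purity=purity)]
        truth = GroundTruth()
        truth.entry("s1")["amplified_genes"] = {gene: copies} if copies else {}
        genes = [f"G{i}" for i in range(19)] + [gene]
        return generate_coverage(meta, genes, cfg, truth)

    @pytest.mark.parametrize(
        "purity, copies, expected_ratio",
        [(0.7, 0, 1.0), (1.0, 8, 4.0), (0.5, 8, 2.5)],
    )
    def test_mixture_model_ratios(self, purity, copies, expected_ratio):
        matrix = self._one_sample(purity, copies)
        ratios = relative_coverage(matrix, "s1")
        assert ratios["MYC"] == pytest.approx(expected_ratio, rel=1e-6)

    def test_amplification_prevalence_calibration(self):
        """Secondary-cluster MYC amplification frequency converges to the
        configured 68% at large n."""
        cfg = SimulationConfig(seed=8)
        cfg.genomic_n = {s: n * 40 for s, n in GENOMIC_N.items()}
        meta, truth = generate_cohort(cfg, arm="genomic")
        generate_amplifications(meta, cfg, truth)
        sec = [m for m in meta if m.cluster == "secondary"]
        frac = np.mean([
            "MYC" in truth.samples[m.sample_id]["amplified_genes"] for m in sec
        ])
        assert frac == pytest.approx(0.68, abs=0.04)


class TestDdrPrevalenceRecovery:
    def test_secondary_ddr_fraction_converges(self, default_panel, reference_contexts):
        """With defaults, the secondary-cluster DDR-mutation fraction
        converges to the configured 0.60."""
        cfg = SimulationConfig(seed=9)
        n = 400
        meta = [SampleMeta(f"g{i:04d}_rt", "rt", purity=0.5) for i in range(n)]
        cfg.burden_rate["rt"] = 0.5  # passengers are irrelevant here
        truth = GroundTruth()
        generate_variants(meta, default_panel, cfg, reference_contexts, truth)
        frac = np.mean([truth.samples[m.sample_id]["ddr_mutated"] for m in meta])
        se = math.sqrt(0.6 * 0.4 / n)
        assert abs(frac - 0.60) < 1.96 * se * 1.5


class TestRoundTrips:
    def test_all_emitted_files_round_trip(self, sim_dir):
        raw = io.read_vcf(f"{sim_dir}/variants.vcf")
        assert raw, "synthetic VCF must contain records"
        cov = io.read_coverage_tsv(f"{sim_dir}/coverage.tsv")
        assert cov.coverage.shape[0] == 50
        dens = io.read_density_tsv(f"{sim_dir}/densities.tsv")
        assert dens.shape[0] == 257 + 50
        meta, arms = io.read_metadata_tsv(f"{sim_dir}/metadata.tsv")
        assert len(meta) == 307
        assert set(arms.values()) == {"immune", "genomic"}

    def test_vcf_round_trip_preserves_fields(self, tmp_path, toy_panel):
        from angiomics.filters import VariantRecord

        original = [
            VariantRecord("chr1", 150, "C", "T", "GENEA", "missense",
                          0.0005, 480, 120, "s1", 4),
            VariantRecord("chr1", 1005, "G", "A", "GENEB", "synonymous",
                          0.0, 510, 260, "s2", "unknown"),
        ]
        path = tmp_path / "v.vcf"
        io.write_vcf(original, path, {"chr1": 10_000}, sample_ids=["s1", "s2"])
        back = io.read_vcf(path)
        assert back == original
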