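"""Shared fixtures: a toy two-gene panel, the default synthetic panel with
its seeded reference, and one fully simulated + analyzed study per session."""

from __future__ import annotations

import pytest

from angiomics import pipeline, simulate
from angiomics.panel import PanelDefinition


@pytest.fixture
def toy_panel() -> PanelDefinition:
    """Two genes on one contig plus a TERT promoter interval.

    GENEA: exons [100, 200) and [300, 400); GENEB: [1000, 1500);
    TERT promoter: [5000, 5300); splice flank 2 bp.
    """
    return PanelDefinition(
        genes={
            "GENEA": [("chr1", 100, 200), ("chr1", 300, 400)],
            "GENEB": [("chr1", 1000, 1500)],
        },
        splice_flank_bp=2,
        tert_promoter=("chr1", 5000, 5300),
    )


@pytest.fixture(scope="session")
def default_panel() -> PanelDefinition:
    return simulate.build_default_panel()


@pytest.fixture(scope="session")
def reference_contexts(default_panel) -> simulate.ReferenceContexts:
    reference = simulate.generate_reference(default_panel, seed=0)
    return simulate.ReferenceContexts(reference, default_panel)


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory) -> str:
    """One default synthetic study (seed 0) shared across the session."""
    out = tmp_path_factory.mktemp("sim")
    pipeline.cmd_simulate(out, simulate.SimulationConfig(seed=0))
    return str(out)


@pytest.fixture(scope="session")
def analyzed_dir(sim_dir, tmp_path_factory) -> str:
    out = tmp_path_factory.mktemp("analyzed")
    cfg = pipeline.RunConfig(out_dir=str(out))
    pipeline.cmd_analyze(cfg, sim_dir)
    return str(out)
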