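"""Total tumor mutational burden (TMB) per sample and TMB-high classification.

Total TMB counts both synonymous and non-synonymous eligible mutations per
megabase of panel territory; the denominator is the panel's effective size
including splice flanks, i.e. exactly the territory whose variants enter the
numerator.  A sample is TMB-high when TMB >= 10 mut/Mb (the cutoff value
itself counts as high).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .filters import VariantRecord
from .panel import PanelDefinition, SampleMeta

logger = logging.getLogger(__name__)

TMB_HIGH_CUTOFF = 10.0  # mut/Mb, inclusive


@dataclass(frozen=True)
class TmbResult:
    sample_id: str
    n_eligible_variants: int
    effective_size_mb: float
    tmb: float
    tmb_high: bool


def compute_tmb(
    eligible: list[VariantRecord],
    panel: PanelDefinition,
    sample_id: str | None = None,
    cutoff: float = TMB_HIGH_CUTOFF,
) -> TmbResult:
    """TMB = eligible mutation count / panel megabases; high iff tmb >= cutoff."""
    mb = panel.effective_size_mb
    if mb <= 0:
        raise ValueError("panel effective size must be positive")
    if sample_id is None:
        ids = {v.sample_id for v in eligible}
        if len(ids) > 1:
            raise ValueError("variants from multiple samples; pass sample_id")
        sample_id = ids.pop() if ids else ""
    n = len(eligible)
    tmb = n / mb
    return TmbResult(sample_id, n, mb, tmb, tmb >= cutoff)


def summarize_tmb(
    results: list[TmbResult], meta: list[SampleMeta]
) -> pd.DataFrame:
    """Median, range and TMB-high counts per cluster and per subgroup.

    Median is the standard order statistic (mean of the two central values
    for even n).  Empty groups are omitted with a warning.
    """
    by_id = {m.sample_id: m for m in meta}
    missing = [r.sample_id for r in results if r.sample_id not in by_id]
    if missing:
        raise KeyError(f"samples without metadata: {missing[:5]}")
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "tmb": [r.tmb for r in results],
            "tmb_high": [r.tmb_high for r in results],
            "cluster": [by_id[r.sample_id].cluster for r in results],
            "subgroup": [by_id[r.sample_id].subgroup for r in results],
        }
    )
    rows = []
    for level in ("cluster", "subgroup"):
        for name, g in df.groupby(level, sort=True):
            if g.empty:  # pragma: no cover - groupby never yields empty groups
                logger.warning("empty TMB group %s omitted", name)
                continue
            rows.append(
                {
                    "level": level,
                    "group": name,
                    "n": len(g),
                    "median_tmb": float(np.median(g["tmb"])),
                    "min_tmb": float(g["tmb"].min()),
                    "max_tmb": float(g["tmb"].max()),
                    "n_tmb_high": int(g["tmb_high"].sum()),
                }
            )
    return pd.DataFrame(rows)


def tmb_table(results: list[TmbResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "n_eligible": [r.n_eligible_variants for r in results],
            "mb": [r.effective_size_mb for r in results],
            "tmb": [r.tmb for r in results],
            "tmb_high": [r.tmb_high for r in results],
        }
    )
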