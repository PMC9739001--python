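"""Gene amplification calling from median-normalized relative coverage.

Relative coverage of gene *g* in a sample is the gene's mean coverage,
divided by its baseline capture-efficiency weight, normalized by the
per-sample median of these weighted coverages.  A relative coverage >= 3 is
called amplification (inclusive threshold).  Under a two-population mixture
of diploid normal cells and tumor cells carrying *c* copies,

    ratio = (1 - purity) + purity * c / 2,

so the purity-corrected copy number is c = (2*ratio - 2*(1 - purity)) / purity,
floored at 0.  Losses/deletions are not called.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

AMP_RATIO_THRESHOLD = 3.0
MIN_GENES_FOR_MEDIAN = 10


@dataclass
class CoverageMatrix:
    """samples x genes mean coverage plus per-gene baseline weights.

    ``coverage`` is a DataFrame indexed by sample_id with gene columns;
    ``weights`` maps gene -> expected relative capture efficiency (default 1).
    """

    coverage: pd.DataFrame
    weights: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.coverage.values < 0).any():
            raise ValueError("coverage must be non-negative")
        if self.weights is None:
            self.weights = pd.Series(1.0, index=self.coverage.columns)
        else:
            self.weights = self.weights.reindex(self.coverage.columns).fillna(1.0)
        if (self.weights <= 0).any():
            raise ValueError("baseline weights must be positive")

    @property
    def genes(self) -> list[str]:
        return list(self.coverage.columns)

    @property
    def samples(self) -> list[str]:
        return list(self.coverage.index)


@dataclass(frozen=True)
class AmplificationCall:
    sample_id: str
    gene: str
    relative_coverage: float
    amplified: bool
    estimated_copies: float | None  # reported only when amplified


def relative_coverage(matrix: CoverageMatrix, sample_id: str) -> pd.Series:
    """gene -> weighted coverage over the per-sample median weighted coverage."""
    cov = matrix.coverage.loc[sample_id]
    weighted = cov / matrix.weights
    positive = weighted[weighted > 0]
    if len(positive) == 0:
        raise ValueError(f"all-zero coverage for sample {sample_id}")
    if len(positive) < MIN_GENES_FOR_MEDIAN:
        raise ValueError(
            f"need >= {MIN_GENES_FOR_MEDIAN} covered genes for a stable median, "
            f"got {len(positive)}"
        )
    med = float(np.median(positive))
    return weighted / med


def estimate_copies(ratio: float, purity: float) -> float:
    """Invert the diploid-background mixture model; floored at 0 copies."""
    if not 0 < purity <= 1:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    return max(0.0, (2.0 * ratio - 2.0 * (1.0 - purity)) / purity)


def expected_ratio(copies: float, purity: float) -> float:
    """Forward mixture model: relative coverage expected at a copy number."""
    if not 0 < purity <= 1:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    return (1.0 - purity) + purity * copies / 2.0


def call_amplifications(
    ratios: pd.Series,
    sample_id: str,
    purity: float,
    threshold: float = AMP_RATIO_THRESHOLD,
) -> list[AmplificationCall]:
    """One call per gene; amplified iff ratio >= threshold (3.0 exactly is amplified)."""
    if not np.isfinite(ratios).all():
        raise ValueError("non-finite relative coverage")
    calls = []
    for gene, ratio in ratios.items():
        amp = bool(ratio >= threshold)
        calls.append(
            AmplificationCall(
                sample_id=sample_id,
                gene=str(gene),
                relative_coverage=float(ratio),
                amplified=amp,
                estimated_copies=estimate_copies(float(ratio), purity) if amp else None,
            )
        )
    return calls


def calls_table(calls: list[AmplificationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "gene": [c.gene for c in calls],
            "relative_coverage": [c.relative_coverage for c in calls],
            "amplified": [c.amplified for c in calls],
            "estimated_copies": [
                c.estimated_copies if c.estimated_copies is not None else np.nan
                for c in calls
            ],
        }
    )
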