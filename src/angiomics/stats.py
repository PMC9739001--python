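"""Cohort statistics: Fisher exact tests, Mann-Whitney U, density summaries,
feature prevalences, and the per-sample integration (oncoprint-style) table.

Two-sided Fisher exact p-values use the point-probability rule: with all
margins fixed, sum the hypergeometric probabilities of every table whose
point probability does not exceed that of the observed table (relative
tolerance 1e-12 on the comparison, to avoid floating-point tie artifacts).
Mann-Whitney U uses midranks, exact enumeration for small tie-free samples
and the tie- and continuity-corrected normal approximation otherwise.
Group summaries report median and interquartile range (linear-interpolation
quantiles).  p-values are reported raw; no multiplicity adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, mannwhitneyu

from .panel import GeneSets, SampleMeta

logger = logging.getLogger(__name__)

MARKERS = ("CD3", "CD8", "FoxP3", "CD4", "CD20")
NK_MARKER = "CD56"

_TIE_RTOL = 1e-12
_EXACT_MWU_MAX = 400  # exact enumeration when n_a * n_b <= this and no ties


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts; rows = groups, columns = feature present/absent."""

    a: int  # group 1, present
    b: int  # group 1, absent
    c: int  # group 2, present
    d: int  # group 2, absent

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table is empty")


def fisher_exact_two_sided(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p by hypergeometric point-probability summation.

    Degenerate tables (a zero margin) return p = 1.0.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    r1 = a + b          # row 1 margin
    k = a + c           # column "present" margin
    if r1 == 0 or r1 == n or k == 0 or k == n:
        logger.debug("degenerate contingency table %s: p = 1", table)
        return 1.0
    lo = max(0, k - (n - r1))
    hi = min(k, r1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, k, r1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + _TIE_RTOL)].sum())
    return min(p, 1.0)


def mann_whitney_u(
    values_a, values_b
) -> tuple[float, float]:
    """Mann-Whitney U (midranks) and two-sided p.

    Exact enumeration when n_a*n_b <= 400 with no ties; otherwise normal
    approximation with tie correction and continuity correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(a) * len(b) <= _EXACT_MWU_MAX and not has_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method,
                       use_continuity=True)
    return float(res.statistic), float(res.pvalue)


@dataclass
class GroupComparison:
    feature: str
    groups: tuple[str, str]
    statistic: float
    p_value: float
    summaries: dict  # per-group summary dict


def _median_iqr(values: np.ndarray) -> tuple[float, float]:
    """Median and Q3-Q1 with linear-interpolation (type-7) quantiles."""
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return float(med), float(q3 - q1)


def summarize_densities(
    densities: pd.DataFrame,
    meta: list[SampleMeta],
    grouping: str = "cluster",
    markers: tuple[str, ...] = MARKERS,
) -> list[GroupComparison]:
    """Median (IQR) per group and Mann-Whitney p per marker.

    ``densities`` is indexed by sample_id with marker columns (cells/mm²).
    ``grouping`` is "cluster" (two groups, with p-value) or "subgroup"
    (summaries only).  Samples missing a marker are dropped for that marker
    with a warning.
    """
    by_id = {m.sample_id: m for m in meta}
    labels = pd.Series(
        {sid: getattr(by_id[sid], grouping) for sid in densities.index if sid in by_id}
    )
    out: list[GroupComparison] = []
    group_names = sorted(labels.unique())
    for marker in markers:
        col = densities.loc[labels.index, marker]
        n_missing = int(col.isna().sum())
        if n_missing:
            logger.warning("%d samples missing %s dropped for that marker",
                           n_missing, marker)
        col = col.dropna()
        summaries = {}
        per_group_values = {}
        for g in group_names:
            vals = col[labels.reindex(col.index) == g].to_numpy()
            per_group_values[g] = vals
            if len(vals) == 0:
                logger.warning("group %s empty for marker %s; omitted", g, marker)
                continue
            med, iqr = _median_iqr(vals)
            summaries[g] = {"n": len(vals), "median": med, "iqr": iqr}
        if len(group_names) == 2 and all(len(v) > 0 for v in per_group_values.values()):
            u, p = mann_whitney_u(per_group_values[group_names[0]],
                                  per_group_values[group_names[1]])
        else:
            u, p = float("nan"), float("nan")
        out.append(GroupComparison(
            feature=marker,
            groups=tuple(group_names)[:2] if len(group_names) == 2 else ("", ""),
            statistic=u, p_value=p, summaries=summaries,
        ))
    return out


def density_summary_table(comparisons: list[GroupComparison]) -> pd.DataFrame:
    rows = []
    for comp in comparisons:
        for group, s in comp.summaries.items():
            rows.append({
                "marker": comp.feature, "group": group, "n": s["n"],
                "median": s["median"], "iqr": s["iqr"], "p_value": comp.p_value,
            })
    return pd.DataFrame(rows)


def feature_prevalence(
    features: pd.DataFrame,
    meta: list[SampleMeta],
) -> pd.DataFrame:
    """Counts/percents of boolean features per cluster and subgroup, with
    cluster-level Fisher exact p.

    ``features`` is indexed by sample_id with boolean columns (e.g.
    pathogenic_mutation, ddr_mutation, any_amplification, amp_MYC, tmb_high).
    """
    by_id = {m.sample_id: m for m in meta}
    cluster = pd.Series({s: by_id[s].cluster for s in features.index})
    subgroup = pd.Series({s: by_id[s].subgroup for s in features.index})
    rows = []
    for feat in features.columns:
        col = features[feat].astype(bool)
        prim = col[cluster == "primary"]
        sec = col[cluster == "secondary"]
        tbl = ContingencyTable(
            a=int(prim.sum()), b=int((~prim).sum()),
            c=int(sec.sum()), d=int((~sec).sum()),
        )
        p = fisher_exact_two_sided(tbl)
        for name, grp in (("primary", prim), ("secondary", sec)):
            rows.append({
                "feature": feat, "level": "cluster", "group": name,
                "n_present": int(grp.sum()), "n_total": len(grp),
                "percent": 100.0 * grp.sum() / len(grp) if len(grp) else float("nan"),
                "fisher_p": p,
            })
        for name in sorted(subgroup.unique()):
            grp = col[subgroup == name]
            rows.append({
                "feature": feat, "level": "subgroup", "group": name,
                "n_present": int(grp.sum()), "n_total": len(grp),
                "percent": 100.0 * grp.sum() / len(grp) if len(grp) else float("nan"),
                "fisher_p": float("nan"),
            })
    return pd.DataFrame(rows)


def sample_features(
    meta: list[SampleMeta],
    variants_by_sample: dict[str, list],
    amp_calls: pd.DataFrame,
    tmb_results: pd.DataFrame,
    gene_sets: GeneSets,
) -> pd.DataFrame:
    """Boolean feature flags per sample for the prevalence bookkeeping.

    ``variants_by_sample`` maps sample -> kept (reportable) VariantRecords;
    ``amp_calls`` and ``tmb_results`` are the tables written by the copy
    number and TMB stages.
    """
    rows = {}
    amp_by_sample = (
        amp_calls[amp_calls["amplified"]].groupby("sample_id")["gene"].agg(set)
        if len(amp_calls) else pd.Series(dtype=object)
    )
    tmb_high = dict(zip(tmb_results["sample_id"], tmb_results["tmb_high"])) \
        if len(tmb_results) else {}
    amp_gene_cols = sorted(gene_sets.amplification_genes)
    for m in meta:
        kept = variants_by_sample.get(m.sample_id, [])
        path = [v for v in kept if v.pathogenicity_class in (4, 5)]
        amps = amp_by_sample.get(m.sample_id, set())
        row = {
            "pathogenic_mutation": bool(path),
            "ddr_mutation": any(v.gene in gene_sets.ddr_genes for v in path),
            "any_amplification": bool(amps),
            "tmb_high": bool(tmb_high.get(m.sample_id, False)),
        }
        for g in amp_gene_cols:
            row[f"amp_{g}"] = g in amps
        rows[m.sample_id] = row
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def build_integration_table(
    meta: list[SampleMeta],
    tmb_results: pd.DataFrame,
    amp_calls: pd.DataFrame,
    allelic_calls: pd.DataFrame,
    variants_by_sample: dict[str, list],
    densities: pd.DataFrame | None,
    min_samples_per_gene: int = 2,
) -> pd.DataFrame:
    """One row per sample: subgroup, TMB, per-gene mutation class and
    amplification flags, DDR flag, and lymphocyte densities.

    Gene columns are restricted to genes altered (class-4/5 mutation or
    amplification) in at least ``min_samples_per_gene`` samples; pass 1 to
    emit the full table.  Missing modalities leave columns empty but retain
    the row.
    """
    gene_sets = GeneSets()
    mut_genes: dict[str, set[str]] = {}
    for sid, kept in variants_by_sample.items():
        for v in kept:
            if v.pathogenicity_class in (4, 5):
                mut_genes.setdefault(v.gene, set()).add(sid)
    amp_genes: dict[str, set[str]] = {}
    if len(amp_calls):
        for _, r in amp_calls[amp_calls["amplified"]].iterrows():
            amp_genes.setdefault(r["gene"], set()).add(r["sample_id"])
    altered: dict[str, set[str]] = {}
    for g, s in mut_genes.items():
        altered.setdefault(g, set()).update(s)
    for g, s in amp_genes.items():
        altered.setdefault(g, set()).update(s)
    selected = sorted(g for g, s in altered.items() if len(s) >= min_samples_per_gene)

    tmb_by_sample = tmb_results.set_index("sample_id") if len(tmb_results) else None
    biallelic = (
        allelic_calls[allelic_calls["state"] == "biallelic"]
        .groupby("sample_id")["gene"].agg(set)
        if len(allelic_calls) else pd.Series(dtype=object)
    )
    rows = []
    for m in meta:
        kept = variants_by_sample.get(m.sample_id, [])
        path = [v for v in kept if v.pathogenicity_class in (4, 5)]
        row: dict = {
            "sample_id": m.sample_id,
            "cluster": m.cluster,
            "subgroup": m.subgroup,
            "purity": m.purity,
        }
        if tmb_by_sample is not None and m.sample_id in tmb_by_sample.index:
            row["tmb"] = float(tmb_by_sample.loc[m.sample_id, "tmb"])
            row["tmb_high"] = bool(tmb_by_sample.loc[m.sample_id, "tmb_high"])
        else:
            row["tmb"] = np.nan
            row["tmb_high"] = pd.NA
        row["ddr_mutation"] = any(v.gene in gene_sets.ddr_genes for v in path)
        bia = biallelic.get(m.sample_id, set())
        for g in selected:
            classes = sorted(
                v.pathogenicity_class for v in path if v.gene == g
                if isinstance(v.pathogenicity_class, int)
            )
            label = ""
            if classes:
                label = f"class{max(classes)}"
                if g in bia:
                    label += "_biallelic"
            row[f"mut_{g}"] = label
            row[f"amp_{g}"] = m.sample_id in amp_genes.get(g, set())
        for marker in MARKERS:
            if densities is not None and m.sample_id in densities.index:
                row[marker] = float(densities.loc[m.sample_id, marker])
            else:
                row[marker] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id").sort_index()
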