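"""96-channel single-base-substitution catalogs and signature refitting.

SNVs are binned into the standard 96 trinucleotide channels: substitution
class in {C>A, C>G, C>T, T>A, T>C, T>G} crossed with the 5' and 3' flanking
bases, all expressed on the pyrimidine strand (purine-reference SNVs are
reverse-complemented before binning).  Channel order is the lexicographic
(substitution, 5' base, 3' base) layout with labels like ``A[C>T]G``.

Catalogs of samples with high mutational burden are refit against a fixed
signature set by non-negative least squares (NNLS) on the channel-normalized
catalog; exposures are renormalized to fractions, and the cosine similarity
between the catalog and its reconstruction is reported as fit quality.

The bundled signature set is a synthetic five-column stand-in emulating the
qualitative spectra of clock-like deamination (SBS1: C>T at NpCpG),
a broad flat background (SBS5), UV photodamage (SBS7a/SBS7b: C>T at
dipyrimidines), and a uniform channel ("flat").  Any COSMIC-format matrix
(rows labeled ``A[C>A]A``-style) can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .tmb import TmbResult

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Channel labels in canonical order, e.g. "A[C>A]A", "A[C>A]C", ...
CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)
CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}

MIN_SNVS_FOR_FIT = 20
BUNDLED_SIGNATURES = "sbs_signatures_synthetic.tsv"


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def channel_of(ref: str, alt: str, context: str) -> str:
    """Map an SNV with its reference trinucleotide context to a channel label.

    ``context`` is the 3-base reference sequence centered on the variant.
    Purine references are collapsed onto the pyrimidine strand, e.g. G>A in
    context TGT maps to A[C>T]A.
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(context) != 3 or context[1] != ref:
        raise ValueError(f"context {context!r} does not center on ref {ref!r}")
    if ref == alt or ref not in COMPLEMENT or alt not in COMPLEMENT:
        raise ValueError(f"not an SNV: {ref}>{alt}")
    if ref in ("G", "A"):
        ref, alt, context = COMPLEMENT[ref], COMPLEMENT[alt], revcomp(context)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


@dataclass
class SbsCatalog96:
    """Per-sample counts over the 96 channels; sum equals the SNV count used."""

    sample_id: str
    counts: np.ndarray
    n_skipped: int = 0  # SNVs without a retrievable context

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (96,):
            raise ValueError("catalog must have exactly 96 channels")
        if (self.counts < 0).any():
            raise ValueError("catalog counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class SignatureSet:
    """96 x k column-stochastic signature matrix with names."""

    names: list[str]
    matrix: np.ndarray  # shape (96, k)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (96, len(self.names)):
            raise ValueError("matrix must be 96 x len(names)")
        if (self.matrix < 0).any():
            raise ValueError("signature probabilities must be non-negative")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("each signature column must sum to 1")

    def subset(self, names: list[str]) -> "SignatureSet":
        idx = [self.names.index(n) for n in names]
        return SignatureSet(names=list(names), matrix=self.matrix[:, idx])


@dataclass
class ExposureVector:
    sample_id: str
    exposures: dict[str, float]  # fractions summing to 1 (empty if indeterminate)
    cosine: float
    indeterminate: bool = False


def build_catalog(
    snvs: list,
    context_lookup,
    sample_id: str = "",
) -> SbsCatalog96:
    """Bin SNVs into a 96-channel catalog.

    ``context_lookup(contig, pos_1based) -> str | None`` returns the 3-base
    reference context centered on the position; SNVs whose context is
    unavailable (or disagrees with the record's ref allele) are skipped and
    counted in ``n_skipped``.
    """
    counts = np.zeros(96, dtype=np.int64)
    skipped = 0
    for v in snvs:
        if not getattr(v, "is_snv", True):
            skipped += 1
            continue
        ctx = context_lookup(v.contig, v.pos_1based)
        if ctx is None or len(ctx) != 3 or ctx[1].upper() != v.ref.upper():
            skipped += 1
            continue
        counts[CHANNEL_INDEX[channel_of(v.ref, v.alt, ctx)]] += 1
    return SbsCatalog96(sample_id=sample_id, counts=counts, n_skipped=skipped)


def fit_exposures(
    catalog: SbsCatalog96,
    signatures: SignatureSet,
    min_snvs: int = MIN_SNVS_FOR_FIT,
) -> ExposureVector:
    """NNLS refit of a catalog against a signature set.

    Raises on an all-zero catalog (such samples are not analyzed).  Catalogs
    with fewer than ``min_snvs`` mutations yield an indeterminate result:
    panel-scale catalogs below that size cannot support a stable refit.
    """
    total = catalog.total
    if total == 0:
        raise ValueError(
            "cannot fit an empty catalog; signature refitting applies only to "
            "samples with mutations (select TMB-high samples first)"
        )
    if total < min_snvs:
        return ExposureVector(catalog.sample_id, {}, float("nan"), indeterminate=True)
    target = catalog.counts / total
    coef, _ = nnls(signatures.matrix, target)
    if coef.sum() == 0:  # pragma: no cover - requires pathological signatures
        return ExposureVector(catalog.sample_id, {}, 0.0, indeterminate=True)
    fractions = coef / coef.sum()
    recon = signatures.matrix @ coef
    denom = np.linalg.norm(target) * np.linalg.norm(recon)
    cosine = float(target @ recon / denom) if denom > 0 else 0.0
    cosine = min(max(cosine, 0.0), 1.0)
    return ExposureVector(
        catalog.sample_id,
        dict(zip(signatures.names, fractions.tolist())),
        cosine,
    )


def select_signature_samples(results: list[TmbResult]) -> list[str]:
    """Sample ids eligible for signature analysis: TMB-high (tmb >= 10, inclusive)."""
    return [r.sample_id for r in results if r.tmb_high]


# ----------------------------------------------------------------------
# Synthetic signature construction and COSMIC-format I/O


def _spread(channel_weights: dict[str, float], background: float) -> np.ndarray:
    col = np.full(96, background / 96.0)
    for label, w in channel_weights.items():
        col[CHANNEL_INDEX[label]] += w
    return col / col.sum()


def synthetic_signature_set() -> SignatureSet:
    """Construct the bundled synthetic 5-signature set.

    These are *synthetic* spectra, not the reference COSMIC matrices: each
    captures the defining channels of the process it is named after, which
    is sufficient for refitting and recovery experiments on synthetic data.
    """
    # SBS1-like: C>T at NpCpG (5-methylcytosine deamination)
    sbs1 = _spread(
        {f"{b}[C>T]G": 0.95 / 4 for b in BASES},
        background=0.05,
    )
    # SBS5-like: broad, mildly structured background (fixed-seed Dirichlet)
    rng = np.random.default_rng(202211)
    sbs5 = rng.dirichlet(np.full(96, 2.0))
    # SBS7a-like: C>T at TpC dipyrimidines dominant
    sbs7a = _spread(
        {**{f"T[C>T]{b}": 0.85 / 4 for b in BASES},
         **{f"C[C>T]{b}": 0.10 / 4 for b in BASES}},
        background=0.05,
    )
    # SBS7b-like: C>T at CpC dipyrimidines dominant
    sbs7b = _spread(
        {**{f"C[C>T]{b}": 0.80 / 4 for b in BASES},
         **{f"T[C>T]{b}": 0.15 / 4 for b in BASES}},
        background=0.05,
    )
    flat = np.full(96, 1.0 / 96.0)
    matrix = np.column_stack([sbs1, sbs5, sbs7a, sbs7b, flat])
    return SignatureSet(
        names=["SBS1", "SBS5", "SBS7a", "SBS7b", "flat"], matrix=matrix
    )


def read_signature_tsv(path: str | Path) -> SignatureSet:
    """Read a COSMIC-format signature TSV (rows = 96 labeled contexts)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(CHANNELS) - set(df.index)
    if missing:
        raise ValueError(f"signature TSV missing channels: {sorted(missing)[:3]} ...")
    df = df.loc[list(CHANNELS)]
    return SignatureSet(names=list(df.columns), matrix=df.to_numpy())


def write_signature_tsv(signatures: SignatureSet, path: str | Path) -> None:
    pd.DataFrame(
        signatures.matrix, index=pd.Index(CHANNELS, name="Type"),
        columns=signatures.names,
    ).to_csv(path, sep="\t", float_format="%.8g")


def load_bundled_signatures() -> SignatureSet:
    """Load the synthetic signature TSV shipped with the package."""
    ref = resources.files("angiomics").joinpath(f"data/{BUNDLED_SIGNATURES}")
    with resources.as_file(ref) as path:
        return read_signature_tsv(path)
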