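# Methods

## Panel model and territory

The targeted panel is a set of per-gene exon intervals (BED4, 0-based
half-open on disk; all in-memory queries are 1-based, VCF convention, with
conversion only at the reader boundary). Callable territory is the union of
exons, a configurable splice flank of 2 intronic bases on each exon edge
(the canonical splice-site convention), and a TERT promoter interval
(default: 300 bp upstream of the TERT transcription start, the hotspot
convention). The panel's effective size in megabases is the merged length
of exactly this territory, so the TMB denominator matches the territory
whose variants enter the numerator. The panel's megabase size is a
parameter, not a constant; the bundled synthetic panel covers ≈1.16 Mb
(65 genes × 12 exons × 1.5 kb).

Every position maps to exactly one category (exonic / splice /
tert_promoter / outside); unknown contigs are outside, logged, never an
error.

## Filter cascade

Four exclusion rules are evaluated exhaustively (no short-circuit) so
per-rule removal counts are complete: R1 out-of-territory (TERT promoter
excepted), R2 synonymous unless in a splice site, R3 population allele
frequency strictly above 0.1%, R4 VAF strictly below 5%. Both thresholds
are strict inequalities mirroring their usual statement, so boundary values
(pop AF = 0.001, VAF = 0.05) survive. A missing population AF is treated as
0: absence from a population database is not evidence of commonness.
Zero-depth records are flagged malformed, a state distinct from an R4
failure. The TMB-eligible set is derived from the same outcome objects by
re-admitting variants whose only failure is R2, because total TMB counts
synonymous and non-synonymous mutations alike; consequently the reportable
set is always a subset of the TMB-eligible set. Pathogenicity classes
(1–5) are input annotations and enter TMB regardless of class.

## TMB

`tmb = n_eligible / effective_Mb`; TMB-high uses the inclusive cutoff
10 mut/Mb. No germline-subtraction model beyond rule R3 (the pipeline is
tumor-only by design). Group summaries use the standard order-statistic
median.

## Copy number

Relative coverage divides each gene's mean coverage by its baseline
capture-efficiency weight (default 1, standing in for a panel of normals)
and normalizes by the per-sample median across genes; at least 10 covered
genes are required for a stable median. Amplification is called at the
inclusive ratio threshold 3. Copy number assumes a two-population mixture
of diploid normal cells and tumor cells at purity ρ carrying c copies,
`ratio = (1−ρ) + ρ·c/2`, inverted and floored at zero. The tumor background
is assumed diploid; losses are not called.

## Allelic state

For class-4/5 variants in tumor-suppressor genes, with purity ρ: the
expected heterozygous VAF is ρ/2 and the expected LOH VAF is ρ/(2−ρ); a
germline heterozygous SNP shifts from 0.5 by ρ/(2(2−ρ)) under LOH. The
named evidence sources (relative coverage, variant VAF, nearby SNP allele
fractions) are combined into an explicit three-tier rule of this package's
design: (1) ≥2 distinct class-4/5 variants in the gene → biallelic
(second hit); (2) an exact binomial test rejects the het model upward at
α = 0.05 while a two-sided test does not reject the LOH model → biallelic
(LOH by VAF); (3) the median absolute shift of ≥3 nearby heterozygous SNPs
exceeds half the expected LOH shift → biallelic (LOH by SNPs); otherwise
monoallelic. Calls are indeterminate below 50× depth, with unknown purity,
or when the gene itself is amplified (the diploid VAF model no longer
applies). "Nearby" means within 1 Mb of the gene (configurable); the
population-common records that the somatic filter removes are re-used as
heterozygous-SNP probes (population AF above 0.1%, allele fraction in
(0.05, 0.95)).

## Mutational signatures

SNVs are binned into the standard 96 channels — substitution class
{C>A, C>G, C>T, T>A, T>C, T>G} × 5′ base × 3′ base, purine-reference SNVs
reverse-complemented onto the pyrimidine strand — in lexicographic order
with `A[C>T]G`-style labels. Catalogs are built only for TMB-high samples
(inclusive ≥10 mut/Mb). Refitting is non-negative least squares on the
channel-normalized catalog; exposures are renormalized to fractions and the
cosine similarity between catalog and reconstruction is reported. NNLS was
chosen because it is the standard deterministic refitting approach.
Catalogs under 20 SNVs (configurable) are reported indeterminate: panel
catalogs are tiny, and refits below that size are unstable. There is no
hard "detected" label; exposures plus cosine are reported and any detection
threshold is left to the caller (0.2 is a reasonable default).

The bundled signature set is **synthetic**: five 96-channel columns built in
code (`synthetic_signature_set`) that capture the defining channels of the
processes they are named after — SBS1-like (C>T at NpCpG, 5-methylcytosine
deamination), SBS5-like (broad background, fixed-seed Dirichlet),
SBS7a-like (C>T at TpC dipyrimidines), SBS7b-like (C>T at CpC
dipyrimidines), and a flat column. They are not the reference COSMIC
matrices; any COSMIC-format TSV can be supplied instead. A small fixed set
is used by default because refitting a 60+ column catalog against a
panel-scale catalog invites overfitting.

## Cohort statistics

Two-sided Fisher exact p-values use the point-probability rule: with
margins fixed, sum hypergeometric probabilities of all tables whose point
probability is at most that of the observed table, with a relative
tolerance of 1e-12 on the comparison to avoid floating-point tie artifacts
(for tables with N ≤ 40, genuinely distinct probability ratios differ from
1 by more than ~7e-12, so the tolerance cannot misclassify a tie).
Degenerate tables (a zero margin) return p = 1. Mann–Whitney U uses
midranks; exact enumeration when n₁·n₂ ≤ 400 with no ties, otherwise the
normal approximation with tie and continuity corrections. Quantiles are
linear-interpolation (type-7). p-values are reported raw — no multiplicity
adjustment. Percentages are 100·count/group-size. The integration table
restricts gene columns to genes altered in ≥2 samples by default (the full
table is available via a parameter).

## Synthetic cohort generator

The generator emulates the two-arm study design: an immunology arm of
79 primary + 178 secondary tumors (subgroup sizes 11/20/15/28/5 and
126/38/14) and a genomic arm of 25 + 25 (4/5/4/7/5 and 13/7/5). All draws
flow from a single seed through named substreams, so every emitted file is
byte-reproducible.

* **Densities** (cells/mm²) are log-normal per subgroup and marker, with σ
  solved from the configured median m and IQR via
  `IQR = 2·m·sinh(z₀.₇₅·σ)`, so the distribution's median and central 50%
  mass match the configured values; IQR = 0 degenerates to the constant
  median. Defaults are the published subgroup median/IQR tables (e.g. UV
  CD3⁺ 817 (862)). NK cells are zero with probability 0.7, otherwise
  uniform on 1–30, reproducing "rare, never above 30, median 0".
* **Somatic SNVs**: counts are Poisson(rate × Mb) with per-sample
  log-normal rate heterogeneity (σ_log = 0.4). Passenger rates are set so
  *total* TMB (passengers + injected drivers, which add roughly one
  mutation per driver-positive sample) lands near the published levels: UV
  9.4, visceral 3.2, non-UV skin 5.6 mut/Mb subgroup medians and 3.2/3.9
  cluster medians, with UV ≫ others. Trinucleotide contexts are drawn from
  the subgroup's signature mixture (UV-associated: 85% SBS7a/7b) and placed
  on reference sites carrying the required context; the reference is a
  seeded random FASTA over the panel contig, so no genome download is
  needed. VAFs are binomial at depth ~Poisson(500) around ρ/2, or ρ/(2−ρ)
  for designated LOH events.
* **Drivers**: DDR-pathway class-4/5 mutations at the published cluster
  prevalences (24%/60%), TP53 restricted to secondary tumors (~20% of them,
  always biallelic); non-TP53 hits are biallelic with probability 0.5
  (30% of those via a literal second hit, the rest via LOH). Non-DDR
  drivers are added at the rate that brings total pathogenic-mutation
  prevalence to 80%/88%. Three germline het SNPs flank every hit TSG
  (allele fractions shifted under LOH) to exercise the SNP evidence tier.
* **Amplifications**: per-subgroup marginal probabilities calibrated to the
  published pattern (MYC 4/25 primary vs 17/25 secondary in expectation;
  FLT4 only with MYC; CRKL rare). Copy numbers are drawn above the
  purity-dependent detection floor (expected ratio ≥ 3.5), because
  prevalences measured by the ratio-threshold rule refer to detectable,
  high-level events. Coverage is baseline × per-sample depth factor ×
  2% multiplicative noise (gene-level mean coverage at ~500× has negligible
  counting noise; 2% represents capture variability), times the mixture
  factor for amplified genes.
* **Nuisance records**: exactly 8 population-common (AF 0.002–0.2) and 5
  low-VAF (< 5%) records per sample, labeled in the ground truth so filter
  tests can count exact removals. A configured 30% of passengers are
  synonymous.
* **Purity**: uniform on [0.30, 0.90] for genomic-arm samples (the study
  requires ≥30% tumor cells for genomic analysis).

What the generator does *not* emulate: indels and structural variants,
read-level sequencing error, FFPE artifact spectra beyond the low-VAF
channel, inter-marker density correlation within a sample, microsatellite
status, and subgroup-specific driver genes beyond TP53/SETD2-level
structure. Passing tests therefore demonstrate correctness of the
analysis stages under the stated statistical model, not performance on
real FFPE panel data.

## Problem sizes and determinism

Default problem sizes (50 genomic + 257 immunology samples, ~1.16 Mb panel,
~1500 variant records) run the full pipeline in a few seconds; test-suite
simulations reuse one session-scoped cohort. Recovery experiments use 100
catalogs × 500 mutations (signatures) and the full default cohort
(copy number). All randomness flows from explicit seeds; reruns are
byte-identical, and the acceptance script derives every substream from its
`--seed` argument.

## Known limitations

* Tumor-only pipeline: germline variants are removed only by the population
  rule, so rare germline variants can survive as apparent somatic calls —
  as in any panel workflow without a matched normal.
* The copy-number model assumes a diploid background and whole-gene events;
  subclonal or focal intragenic amplifications bias c downward.
* The allelic-state rule treats evidence tiers hierarchically; conflicting
  tiers (e.g. balanced SNPs with an LOH-consistent VAF) resolve in favor of
  the VAF test.
* With the published burden levels, many TMB-high panel catalogs carry
  fewer than 20 SNVs and are reported indeterminate rather than refit —
  mirroring the small number of tumors with enough mutations for signature
  analysis.
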