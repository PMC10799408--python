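# Methods

This note documents the models, rules, and numerical choices behind each
module, the assumptions of the synthetic-data generator, and what the tests
do and do not demonstrate about real data.

## Somatic SNV filter (`filters`)

A variant is removed when it triggers at least one of ten exclusion
criteria; all criteria are always evaluated so the rejects carry every
triggered reason (no short-circuiting). The criteria, with defaults:

| reason | rule | default |
|---|---|---|
| low_depth | depth < min_depth | 30 |
| blacklist | flagged in a curated artifact blacklist | — |
| intronic | region class is intronic | — |
| nonsense | variant class is nonsense | on (configurable) |
| db_absent | SNV in neither COSMIC nor snp138 | on (configurable) |
| hla_or_none_gene | gene is `NONE` or begins with `HLA` | — |
| polyphen_benign | both PolyPhen-2 codes are B (missing never triggers) | — |
| population_af | popmax population AF > 0.001 | 0.001 |
| strand_support | fewer than 1 alt read on either strand | — |
| vaf_support | alt reads < 5 or tumor VAF < 5% | 5 / 5% |

Hotspot sites bypass only `vaf_support` and are instead held to alt
support ≥ 5, matched-control (plasma) VAF ≥ 1%, and tumor (tissue)
VAF ≥ 5%. Criteria that annotate substitutions (PolyPhen, the database and
population-frequency lookups) are skipped for indels; depth, blacklist,
region, gene, strand and frequency/support apply to every record.

Design choices made where the rule set was genuinely open: exclusions
combine by OR (standard somatic-filter semantics); `db_absent` removes
variants found in *neither* database, but the direction is configurable
because the intended reading is debatable (an alternative is to treat
snp138-only membership as germline evidence); the benign-PolyPhen rule
requires *both* codes to be B, the least destructive reading; the
non-hotspot frequency/support thresholds mirror the hotspot numbers because
no separate values are established. Excluding nonsense variants is unusual
for somatic work — most pipelines retain them as candidate loss-of-function
drivers — so it sits behind `exclude_nonsense`.

## Spectrum and TiTv (`spectrum`, `stats`)

Substitutions are collapsed onto the pyrimidine strand (COSMIC/maftools
convention), mapping the 12 ordered base pairs onto six classes. Transitions
(C>T, T>C) are 2 of the 6 classes, so the null Ti proportion under a uniform
spectrum is 1/3.

* Within a sample: exact two-sided binomial test of the Ti count in
  Ti+Tv trials against 1/3.
* Between groups: two-sided rank-sum test on per-sample Ti fractions (and,
  per class, on per-sample class proportions). Group-level proportions are
  pooled counts over pooled totals — matching stacked-bar presentation —
  while tests always use per-sample values.

For small groups the rank-sum p-value is computed by full enumeration of
the permutation distribution of the U statistic with half-credit for ties
(`stats.exact_rank_sum_p`), because the asymptotic tie-corrected
approximation is visibly conservative at n ≈ 6 per arm and per-sample Ti
fractions tie frequently when they are ratios of small integer counts. The
enumeration is exact for any group sizes with ≤ 200,000 assignments (up to
roughly 10 vs 10); beyond that scipy's Mann-Whitney is used. Samples with
zero SNVs are dropped from tests with a warning; groups of one sample get
proportions but no p-value.

## TMB and MATH (`burden`)

TMB counts exonic, non-synonymous SNVs and indels with depth ≥ 30 and tumor
VAF ≥ 5% (both configurable; the candidate thresholds reuse the filter's
numbers since no separate convention is established), scaled by 10⁶ /
exon_bases. The targeted footprint `exon_bases` has no default — it is a
property of the capture design (≈ 3.4 × 10⁷ for a standard human exome).

MATH selection keeps SNVs with VAF ≥ 5%, depth ≥ 50×, exonic and
non-synonymous; VAFs below 10% are retained only when at least 10× the
matched-control VAF, a guard against residual germline or contamination
signal. The statistic is MAD/median of the selected VAFs. The default
`canonical` style multiplies by 100 and the 1.4826 Gaussian-consistency
constant, making values comparable to the MATH literature; the `literal`
style reports the bare ratio. MAD is the *median* absolute deviation. With
fewer than two VAFs or a zero median the statistic is undefined (`None`).

## MSI (`msi`)

Allele QC: a locus is evaluable only when total depth strictly exceeds
100×; detectable alleles need ≥ 2 reads and ≥ 5% of the top allele's reads
(both ≥, boundary passing). The baseline stores, per locus, the mean and
sample (n−1) SD of panel allele counts; loci evaluable in fewer than 2
panel samples are dropped with a warning. A tumor locus is unstable when
its allele count *strictly* exceeds mean + 4·SD. Sample status: MSI-H with
≥ 2 unstable loci, else MSS with ≥ 4 stable loci, else QNS; when both
thresholds are met, instability evidence dominates and the sample is MSI-H.
The (n−1) SD is the conservative choice for the small panels this targets;
a degenerate panel (SD = 0) makes any excess allele count unstable, which
the panel-self-consistency test bounds in aggregate.

The caller consumes allele-length histograms; extracting STR-spanning reads
from alignments is upstream of this package.

## Copy number and CNI (`copynumber`)

GC/length correction divides each region's read rate (count/length) by the
median rate of its 2% GC bin and rescales by the global median rate; bins
with fewer than 5 regions fall back to the global median. This is the
simplest standard median-binning scheme — it assumes most regions are
copy-neutral so bin medians estimate the bias, and it cannot correct bias
that correlates with true copy number.

log2 ratios use the panel mean with a half-read-equivalent epsilon guarding
zero counts. Panel members get leave-one-out ratios (each against the mean
of the others) so the panel's spread at each region is not deflated by
self-reference. Z-scores standardize the tumor ratio by the panel's
per-region mean and (n−1) SD, floored at 1e-6 (near-constant regions are
logged, as any deviation there produces an extreme |z|). The retention
threshold is the 95th percentile of the panel's z-scores plus twice their
SD, computed per region by default (a pooled `global_threshold` mode
exists); quantiles use linear interpolation between order statistics, so
the P95 is reproducible bit-for-bit. The CNI score sums retained z-scores.
Summation is one-sided (z > threshold) as the rule is conventionally
stated; deletions then never contribute, so a `two_sided` option retaining
|z| exceedances is provided and documented as an interpretation.

CN estimates, when not supplied, are 2 · 2^log2 (diploid autosome
assumption; sex chromosomes are out of scope). Gain/loss use strict
inequalities — CN > 4 and CN < 1.2 — with boundary values neutral. CNV
burden is (gains + losses) / regions. Segmentation is deliberately absent:
the region is the unit of analysis, matching the CNI grid.

## Cohort comparison (`report`)

One metrics row per sample (TMB, MATH, MSI status, gain/loss counts, CNV
burden, CNI); missing input modalities yield missing fields with warnings,
never silent zeros. Continuous metrics are contrasted with the exact
rank-sum test above; MSI with Fisher's exact test on MSI-H vs not. No
multiple-testing correction is applied and the report says so: at these
sample sizes the p-values are descriptive companions to medians and IQRs.
The JSON report is checked against a shipped minimal schema.

## Synthetic cohorts (`simulate`)

The generator emulates the statistical structure the analysis assumes, not
sequencing itself. Per sample: SNV classes are multinomial over the six
collapsed classes and rendered on a random strand; depths are negative
binomial (mean 200, dispersion 10 — WES-like overdispersion); VAFs are
Beta(2, 5) (clonal-ish mean ≈ 0.29); strand splits are binomial. A
configurable fraction of variants is engineered to violate exactly one
named filter criterion, recorded per variant in the truth manifest. STR
panels draw per-locus allele counts from rounded Gaussians (means 2–3.5,
SDs 0.3–0.7, rendered as QC-passing histograms at ≈ 400× depth); MSI-H
tumors inflate designated loci to ceil(mean + 4·SD) + 2 alleles. Region
grids (default 200 regions of 200–500 bp, GC ~ Uniform(0.3, 0.7)) get
Poisson counts around length × GC-bias × (CN/2) with a quadratic GC bias
peaking at 45% GC; the panel (default n = 30, matching common
normal-reference practice) is diploid throughout.

Default cohort shape: two arms of six tumors, one spectrum C>A-dominant
(70%) and the other C>T-dominant (70%), one MSI-H tumor in the insensitive
arm — proportions chosen to mirror the contrast structure of small
treatment-sensitivity cohorts at sizes where every pipeline stage remains
fast enough for repeated replication in tests. All randomness flows from
one integer seed through SeedSequence spawn keys (one child stream per
sample), so outputs are byte-identical per seed and single samples are
reproducible in isolation.

What the generator does *not* emulate — and therefore what passing tests do
not show about real data: trinucleotide context and mutational signatures,
subclonal structure and purity, mapping artifacts, segment-level CN
correlation, locus-specific STR noise (stutter), and batch effects between
tumor and panel. Recovery results demonstrate the pipeline's correctness
under its own model, not clinical performance.

## Problem sizes

Tests and the acceptance script run cohorts of 12 samples × 300 variants,
200-region grids with 20–30 panel members, and 8–12 STR loci with panels of
12–30; calibration uses 400 replicates for the TiTv level and 200 each for
null CNI and MSS rates. These sizes give stable rates (binomial SE ≈ 1
percentage point at 400 replicates) while keeping full runs fast enough to
replicate many times.

## Known limitations

* The filter's `db_absent` direction and the nonsense exclusion follow an
  unusual convention; both are config-exposed rather than hard-coded.
* The CNI score is one-sided by default, blind to deletions.
* MSI locus thresholds assume the panel's allele-count distribution is
  roughly Gaussian; heavily skewed loci would mis-calibrate mean + 4·SD.
* No purity/ploidy correction: CN estimates are tumor-content-diluted.
* Group tests assume exchangeable samples; no covariate adjustment.
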