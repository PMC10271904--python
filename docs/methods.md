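# Methods

This note documents the models, conventions and numerical choices
behind `nlrmeth`, and what the synthetic study conditions do and do not
establish about real data.

## Coordinates and formats

All internal coordinates are 0-based half-open on the plus strand;
GFF3 (1-based closed) and CX reports (1-based positions) are converted
at the parsing boundary and nowhere else. Parsers reject malformed
rows with line numbers rather than repairing them. Zero-coverage
cytosines are retained at parse time; coverage policy is applied once,
at aggregation (`min_depth`, default 1 read — any covered cytosine
counts, configurable because shallow WGBS inflates per-gene variance).
TE annotations are reduced to intervals; class and strand are ignored
because only accumulated length enters the analysis, and overlapping
or nested annotations are unioned per chromosome before any coverage
arithmetic so duplicated entries cannot push coverage past 100 %.

## Copy-number cutoff

The cutoff separating expanded from conserved families is selected
from the frequency distribution f(k) of copy number k over all
(species, family) pairs: compute |f(kᵢ) − f(kᵢ₊₁)| / f(k_min) over
consecutive support points and return the smallest k from which every
remaining normalised difference stays below τ (default 0.01). Two
guards keep the rule stable on small samples: the stable run must span
at least two consecutive differences (a lone near-zero difference at
the tail of a sparse distribution is noise, not a plateau), and when
no k qualifies the configured fallback (default 5, the operational
high/low-copy boundary) is used with a warning. Classification is
strict: copy number > cutoff ⇒ type I, ≤ cutoff ⇒ type II. Copy
numbers are tallied per (species, family) pair, consistent with
per-species classification.

## Weighted methylation

The level of a region × context is Σmᵢ / Σ(mᵢ + uᵢ) over all
qualifying cytosines on either strand — a count-weighted ratio, not a
mean of per-site fractions. Integer prefix sums make every query exact,
so the level of any region equals the (m, m+u)-weighted combination of
the levels of any partition of it; the test suite checks this identity
per gene across the 100 metagene bins. A region with no covered
cytosine has an *undefined* level, propagated as missing and dropped
listwise in tests — never coerced to zero, which would bias sparse
flanks downward.

## Regions

Upstream/downstream are transcriptional: for a minus-strand gene the
upstream flank lies at higher genomic coordinates. The coarse scheme
is four 5 kb bins per 20 kb flank plus the gene body; windows are
clipped at chromosome ends and clipped-away bins are kept zero-length
(flagged truncated) so bin counts are constant across genes. For the
screens, flank bins are aggregated to one upstream and one downstream
region by summing counts (methylation) or covered bp (TE) — exactly
the 20 kb region's weighted value — because the per-species tests are
reported at upstream/body/downstream resolution while per-bin values
feed profiles. The metagene scheme bins body and each 5 kb flank
independently (100 + 100 + 100 at defaults), keeping TSS and TTS as
hard anchors; the body partition uses the largest-remainder rule with
the wider bins 5'-most, so bin widths differ by at most 1 bp and every
base belongs to exactly one bin. Genes shorter than the bin count get
one base per bin with trailing empty bins flagged. Neighbouring genes
do not truncate flanks.

## Statistics

The unit of observation is the gene (one weighted level or coverage
value per aggregated region), avoiding the pseudo-replication of
per-cytosine tests. Two-group comparisons use Welch's t-test
(two-sided, Welch–Satterthwaite df); zero-variance ties give t = 0,
p = 1. A stratum is testable with ≥ 3 non-missing values per type
(`min_group_n`; no such floor is standard, 3 is the minimum giving a
meaningful variance estimate). The default screen alpha is 0.001, with
0.01 offered as well — published screens of this design have used
both thresholds, and the discrepancy is surfaced in the configuration
rather than resolved silently. No multiple-testing correction is
applied by default, matching common practice for these per-species
tallies; a Benjamini–Hochberg option exists. "Consensus region"
means a (feature, region) stratum restricted to its significant
species; the pooled test runs one Welch test on the pooled per-gene
values of exactly those species, and with a single significant species
it reduces to that species' screen test. The similarity contrast
likewise compares per-(species, family) mean identities rather than
pooled pairs. The overlap statistic is emitted in both interpretations
— species significant in any region (`any_region`, default) or in the
same region (`matched_region`) — because the per-region reading is as
defensible as the per-species one.

## Synthetic data model

Per species, one chromosome of uniform random sequence carries
non-overlapping genes (2 kb, ≥ 8 kb apart) assigned to families whose
copy numbers follow a heavy low-copy law with a high-copy tail
(mass {1: 0.55, 2: 0.2, 3: 0.1, 4: 0.06, 5: 0.04, 6: 0.02, 8: 0.02,
12: 0.01} — a fixture shape, not a claim about real genomes). Family
sizes are drawn from the law conditioned on the type boundary until
the per-type gene targets (40 + 40 by default) are met exactly.

TE insertions are planted upstream within 5 kb of the TSS with
probability 0.8 for type I genes and 0.1 for type II, 3 kb long
(LTR/DNA-transposon scale), on a background of 20 random TEs per Mb.
Methylation probability at a cytosine is
μ(context) + δ(context)·exp(−d/L) clipped to [0, 1], with background
μ = 0.30/0.10/0.03 (CG/CHG/CHH), TE effect δ = 0.12 for CHG and CHH
and 0 for CG, and decay length L = 1 kb — an exponential caricature
of methylation spreading from silenced TEs. Read counts are
beta-binomial: per-site p ~ Beta(mean, precision κ = 50), depth ~
Poisson(λ = 10), methylated reads ~ Binomial(depth, p); κ → ∞
recovers the binomial for analytic checks. Protein similarity comes
from per-family star phylogenies with per-site divergence 0.30
(high-copy) vs 0.05 (low-copy) families, so expanded families are
more diverged, and identity is the fraction of matching sites (copies
are generated ungapped). All draws flow from one seeded generator in
fixed order; regeneration and file output are byte-identical.

What this emulates: the planted direction and rough effect geometry
of TE-associated non-CG hypermethylation around expanded NLRs, copy-
number skew, and divergence–expansion coupling. What it does not:
real genome composition and TE taxonomy, methylation-state spatial
autocorrelation beyond the TE decay, bisulfite conversion error,
mapping bias, or between-species phylogenetic dependence. Passing
tests therefore demonstrate the pipeline's arithmetic and inferential
behaviour under known truth, not biological conclusions about any
real species.

## Problem sizes

Default study conditions are 3 species × 80 genes on 1 Mb chromosomes
(~5 × 10⁵ cytosines per species). The null-calibration check uses 60
down-scaled species (10 + 10 genes, 240 kb) to accumulate 720 testable
strata with no planted effect; the detection-rate check uses 20 seeded
replicates at the default conditions. These sizes keep every check
exact or well-powered while the whole suite runs in about a minute.

## Known limitations

- The cutoff rule operationalises "the difference slope becomes
  stable"; on distributions whose tail frequencies tie exactly over
  longer runs it can still select a tail plateau. The fallback and
  the guard cover the cases observed in practice.
- `pairwise_identity` is a test-scale global aligner (match +1,
  mismatch −1, gap −2, ties preferring diagonal then vertical); it is
  not a BLASTP substitute and is quadratic in sequence length.
- The pooled consensus test inherits the selection of its species from
  the screen; its p-value is conditional on that selection and should
  be read as descriptive, as in the study design it mirrors.
- TE coverage within the gene body is emitted as a single body region
  (plus optional per-bin values); body-internal 5 kb binning is not a
  separate statistic.
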