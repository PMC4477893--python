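# Methods

This note documents the models implemented in gistkit, the parameter
defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical and design decisions that were
genuinely open.

## Founder-mutation model

A somatic mutation present in essentially all tumour cells ("founding
mutation") of a sample with purity *p* ∈ (0, 1] is carried by one of the
two alleles in a fraction *p* of cells, so each sequenced read covers the
mutant allele with probability *q* = *p*/2. At coverage *n* the mutant
read count is *X* ~ Binomial(*n*, *q*). Because allele sampling is
stochastic, a fixed allele-fraction cutoff would discard true founders at
low coverage; instead the classifier uses the coverage-dependent threshold

  k(n) = max{ k ≥ 1 : P(X ≥ k) ≥ γ },  γ = 0.95,

so that an expected fraction γ of true founders is retained at every
coverage. When no k ≥ 1 satisfies the tail condition (very small n) the
threshold floors at 1 — a call must always have at least one supporting
read. k(n) is non-decreasing in n, and for every k(n) > 1 the exact tail
brackets γ: P(X ≥ k) ≥ γ > P(X ≥ k+1).

Parameters, with defaults:

- **purity** *p* = 0.6. The histological estimate for the studied case is
  60–70%; 0.6 is the value in that range consistent with the model's
  published threshold boundaries (at 0.65 the threshold would already be 2
  at coverage 13). Configurable.
- **het_factor** = 1/2, the heterozygous dilution. Exposed so hemizygous
  sites on a monosomic arm can use factor 1.
- **inclusion** γ = 0.95.

Numerics: tails are computed by summing binomial pmf terms from the upper
end (smallest terms first) rather than by a normal approximation — the
threshold boundaries near n ≈ 30 are decided by tail-mass differences of
order 10⁻³. The test suite cross-checks every threshold for n ≤ 200 at
five purity levels against a brute-force oracle in exact rational
arithmetic (`fractions.Fraction`).

The model is deliberately minimal: no multi-sample deconvolution, no
cancer-cell-fraction posterior, no copy-number adjustment. It is an
inclusion rule for heterozygous-diploid candidates, nothing more.

## Variant-filter cascade

Six independent predicates applied in a fixed order: somatic (control alt
reads ≤ tolerance, default 0), both strands represented among mutant
reads, depth ≥ 10 in tumour *and* control, exonic region, non-silent
effect, no known-SNP identifier. The final survivor set is
order-independent (the predicates are independent); the fixed order exists
so per-stage attrition counts are well defined, and a record failing
several stages is charged to the first. Applying the depth rule to both
samples is the conservative symmetric reading of "a reliable estimate on
allele frequency needs depth"; both the depth and the control-tolerance
are configurable. Known-SNP status is an input annotation or a plain-text
id list — never a live database lookup, for version independence.
Region/effect classes are consumed as annotations; the package does no
effect prediction.

## Arm-level LOH and purity from BAF

At a germline-heterozygous SNP, reads in a tumour sample of purity *t*
with monoallelic loss in all tumour cells are drawn from 2(1 − *t*) normal
alleles plus (1 − 0)·(*t*) retained tumour alleles, giving expected BAF
(1 − *t*)/(2 − *t*) for the lost haplotype and 1/(2 − *t*) for the
retained one; the two bands sum to 1. The folded BAF min(f, 1 − f)
collapses both bands onto b = (1 − *t*)/(2 − *t*), and the median folded
BAF of an arm inverts to the purity estimate t̂ = (1 − 2b)/(1 − b),
clipped to [0, 1]. The estimate requires ≥ 20 usable sites; fewer raise an
insufficient-data error rather than returning a noisy number.

Usable sites are control heterozygotes: control BAF in [0.4, 0.6] and
depth ≥ 10 in both samples (reusing the filter module's depth rule) — the
mixture algebra holds only at genuinely heterozygous sites.

The summary is per chromosome arm, not segmented: the analysis this
package reproduces presents whole-arm loss only, so no breakpoint model is
claimed or implemented. The LOH decision is a fixed, reproducible rule:
median folded BAF below the midpoint between 0.5 and the purity-expected
band when the purity is known, below 0.4 otherwise.

Depth ratios are reported in two conventions, because raw tumour/control
ratios conflate library size with copy number: `depth_ratio` divides each
sample by its genome-wide median depth before forming the arm-level ratio
(expected (2 − *t*)/2 ≈ 0.675 at *t* = 0.65 for a lost arm), and
`depth_ratio_raw` is the unnormalized arm ratio. Which convention a given
published "half the control depth" figure used is generally not stated, so
both are exposed and neither is guessed.

## Screen enrichment

A prevalence screen reports, for each polymorphic site, in how many of N
panel samples the variant was seen. Under the null that the panel is an
ordinary diploid draw from the population, the mutant allele count among
2N chromosomes is Binomial(2N, MAF). Each carrier sample is counted as
one mutant allele — zygosity is unreported in such screens, so this is a
conservative lower bound on the observed count (an
`alleles_per_carrier=2` mode gives the upper bound). The test is the
one-sided upper-tail exact binomial test, unadjusted by default (a
Bonferroni option exists but is off, matching the single-claim reading of
the original analysis); sites with unknown MAF are reported
not-applicable, never imputed. MAFs come verbatim from the input table;
there is no live population-database lookup.

The discreteness of the exact test makes it conservative: the per-site
type-I error under the null simulation stays below the nominal 0.05.

## C2H2 zinc-finger scanning

The scanner matches C-x(1,5)-C-x(10,14)-H-x(3,5)-H, a relaxation of the
canonical C-x2-C-x12-H-x3-H spacing (finger databases disagree on
stringency, and predicted finger counts in long zinc-finger proteins vary
several-fold with it; bounds are configurable). Matching is left-to-right
and non-overlapping; among admissible anchor assignments at a starting
cysteine the one lexicographically closest to the canonical spacing wins,
then leftmost anchors. The spacing preference matters in practice: a
histidine inside the recognition helix (e.g. at offset 9 of one of the
packaged ZNF407 motifs) must not be mistaken for the first coordinating
histidine.

Substitution roles: the four anchors are zinc-coordinating; residues
strictly between the second cysteine and first histidine are
recognition-helix (these determine the DNA triplet read by the finger);
everything else is spacer, with positions between the two histidines
flagged helix-adjacent — the recognition helix runs through the
histidines, but no finer partition is defensible from spacing alone, so
none is claimed. The distance upstream of the terminal histidine is
reported because residue preferences at those positions are sharply
constrained in functional fingers. No position-specific scoring matrix is
evaluated; in-finger position and distance are the computed outputs.

## Methylation pipeline

Per-probe normalization rescales a raw intensity linearly between
reference intensities of the fully unmethylated and fully methylated
states and clips to [0, 1] — the minimal model of "normalize each probe
between 0 and 1 against reference signals", exploiting that a probe's
dynamic range is consistent across samples. A conventional beta transform
M/(M + U + offset) is available for two-channel input. No type-I/type-II
probe-chemistry correction beyond the per-probe rescale is modelled.

Probes are filtered by across-sample variance > 0.1 (sample variance,
n − 1 denominator — the convention is configurable because the cutoff is a
hard threshold). Samples are clustered agglomeratively with distance
d = 1 − r (Pearson correlation across probes; anticorrelated profiles are
maximally distant, so the absolute value is *not* taken) and complete
linkage, via scipy's implementation, which is deterministic for a given
input order; a zero-variance sample is an error naming the sample, not a
silent NaN. Dendrograms export to Newick; flat labels come from cutting
the tree at a requested cluster count.

## Synthetic data

The generators produce every input the pipeline reads, with truth labels
sufficient to score each stage without re-deriving ground truth, and are
byte-deterministic per seed. Defaults encode the study conditions: purity
0.6, Poisson(45) depth (bracketing the case's tumour/control averages of
42 and 50; a negative-binomial option adds overdispersion), loss of 14q,
a 52-sample panel with the screen's known MAFs, and a two-group
methylation design.

- **Variant tables**: founder alt counts ~ Binomial(n, p/2); subclonal
  mutations at clone fractions uniform in 0.05–0.3 (not a published
  value; chosen to give clear separation from founders at these depths);
  germline hets at 0.5 in both samples; strand split Binomial(alt, 1/2);
  somatic control contamination 0 by default with an optional error rate.
- **LOH genomes**: per-site random phase between the two mixture bands,
  lost-arm depth scaled by (2 − t)/2.
- **Screen panels**: per-sample genotypes Binomial(2, MAF); an enriched
  site generates at 8× its reported MAF (capped at 0.5) — a multiplier
  chosen to make a clearly detectable planted signal, not an estimate of
  any real effect.
- **Methylation**: informative probes are differentially methylated in
  both directions (alternating hyper/hypo between groups, means 0.8/0.2,
  noise sd 0.05) over a low-variance background (sd 0.02). The
  two-directional design is what real differential methylation looks
  like; it is also required for the group contrast to survive a
  correlation distance, which centres each sample profile.
- **Proteins**: planted copies of the two packaged ZNF407 finger motifs
  inside linkers free of C and H (so no spurious fingers can arise), with
  variants at known offsets.

What the generators do **not** emulate: read-level artefacts (mapping
error, strand bias, GC coverage waves), segmental or subclonal copy-number
change, population structure in the panel, probe-chemistry effects, and
correlated noise between probes. Passing the synthetic suites therefore
demonstrates the correctness of the statistics under their own generating
assumptions — not robustness to real-data artefacts, which the original
pipeline delegated to upstream callers and array preprocessing.

## Problem sizes and statistical test design

The validation suites run at the sizes the analyses were designed around:
threshold-oracle equivalence for n ≤ 200 at five purities; 10,000
simulated founders for the sensitivity check (Monte-Carlo error ~0.2%,
so the ≥ 94.5% bound tests the designed 95% inclusion); purity recovery
from 2,000 SNPs; 100 seeded LOH replicates at purities 0.4 and 0.65 with
500 SNPs per arm; 1,000 null screen panels; 50 methylation seeds.
Simulation-based assertions on rates use the stated bounds where a
replicate count makes them stable, and an explicit 3σ Monte-Carlo margin
over the nominal level otherwise.

## Known limitations

- The founder model assumes diploid heterozygous candidates; on lost arms
  the het_factor must be set to 1 by the caller.
- Arm-level LOH only; focal events within an arm dilute the median folded
  BAF and can be missed.
- The purity estimator assumes clonal whole-arm loss; subclonal loss
  biases t̂ downward.
- The screen test ignores zygosity and relatedness within the panel; both
  biases are conservative under the one-allele-per-carrier count.
- The published attrition counts of the original whole-genome analysis
  (thousands of somatic calls down to tens of coding candidates) derive
  from unavailable raw sequencing data; the cascade is therefore validated
  on constructed fixtures with planted per-stage failures, and the
  published candidate table is re-scored only through the founder
  classifier.
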