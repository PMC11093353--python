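# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of `hifseek`. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Factorial differential expression

The expression model is the classical randomized-complete-block ANOVA on
RMA-style log2 summaries: per gene, `y_jb = mu + tau_j + beta_b + e_jb`
with treatments j = 1..t (default t = 8: N2, N2+hypoxia, hif-1,
hif-1+hypoxia, vhl-1, rhy-1, egl-9, swan-1;vhl-1) and blocks b = 1..b
(default 3 biological replicates). In the balanced layout the
least-squares estimate of a zero-sum contrast `sum_j w_j tau_j` is the
contrast applied to treatment means, its variance is
`MSE * sum(w^2) / b`, and the general F-test has (1, (b-1)(t-1)) df —
14 with the default design. The closed form is verified against a general
OLS fit (statsmodels) to 1e-8 on random balanced instances; the package
deliberately rejects unbalanced designs rather than silently switching
estimators, since the design it models is balanced by construction.

Genes with (numerically) zero residual variance are flagged, given an
F = +inf sentinel and an undefined p, and excluded from the q-value
input: a pseudo-p for a constant gene would be arbitrary, and the flag
preserves the information.

**HIF-1 dependence** is operationalized as the interaction contrast
(N2 hypoxia effect minus hif-1 hypoxia effect) with its own F-test and
q-value. Its back-transform is exactly the printed "relative induction
(N2/hif-1)" in the signed fold-change convention, which is why that
single contrast carries the classification: positive dependence requires
interaction q <= 0.05 and relative induction >= 1.6, negative dependence
<= -1.6. The fold-change threshold applies to the back-transformed
contrast estimate; in a balanced design this equals the ratio of
cell-mean back-transforms.

**q-values.** pi0 is estimated from pi0(lambda) = #{p > lambda} /
(m (1 - lambda)) on lambda = 0, 0.05, ..., 0.90, smoothed by a
least-squares polynomial with 3 effective degrees of freedom (a
3-parameter quadratic; the common smoothing-spline-with-3-df choice has
no direct scipy equivalent, and at 19 grid points the two smoothers are
close while the quadratic has the lower endpoint variance), evaluated at
lambda = 0.90 and clamped to (0, 1]. The step-up q computation
`q_(i) = min_{j>=i} pi0 * m * p_(j) / j` reduces exactly to
Benjamini-Hochberg when pi0 is forced to 1, which the tests assert. The
estimator is unbiased but inherits the Monte-Carlo noise of the
empirical tail (SD ~ 0.02 at m = 10,000), so calibration is asserted on
an average over independent draws.

**Probeset deduplication** (one probeset per gene and one gene per
probeset) is stated as a goal, not an algorithm, in the source analyses;
here it is a deterministic greedy matching: probesets in decreasing order
of overall mean intensity, each taking its lexicographically first
still-free annotated gene. Greedy matching is not maximum matching; the
tests assert validity (injectivity both ways), not maximality.

## Binding-region calling

The caller is a transparent substitute for model-based two-sample peak
callers: reads binned by 5' position into 200-bp bins (matching the
sequencing fragment length the bin convention comes from), then a
per-bin one-sided Poisson upper-tail test of the ChIP count against the
depth-normalized input count `lambda_i = input_i * chip_total /
input_total`, floored at the genome-wide mean normalized input per bin.
The floor prevents unbounded enrichment at zero-input bins; it only ever
raises lambda, so it is conservative. BH control runs jointly across all
bins of all chromosomes at FDR 0.05; significant bins merge when
adjacent (a max-gap parameter exists, default 0). "Minimum posterior
probability <= 0.05" from posterior-based callers maps to "minimum
BH-adjusted p <= 0.05" here — a deliberate, documented behavioural
difference confined to the background model; every surrounding quantity
(bin size, FDR level, the four filter criteria with inclusive
thresholds, merging, two-replicate reproducibility) is kept.

Peak filter (2), "averaged input tag count >= 10", is applied to the raw
averaged input count; fold enrichment (filter 4) divides the averaged
ChIP count by the *normalized, floored* averaged input. Both statistics
are carried on every call.

**Reproducibility.** Binding regions are the intersection of the two
replicates' filtered peak-interval unions, each piece snapped outward to
the bin grid, carrying both replicates' peak statistics. Chains
(A1—B1—A2) are grouped by overlap components, but disjoint intersection
pieces are emitted separately: merging across a gap supported by neither
replicate pair would contradict the intersection rule. Intersection
(rather than union, or one replicate's coordinates) was chosen because
it is the conservative reading and yields bin-multiple region sizes.

Coordinates are 0-based half-open internally; 1-based inclusive strings
appear only in reports.

## Target assignment, context, HRE

Distances between disjoint intervals are the difference of nearest
boundary *coordinates* on the 1-based inclusive scale (for half-open
intervals with a left of b: `b.start + 1 - a.end`), and 0 on overlap.
This is the convention that reproduces published promoter distances
exactly (e.g. 1453 bp for the *efk-1* region), and it is measured to the
gene span, not the TSS, so intragenic regions are at distance 0.

Assignment: candidate genes within 6 kb; if any candidate is on the
differentially-expressed union (hypoxia-responsive, HIF-1-dependent, or
mutant-misregulated), *all* such candidates are assigned
(basis `de_priority` — a region can therefore map to more than one
gene); otherwise the single nearest candidate is assigned, ties broken
toward the smaller start coordinate (an arbitrary but deterministic
rule; the tie is a measure-zero event in real data).

Context classification: disjoint regions are upstream/downstream by
strand-aware position; a region overlapping the 5' UTR and extending
beyond the upstream edge of the span is `upstream_5utr_overlap`;
otherwise the interior feature (intron, coding, 3' UTR) with maximal
overlap wins, ties broken intron > coding > three_prime_utr. Span
overlap outside any annotated feature falls back to `intron` (in compact
genomes un-annotated gene-body sequence is intronic space). The
categories are exhaustive and mutually exclusive, which the tests assert
by tiling windows across gene models on both strands.

HRE scanning matches RCGTG (`full`) or the mandatory core CGTG
(`core`), reporting all overlapping matches; `strands="both"` also scans
the reverse complement and reports minus-strand hits at their
forward-sequence offsets. Defaults are `core` on the given strand: the
core motif on one strand is the reading consistent with reported
incidence scales on AT-rich sequence; both knobs are exposed because the
published convention is ambiguous.

## Overlap and enrichment statistics

Gene-list overlap is Fisher's exact test on the 2x2 table over the array
population (default 18,011 unique genes; always overridable — synthetic
runs use the simulated population). One-sided "greater" is the default
alternative because overlap enrichment is the scientific question;
two-sided is available. Published overlap p-values are not asserted
anywhere: independent reconstruction from printed marginals does not
reproduce them exactly under either sidedness, suggesting unprinted list
adjustments; only significance at p < 0.001 is a contract, and the
implementation is instead verified against an exhaustive hypergeometric
sum at small population sizes to 1e-12.

Category enrichment takes a generic 3-level annotation table
(Cat1/Cat2/Cat3 paths), tests each category per level with the
hypergeometric upper tail, and applies Bonferroni correction within the
level (cut-off 0.01). It does not ship any annotation database.

## Phenotype testing and qPCR

Survival endpoints (hatched at 24 h, adult at 72 h, against the plated
total) are tested per genotype by a binomial GLM with logit link and
additive replicate + treatment factors; the p-value is the
likelihood-ratio test of the treatment term. "Inappropriate" model
situations are operationalized as complete separation (an arm pooled at
0% or 100%) or non-convergence; then a replicate-stratified
randomization test runs instead: treatment labels permuted within each
replicate, statistic = difference in pooled success proportions. The
null distribution is a product of per-replicate hypergeometrics, so when
the stratified space is small (<= 250,000 states) the p-value is computed
exactly; otherwise Monte Carlo with p = (1 + #{|T*| >= |T|}) /
(1 + n_perm) at 10,000 permutations. Per-embryo Bernoulli data are
aggregated to replicate-level binomial counts (equivalent likelihood).

ChIP-qPCR enrichment is the efficiency-corrected comparative method:
`E_t^(Ct_t,input - Ct_t,IP) / E_r^(Ct_r,input - Ct_r,IP)`, with
efficiencies in (1, 2.2] (fold per cycle; 2 = perfect doubling). Under
equal efficiencies it is invariant to a common Ct shift.

## The synthetic-data generator

The generator's defaults are the study conditions the tests run under;
they are fixed, not tuned per test.

* **Expression** (2,000 genes): planted log2 effect 2.0 (linear 4.0),
  residual SD 0.25, per-gene block SD 0.3, baseline N(7, 1). Classes:
  5% hypoxia-up, 5% hypoxia-down (effect in both genotypes' hypoxia
  arms), 5% HIF-1-positive (effect in the N2 hypoxia arm only, so the
  interaction equals the planted effect), 5% HIF-1-negative (mirror),
  2% + 2% mutant-misregulated (effect in the vhl-1 arm), remainder null.
  Class labels are shuffled across gene ids.
* **Genome**: 2 chromosomes x 6 Mb, genes of 1.5-3 kb with 100-bp 5'
  UTR, 150-bp 3' UTR, 2-4 exons, alternating strand, 2-kb intergenic
  spacing; sequence i.i.d. at GC 0.36 (the *C. elegans* genome-wide
  value). 6 Mb is the smallest round size at which the default 2,000
  genes fit with this spacing.
* **ChIP**: two replicates; input and background ChIP counts are
  negative binomial with mean 20 per bin and size 200 (variance/mean =
  1.1). The generator deliberately omits mappability and GC bias, and a
  bias-free uniformly sampled library is near-Poisson, so only mild
  extra-Poisson noise is realistic; the choice also keeps the generator
  consistent with its own null contract (null tracks produce ~0 peaks at
  FDR 0.05, which the tests check against the analytic NB tail mass).
  Planted peaks are bin-aligned (3 bins = 600 bp, matching reported
  bin-multiple region sizes), placed 1-4 bins upstream of the TSS of
  target genes drawn round-robin from the planted classes plus nulls,
  with the ChIP mean multiplied by 5. A peak is only planted where no
  second non-null gene lies within the 6-kb assignment range, making the
  constructed gene the unique by-construction target. Decoys are planted
  in replicate 1 only. 1-3 RCGTG motifs are spliced into each planted
  peak's sequence.
* **Phenotype**: binomial counts, 300 animals per arm and replicate,
  three replicates; defaults give the wild type no hypoxia penalty and
  the hif-1 mutant 78% hatching / 18% adulthood under hypoxia.
  Adulthood is drawn as a subset of hatched animals.

One RNG stream per artifact ("expression", "genome", "chip",
"phenotype"), derived from the master seed by fixed CRC-labelled
SeedSequences: adding a generator cannot perturb the others, and
identical configs are bit-identical.

**What passing tests do and do not show.** The generator has Gaussian
log2 noise, no probe-level effects, no correlation between genes, no
ChIP bias fields, no read-level artifacts and i.i.d. genome sequence.
Recovery results on it demonstrate the pipeline's correctness under its
stated assumptions — calibration of the tests, exactness of the
interval/label logic — not performance on real arrays or real ChIP-seq,
where overdispersion, bias and annotation error dominate.

## Problem sizes

The default test-suite study sizes (2,000 genes; 2 x 6 Mb at 200-bp bins
= 60,000 bins per track; 10 simulation seeds for recovery; 500 null
simulations for calibration) were chosen as the smallest sizes at which
the Monte-Carlo assertions have comfortable margins; all are plain
parameters and scale up linearly.

## Known limitations

* The peak caller's Poisson background is anti-conservative on strongly
  overdispersed real data; it is meant as a transparent, testable
  substitute for model-based callers, not a drop-in replacement on real
  libraries.
* Greedy probeset matching can be smaller than a maximum matching.
* The pipeline's overlap stage compares two internally derived lists as
  a demonstration; real cross-study overlaps should be run through
  `fisher_overlap` with externally curated lists and the appropriate
  population size.
* `category_enrichment` treats the annotation as complete; genes missing
  from it are counted in the population only (with a warning).
* The randomization test assumes exchangeability within replicate; it
  does not model plate effects beyond the replicate stratification.
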