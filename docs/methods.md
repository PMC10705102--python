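# Methods

This note documents the models, defaults and numerical choices behind
`clonmet`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Statistical primitives

**Fisher exact test.** The two-sided p-value for a 2×2 table with
fixed margins is the sum of hypergeometric probabilities of all tables
no more probable than the observed one; probabilities within a relative
tolerance of 1e-7 of the observed one are counted as ties and included.
The implementation groups tables by their margins so that a variant
table is tested in one vectorized pass per distinct margin
configuration (`fisher_exact_many`); the scalar `fisher_exact_2x2` uses
the same core. The test suite checks the implementation against two
independent oracles — `scipy.stats.fisher_exact` and an
exact-integer-arithmetic enumeration — and agrees with the enumeration
to < 1e-12 over every table with row sums ≤ 60. A row sum of zero makes
the conditional test undefined and raises.

**Benjamini–Hochberg.** Step-up adjustment
q(i) = min over j ≥ i of p(j)·m/j in sorted order, capped at 1,
returned in input order. Properties relied on downstream: q ≥ p,
monotonicity in p, permutation equivariance.

**Jonckheere–Terpstra.** For k ordered groups the statistic J sums
Mann–Whitney counts over all ordered group pairs (ties weighted 0.5).
The null mean and the no-ties variance give a standardized z and a
two-sided normal-approximation p. When the number of distinct group
assignments (the multinomial coefficient) is at most 200,000 the
p-value is computed by exact enumeration instead; this covers every
total n ≤ 12 and most unbalanced larger layouts. A fixed assignment-count
cutoff, rather than a sample-size cutoff, is used because balanced
three-group layouts already exceed 10⁷ arrangements at n = 18 while
unbalanced layouts at larger n remain cheap. Ties with the observed
deviation are counted with a 1e-9 slack so float-identical permutations
are included.

## Somatic significance filter

A variant is tested only when tumor *and* normal depth reach
`min_depth` (default 40); requiring the normal as well avoids unstable
normal AFs when a single depth minimum is quoted without naming the
sample. Retention then requires a signed AF
difference (tumor − normal) strictly greater than `min_af_diff`
(default 0.05) — somatic gain is the target; an `absolute` mode is
provided — and a BH q strictly below `fdr_alpha` (default 0.1), with
the BH family being all depth-qualified variants of the same tumor
sample (the most conservative reading of a per-sample workflow).
Boundary semantics are exactly as printed: depth uses ≥ 40, the AF
difference and FDR use strict inequalities. Tumor variants with no
matched normal counts are dropped with a logged count by default; set
`assume_normal_depth` to test them against a synthetic all-reference
normal instead.

## Clonality analysis

The allele-fraction matrix takes as rows the union of variants
significant in any sample of the patient and back-fills each entry from
raw counts; entries with depth below the calling threshold stay missing
and are never imputed (a 0/100 site is a genuine AF of 0, a 5/15 site
is unknown). Distances between samples are Euclidean over
pairwise-complete entries, rescaled by (total variants / jointly
observed) so sparsely overlapping pairs remain comparable; a pair with
zero joint observations is assigned a distance just above the global
maximum, which isolates such samples as late-merging singletons.
Average linkage is used; sample ids are processed in lexicographic
order so output is deterministic.

Relatedness calls use a presence threshold (AF ≥ 0.05 at adequate
depth) and two explicit artifact parameters — at least 5 shared
variants and Jaccard ≥ 0.2 against some LNM for *metastatic-clone*,
Jaccard < 0.05 against every other tumor sample for *independent* —
because no canonical quantitative criterion exists for clonal
relatedness. Both are
exposed on the CLI and their defaults should be treated as package
choices, not literature values. With ≥ 30 truncal mutations at ~150×
these calls are insensitive to the exact thresholds: related foci share
the whole trunk (Jaccard near 1) while independent foci share ~0.

The cohort common-ancestor fraction is (primary foci not called
independent) / (all classified foci) with a Clopper–Pearson binomial
CI. The clonal-selection test pools alt/ref counts across all LNM and
across all primary foci (the comparison is LNM vs *all* foci; a
per-pair analysis can be run by subsetting samples), tests each variant
with the Fisher exact test, adjusts per patient, and reports direction
by the sign of the pooled AF difference.

## Expression scores

Normalization is log2(CPM + 0.5); adding the pseudocount after library
scaling makes the transform exactly invariant to per-sample count
scaling. The DE engine is deliberately simple — Welch's t on log-CPM
with BH across genes; genes constant in both groups get p = 1 — and the
trend/score stages consume any table with (lfc, q) columns, so output
from a negative-binomial GLM engine can be substituted without code
changes. A gene trends *up* when both stage steps (NP→PTF, PTF→LNM)
have positive fold change and q below `alpha` (default 0.01), *down*
symmetrically; the selection is exactly antisymmetric under matrix
negation.

The signature score z-scores each gene across samples (sd 0 genes
dropped with a warning) and averages over the gene-set members present,
so scores always have cross-sample mean 0 and are invariant to any
affine rescaling applied identically to all genes. The mean (rather
than sum) makes the score independent of how many set members survive
filtering. Stage comparisons use the Jonckheere–Terpstra test above.

## Cohort mutation enrichment

Mutation presence is sample-level binary (any qualifying mutation in
the gene); per gene the 2×2 (mutated/wild-type × metastasis/primary)
table is Fisher-tested two-sided, with BH across all tested genes in
the run. Genes with zero mutations in both arms carry no information
and are skipped with a log message. Odds ratios are displayed with the
Haldane–Anscombe 0.5 correction when a cell is zero; the test always
uses the uncorrected counts.

## Synthetic-data generator

The generator emulates the statistical structure each stage assumes:

* **Clone trees.** One germline root; the first tumor clone carries
  `n_truncal_mutations` (default 30) truncal mutations; each additional
  clone attaches to a uniformly chosen existing clone with
  Poisson(`n_private_mean`, default 10) private mutations. Perfect
  phylogeny / infinite sites: a mutation's carriers are exactly the
  subtree below its branch (asserted in tests). Clonally independent
  foci are separate origins grafted at the germline root, which
  guarantees zero shared somatic mutations by construction.
* **Read counts.** Depth ~ negative-binomial with mean `depth_mean`
  (default 149, a typical whole-exome median) and size
  `depth_dispersion` (default 12, which keeps the simulated median
  within a few reads of the mean while exercising the depth-≥ 40 filter
  at the lower tail). Alt reads ~ Binomial(depth, θ) with
  θ = purity · CCF / 2 for diploid heterozygous mutations, floored at
  the sequencing error rate (0.001); benign samples use θ = error rate
  exactly. Copy number is fixed diploid: CNAs and WGDs are out of
  scope, which keeps the AF semantics exact and testable.
* **Patients.** Default 3 primary foci + 2 LNM + 1 benign lymph node
  (the matched normal); purity uniform on (0.5, 0.9); each focus is
  independently declared clonally independent with probability
  `fraction_independent_foci` (default 0.13); clone fractions are
  Dirichlet(1) over the tree's clones.
* **Expression.** Negative-binomial counts; baseline log2 means
  N(7, 1.5) across genes, NB size 8 (biological CV ≈ 35%). Gene-set
  members get a log2-mean shift of 0, effect/2 and effect for the NP,
  PTF, LNM stages. Note the mean log-CPM shift realized between NP and
  LNM is slightly below the nominal effect (~0.93 at effect 1 with a
  105/2000 gene set) because shifting set members inflates the library
  size — the usual compositional effect of CPM normalization.
* **Cohort tables.** Per gene, Bernoulli mutation indicators: primaries
  at the baseline rate, metastases at the rate whose odds are scaled by
  the gene's odds ratio (baseline 2%, OR 3 → metastasis rate 5.77%).

One integer seed drives named substreams (tree / reads / expression /
cohort / per-patient), so each generator is independently reproducible
and the end-to-end pipeline is byte-deterministic for a fixed
seed + configuration.

**What passing tests do not show.** The generator draws clean binomial
reads at independent sites: no FFPE deamination artifacts, mapping or
strand bias, germline contamination of the normal, copy-number-driven
AF distortion, or linkage between nearby sites. Filter sensitivity and
relatedness-recovery rates measured on it are therefore upper bounds on
real-data performance, and the independence calls inherit the
simplification that independent foci share literally zero mutations.

## Problem sizes used in tests and the acceptance script

Oracle scans cover all 2×2 tables with margins ≤ 60 (test) or ≤ 40
(script); clonality recovery uses 200 patients × 6 samples at ~149×;
selection calibration uses 300–400 single-clone null patients
(~9–12k variant tests) and ~60 two-clone patients for power; signature
analyses use 100 effect runs + 200 null runs at 30 samples per stage ×
1000 genes; cohort enrichment uses the full 3929 + 2721 arm sizes with
500 genes. These sizes make every Monte-Carlo margin small relative to
the thresholds being checked while the whole suite completes in a few
minutes.

## Known limitations

* The DE stand-in is a t-test on log-CPM; it does not model
  count-level dispersion shrinkage and loses power at small n relative
  to negative-binomial GLM engines.
* Relatedness thresholds are heuristics on presence/absence overlap;
  no formal phylogenetic reconstruction or cancer-cell-fraction
  clustering is attempted.
* The subset-based handling of covariates in expression comparisons
  (filter samples, then test) does not adjust model-based for
  confounders.
* Positions in the simulator are placeholders on a synthetic grid; gene
  assignments cycle through a small synthetic universe and carry no
  genomic annotation.
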