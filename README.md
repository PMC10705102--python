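# clonmet

Clonality, clonal-selection and mutation-enrichment analysis for
multi-region tumor sequencing studies — built for cohorts of multi-focal
prostate cancer with matched lymph-node metastases (LNM), and usable for
any study design with several tumor samples and a matched normal per
patient.

## The problem

Prostate cancer is multifocal: one prostate commonly harbors several
tumor foci, which may descend from one ancestral clone or arise as
independent carcinogenesis events. When the disease spreads to pelvic
lymph nodes, the key questions are which focus seeded the metastasis,
whether foci share a common ancestor at all, and which mutations are
preferentially carried (selected) by the metastatic clones. `clonmet`
implements the downstream analytical chain for whole-exome and RNA-seq
data from such designs:

1. **Somatic significance filter.** For each tumor sample vs the
   patient's matched normal, a variant with alt/ref read counts
   (a, r) in the tumor and (a', r') in the normal is retained iff

   * depth ≥ 40 in both samples,
   * AF difference (a/(a+r)) − (a'/(a'+r')) > 0.05 (strict, signed), and
   * Benjamini–Hochberg q < 0.1 for the two-sided Fisher exact test of
     the 2×2 table [[a, r], [a', r']], adjusted across all
     depth-qualified variants of the sample.

2. **Per-patient clonality.** Allele-fraction matrices (variants ×
   samples, AF back-filled from raw counts, entries below the depth
   threshold kept missing), average-linkage clustering on
   pairwise-complete Euclidean distances, and classification of each
   primary focus as *metastatic-clone* (≥ 5 shared variants and
   Jaccard ≥ 0.2 vs an LNM), *clonally independent* (Jaccard < 0.05 vs
   every other tumor sample) or *non-metastatic-clone*, plus the cohort
   common-ancestor fraction with an exact binomial CI.

3. **Clonal selection.** Per variant, alt/ref counts pooled over all
   LNM vs all primary foci, Fisher exact + BH; a variant is *enriched*
   when q < 0.1 with a positive pooled AF difference.

4. **Expression scores.** log2-CPM normalization, a simple two-group DE
   test (Welch t on log-CPM, BH), monotone stage-trend gene selection
   (normal prostate → primary focus → LNM, both steps significant and
   same sign), and a gene-set signature score: per gene z-scores across
   samples, averaged over the set (e.g. an OXPHOS leading-edge list),
   compared across ordered stages with the Jonckheere–Terpstra test.

5. **Cohort mutation enrichment.** Per-gene Fisher exact tests of
   binary mutation status in metastases vs primary tumors at cohort
   scale (thousands of samples per arm), BH-adjusted, with
   Haldane-corrected odds ratios for display.

A seeded synthetic generator (`clonmet.simulate`) produces clone trees
(perfect phylogeny, truncal + private mutations), multi-focus binomial
read counts at negative-binomial exome depth (mean 149×), stage-shifted
negative-binomial expression matrices, and cohort-scale binary mutation
tables — so the whole pipeline runs and is tested without any patient
data.

## Worked example

Run the packaged demo (simulate → filter → clonality → scores → meta)
on a 6-patient synthetic cohort:

```bash
clonmet run --out demo --seed 7
```

which prints (reformatted):

```
pipeline complete:
  simulate:  n_variant_records=2382, n_samples=36
  filter:    n_retained=1313
  clonality: n_relatedness_calls=30, n_selection_tests=397,
             common_ancestor_fraction=0.833 (95% CI 0.586–0.964)
  scores:    n_trend_up=101, n_trend_down=0, trend_test_p=1.5e-23,
             stage_means NP=-0.94 PTF=0.04 LNM=0.90
  meta:      n_genes_tested=100, n_metastasis_enriched=2
```

Reading the numbers: of the 30 classified tumor samples, the primary
foci not called clonally independent give a cohort common-ancestor
fraction of 0.833 (the generator planted 13% independent foci, so ~0.87
is expected). The signature score rises monotonically across the three
stages (means −0.94 → 0.04 → 0.90; ordered-trend p ≈ 10⁻²³) because
the demo plants a two-fold per-stage expression shift on a 105-gene
set, and 101 of those genes are recovered as consistent upward-trend
genes. The meta stage recovers planted metastasis-enriched genes at
q < 0.05. Every output TSV carries `# clonmet <version> / # seed / #
params` header lines; `manifest.json` records per-stage row counts, and
reruns with the same seed are byte-identical.

Individual stages are available as subcommands (`clonmet filter`,
`clonmet clonality`, `clonmet score`, `clonmet trend`, `clonmet meta`,
`clonmet simulate`) over TSV/VCF/GMT inputs; see `clonmet --help`.

## Layout

```
src/clonmet/
  stats.py          Fisher exact (scalar + margin-grouped batch), BH, Jonckheere–Terpstra
  simulate.py       synthetic clone trees, read counts, expression, cohort tables
  somatic_filter.py depth / AF-difference / FDR significance filter
  clonality.py      AF matrices, clustering, relatedness, selection, ancestor fraction
  expression.py     log-CPM, DE, trend genes, signature z-score, stage trend test
  meta.py           cohort metastasis-vs-primary enrichment
  io.py, cli.py, pipeline.py
docs/methods.md     model assumptions, parameter defaults, numerical choices
```

The packaged `data/oxphos_placeholder.gmt` is a synthetic, non-canonical
OXPHOS symbol list shipped only as an example gene-set input; supply
your own GMT for real analyses.
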