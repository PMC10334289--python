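# dipsig

Epigenomic signature inference for DIP-Seq (MeDIP / hmeDIP) experiments:
sliding-window Monte-Carlo segmentation of methylation-enriched domains,
negative-binomial differential region testing, TSS-window gene annotation
with ranked gene-set selection, exact multi-set intersection statistics
across conditions, and gene-length-bias-corrected category enrichment —
with a synthetic-data generator that plants known differential regions
and signature genes so every stage can be validated against ground truth.

The pipeline is aimed at studies that profile 5mC/5hmC remodeling across
several experimental conditions (e.g. different radiation qualities or
doses applied to brain tissue) and ask which genes are *reproducibly*
associated with differential methylation in all of them — a cross-condition
gene "signature".

## The methods in brief

**Segmentation.** The genome is tiled with windows of width *W* (default
1000 bp) at step *W*/2; each window counts the tags whose start position it
contains. The enrichment threshold is

c\* = min{ c : P_null(count ≥ c) ≤ α },

where P_null pools window counts over *n* Monte-Carlo re-placements of the
tags, uniform per chromosome with tag totals preserved. Enriched windows
(count ≥ c\*) are merged into regions; half-open book-ended intervals merge.

**Differential testing.** Per-sample region counts are normalised with
median-of-ratios size factors. Each region gets a two-sided Wald test on
the difference of normalised group means under NB variance
Var = μ + αμ², with per-row method-of-moments dispersions shrunk 50/50
toward a fitted a₀/μ + a₁ trend. Benjamini–Hochberg and Storey q-values
are both reported.

**Annotation and selection.** A differential region is assigned to the
closest TSS within ±25 kb (a 50 kb window centered on the TSS) of its
midpoint. Gene sets are formed from the top-*n* regions ranked by p-value
(default 1500) passing p < 0.01 and an absolute normalised tag difference
> 10, with duplicate genes removed.

**Intersection statistics.** Two-set overlaps use the one-sided Fisher
exact (hypergeometric tail) test. For m > 2 sets the exact null
distribution of the m-set intersection size is built by convolving
hypergeometric kernels,

P_m(x) = Σ_j P_{m−1}(j) · Hypergeom(x | N, j, n_m),

carried in log space so p-values of the order 10⁻⁷⁰ remain exact. The
signature is the plain intersection of all condition gene sets, reported
with its exact p-value against an explicit gene universe.

**Enrichment.** Category tests correct for gene-length selection bias: a
monotone probability weight function (isotonic regression on length-binned
selection fractions) supplies the odds parameter of a Wallenius noncentral
hypergeometric upper-tail test, which reduces exactly to the central
hypergeometric when weights are uniform.

## Worked example

`examples/` contains one short script per capability. The headline run
(`python examples/05_full_pipeline.py`) simulates five conditions whose
treated samples share 8-fold TSS enrichment domains at 45 planted
signature genes, runs the full pipeline, and prints:

```
proton: 53 selected genes
fe_low: 54 selected genes
fe_high: 54 selected genes
si_low: 54 selected genes
si_high: 54 selected genes

derived signature: 43 genes
exact 5-way intersection: log10 p = -77.3
vs planted truth: sensitivity 0.96, 0 false genes
```

i.e. from raw synthetic tags alone the pipeline recovered 43 of the 45
planted signature genes, admitted no false genes, and the 5-way overlap is
astronomically unlikely under independent random sets (p ≈ 10⁻⁷⁷).

The other examples: `01` segmentation of planted domains, `02`
differential region calling (2 treated vs 2 control), `03` exact
multi-set intersection and Venn membership counts, `04` length-bias-
corrected enrichment.

A thin CLI mirrors the library (`dipsig simulate|segment|diff|annotate|
select|intersect|enrich|rnaseq-count|integrate|run-all`); see
`dipsig --help`.

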