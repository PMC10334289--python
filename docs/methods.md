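# Methods

This note documents the models, parameter choices and numerical decisions
behind `dipsig`, and what the synthetic-data validation does and does not
demonstrate about real data.

## Coordinate and data conventions

All genomic coordinates are 0-based half-open (`[start, end)`, the BED
convention) in every module: a tag whose start equals a region's `end`
is outside it, and book-ended intervals merge. Strand is read from BED6
input and recorded for provenance, but all counting is strand-agnostic —
a DIP tag is unstranded evidence of methylation. A tag contributes by its
start position only; fragment extent is never used. Gene models are a
6-column TSV (gene_id, symbol, chrom, strand, tx_start, tx_end); the TSS
is the 5′ end (tx_start on `+`, tx_end on `−`).

## Segmentation model

Windows of width *W* (default 1000 bp, configurable) tile each chromosome
at step *S* (default *W*/2; half-window overlap captures domains that
straddle window boundaries at twice the cost). The null model re-places
each chromosome's tags uniformly at random, preserving per-chromosome tag
totals so chromosome-to-chromosome depth differences cannot masquerade as
enrichment, and pools window counts over `n_perm` permutations (default
1000). The threshold c\* is the smallest count whose pooled upper-tail
probability is ≤ α (default 0.01); calls use count ≥ c\* inclusively.

Because tags enter windows by a single point, the permuted tags are
exchangeable with real ones and the Monte-Carlo tail converges to the
Binomial(n, W/L) ≈ Poisson(nW/L) closed form; the test suite checks both
the threshold agreement and the realised false-call rate. Window counts
for permutations are computed by binning positions into gcd(W, S) cells
and summing fixed runs with a vectorised cumulative sum, so the null
costs O(n_perm · n_tags) rather than a sort per permutation.

Window-size optimisation evaluates each candidate *W* by the number of
merged enriched regions it yields and returns the maximiser, breaking
ties toward the smaller window (higher resolution at equal yield).

Not modelled: CpG density, mappability, input subtraction, PCR
duplicates. On real libraries these produce structured backgrounds that a
uniform null will partially misattribute to enrichment; segmentation
output on real data should be read with that caveat.

## Differential model

Size factors are DESeq-style median-of-ratios computed over rows with no
zero count; when no such row exists the code falls back to library-size
ratios with a warning. Per-row dispersion is estimated by method of
moments on normalised counts pooled within groups, then shrunk 50/50
toward a trend γ(μ) = a₀/μ + a₁ fitted across rows by non-negative least
squares. The 50/50 weight is exposed (`trend_shrinkage`); at 2 vs 2
samples it keeps the null fraction of p < 0.05 near nominal (≈ 0.06 at
dispersion 0.2 in the test suite). With a single sample in any group the
estimator switches to a pooled (all-samples) moment estimate, which is
deliberately conservative because the group difference then inflates the
variance estimate.

The test statistic is a two-sided Wald z on the difference of normalised
group means with variance (μ_A + αμ_A²)/n_A + (μ_B + αμ_B²)/n_B; at
α = 0 it reduces exactly to a two-sample Poisson Wald test, which the
suite checks against an independently coded oracle. The log2 fold change
uses pseudocount 0.5 so it is finite at zero counts; the absolute tag
difference Δ is computed on normalised means so the Fig-style `Δ > 10`
selection threshold is sequencing-depth invariant. A likelihood-ratio
variant was considered and not used: at these group sizes the Wald form
is standard, and swapping it is a one-line change at the call site.

Multiple testing: BH is the statsmodels step-up. Storey's π₀ is
estimated from π₀(λ) = #{p > λ}/((1−λ)n) on a λ grid (0.05…0.95),
smoothed by a precision-weighted average over the upper half of the grid
with weights ∝ 1−λ (the inverse of Var[π₀(λ)]); boundary evaluation of a
fitted cubic was measurably noisier at n = 10⁴ (sd ≈ 0.03 vs ≈ 0.01 on
an 80/20 mixture benchmark). A degenerate grid falls back to the
single-point λ = 0.5 estimate. π₀ is clipped to (0, 1], so Storey q ≤ BH
q always, with equality at π₀ = 1.

## Annotation and selection

Region-to-gene distance is measured from the region midpoint — symmetric
and stable under merging, unlike nearest-edge distance. The default
half-window is 25 kb, reading a "50 kb window centered on the TSS" as
±25 kb; a ±50 kb mode is one parameter away. Each region maps to at most
one gene (closest TSS; exact ties break to the lexicographically smaller
gene id so results are order-invariant); regions with no eligible gene
are dropped. `select_top` applies the rank/threshold rule — direction,
p < p_cut, Δ > min_abs_tagdiff, ascending-p rank, truncate to n_top
*regions* — and only then deduplicates genes, because the selection
quota counts regions, not genes. Presets n_top = 1500 and 3000 are both
meaningful; neither is hard-coded.

Metagene matrices bin tag density (tags/bp) over a fixed upstream flank,
a scaled gene body, and a downstream flank, orient rows 5′→3′, divide by
the median of positive entries, cap at the 80% quantile of the matrix,
and sort rows by descending expression. Genes shorter than the bin count
are handled by fractional (float-edge) binning.

## Intersection statistics

The universe is an explicit argument everywhere; the pipeline default is
every gene in the gene table. One-sided enrichment (upper tail) is the
default; the observed-size expectation is N·∏(nᵢ/N). The m-set exact
test convolves hypergeometric kernels over the running intersection size
in log space (`logsumexp`), so intersections whose p-value underflows
double precision still report an exact log₁₀ p; the suite verifies the
distribution sums to 1, the two-set reduction to Fisher at 10⁻¹² relative
error, and agreement with a 10⁵-draw Monte-Carlo oracle for m = 3…5.
Complexity is O(m·max(nᵢ)²) hypergeometric terms — negligible for gene
sets of a few thousand.

## Length-bias-corrected enrichment

The probability weight function bins genes into 20 length quantiles,
takes per-bin selection fractions, applies isotonic regression
(monotone non-decreasing, occupancy-weighted) and interpolates between
bin median lengths; weights are clipped to [10⁻⁴, 1−10⁻⁴]. Isotonic
regression is used instead of a spline because monotonicity is the
property the correction requires and it introduces no smoothing
parameter. The category test is the Wallenius noncentral hypergeometric
upper tail with odds = mean weight inside the category / mean weight
outside — the standard two-group approximation; the exact multivariate
Wallenius computation is out of scope. Uniform weights give odds exactly
1 and the code then uses the central hypergeometric directly, making the
reduction exact rather than approximate. KEGG-style collections are just
another GMT input to the same test.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the analysis assumes:
uniform background tag placement at a fixed total depth, rectangular
enrichment domains whose interior density is fold × background
(overlapping domains multiply), fixed 36 bp tags (read length is not
modelled from data; configurable), two-group condition designs where
treated samples carry domains and controls do not, multi-condition
designs in which every condition's treated samples share domains at the
TSS of a common signature gene set (default width 2 kb, centered on the
TSS so planted truth is always annotatable within ±25 kb), and
NB-distributed RNA-Seq counts (gamma-Poisson, Var = μ + αμ²; α = 0 is
Poisson). Default replication is 2 samples per group so the NB test has
within-group information; a 1-vs-1 mode mimics pooled-library designs.

Validation scale: the simulated studies use 1–3 Mb genomes with ~60–120
genes, 15k–150k tags per sample, 8-fold signature domains and 4-fold
recovery domains. These sizes make every planted effect comfortably
detectable and every run fast; passing them demonstrates the pipeline's
logic and calibration, *not* performance on genome-scale data with
sequence-driven background structure, nor power at marginal effect
sizes. Tag depth per unit genome (50k/Mb in the recovery experiments) is
the scale-relevant quantity, chosen to be of the same order as a
deep-coverage DIP library on a mammalian genome.

## Pipeline determinism and auditability

One master seed drives everything; per-stage seeds derive from
CRC32(master:stage:sample) mod 2³¹, so adding a sample never reshuffles
another's draws and reruns are bit-identical. Every stage writes its
intermediate (per-sample region BEDs, per-condition differential tables,
gene sets, the JSON report); `resume` reuses cached segmentations. The
report records all parameters, the universe size and the provenance of
every gene set, because overlap p-values are meaningless without their
background universe.

## Known limitations

- Uniform-background null: no CpG/mappability structure (see above).
- One gene per region; enhancer/intergenic regions outside the TSS
  window are dropped, not classified.
- NB test covers two-group designs only — no covariates, pairing, or
  shrunken-LFC estimation.
- Exonic structure is ignored for RNA counting (gene body = transcript
  span), consistent with the simulator, which plants no exons.
- The Wallenius odds uses the two-group mean-weight approximation, not
  per-gene weights.
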