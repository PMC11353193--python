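# Methods

This note documents the models, parameter choices and numerical details
behind `ilsdeconv`, and what the synthetic-data validation does and does
not establish about real data.

## The problem

An introgression line (IL) carries one homozygous chromosomal segment of
a wild relative (*S. pennellii*, "genome B") in a cultivated background
(*S. lycopersicum*, "genome A"). RNA-seq reads from IL tissue must be
attributed to a parental genome before expression can be quantified and
compared across conditions — here, roots of control vs.
broomrape-parasitized plants, three biological replicates each, for a
susceptible cultivar and two ILs. The pipeline's job is species-of-origin
deconvolution followed by standard count-based differential expression,
pathway over-representation, and qPCR validation.

## Species-of-origin partitioning

Each fragment's candidate alignments against the combined two-genome
reference form a bundle. Let bestA and bestB be the maximum alignment
score (`AS` tag) over the bundle's genome-A and genome-B records. The
fragment is labelled

* `SLYC` if it has records only in A, or records in both with bestA > bestB;
* `PENN` symmetrically for B;
* `AMBI` if records exist in both genomes with bestA = bestB.

The three labels are exhaustive and mutually exclusive; comparisons are
on integer scores, so no epsilon logic is involved. Retained records are
the genome-A records for `SLYC` and the genome-B records for both `PENN`
and `AMBI` — ambiguous fragments are carried on the wild-genome side.
Design choices where the convention is genuinely open:

* secondary alignments participate in bundles; supplementary/chimeric
  records are dropped and counted;
* a missing `NH` tag is tolerated (recomputed from bundle size); a
  missing `AS` is fatal, since it is the decision variable;
* ties *within* one genome do not affect the label — all retained
  records pass to the EM quantifier;
* paired-end mates are treated as one fragment whose score is the pair
  score where the aligner reports one (else the mate sum). The synthetic
  generator emits single-end fragments; the partition logic is identical
  either way.

## EM quantification

Retained alignments are intersected with gene intervals (non-overlapping
single-exon models; fragments hitting no gene are tallied as
unassigned). Gene abundances θ start uniform over genes with ≥ 1
candidate fragment; the E-step sets w(f,g) ∝ θ_g over f's candidates,
the M-step θ_g ∝ Σ_f w(f,g), iterating until max|Δθ| < 1e-8 or 200
iterations. The observed-data log-likelihood is asserted non-decreasing
at every step. Expected counts Σ_f w(f,g) are **not** rounded; fragment
totals are conserved to < 1e-6. Ambiguous-subset counts are summed into
the wild-genome matrices by default (`ambi_policy="sum"`); a
`"separate"` policy keeps them apart. No effective-length correction is
applied to counts (the DE stage consumes counts, not TPM).

## Differential expression

Each contrast is a two-group comparison (control vs. parasitized, n = 3
per group) of one count matrix; each IL is analysed twice, once per
parental gene-model set, giving five contrasts in the default study.

**Filtering.** Keep a gene iff CPM ≥ C in ≥ m samples and total count
≥ 15, with m the smallest group size and C = 10 / (median library size
in millions).

**TMM.** Reference sample: 75th-percentile CPM closest to the mean 75th
percentile. Per sample vs. reference, over genes positive in both:
M = log2((y/N)/(y_r/N_r)), A = ½ log2(y y_r/(N N_r)); drop the top and
bottom 30% of M and 5% of A; factor = 2^(Σ wM / Σ w) with inverse
asymptotic binomial variance weights w = (1/y − 1/N + 1/y_r − 1/N_r)⁻¹;
factors rescaled to geometric mean 1. Exact scaling of a whole library
is absorbed by the library size (unit factors); scaling one library
changes the precision weights slightly, so factor invariance under such
scaling is near-exact (≈ 2%), not exact — an inherent property of the
weighted estimator.

**Dispersion.** The NB log-likelihood uses the continuous (gamma
function) form, so EM expected counts need no rounding; φ ≤ 1e-10 falls
back to the Poisson likelihood. The common dispersion maximises the
summed Cox–Reid adjusted profile likelihood (APL; the adjustment is
−½ log det XᵀWX, block-diagonal for one-factor designs) over a 41-point
grid on log φ ∈ [log 1e-4, log 10] with quadratic refinement. Per-gene
dispersions maximise APL_g(φ) + (d_prior/df_res)·mean_g' APL_g'(φ) with
d_prior = 10 prior degrees of freedom — a weighted-likelihood shrinkage
toward the common maximiser. Fitted means come from per-block Fisher
scoring (clipped steps, 1e-10 tolerance); all-zero groups get μ = 0.

**Quasi-likelihood F-test.** Null (intercept) and full (group) NB models
are fitted with log effective-library-size offsets and the shrunk
dispersions. The raw quasi-dispersion s²_g = residual deviance / df_res
is squeezed across genes by matching the moments of log s² to a scaled
F-distribution (digamma/trigamma matching; the trigamma inverse is a
Newton iteration). A degenerate s² spread yields d0 = ∞ (all s² set to
the common value) with a warning. Then F_g = (dev_null − dev_full)/s̃²_g
is referred to F(1, d0 + df_res). log2FC is the offset-adjusted fitted
group-rate ratio; significance is FDR < 0.05 after Benjamini–Hochberg
step-up adjustment (NaN p-values propagate and do not count toward m).
The |log2FC| > 0.6 rule is a volcano-display threshold only, never a
significance filter.

Calibration is enforced empirically, not by matching another tool
bit-for-bit: on null NB simulations (2000 genes, 3v3, φ = 0.1) the raw
p-value distribution is near-uniform (≈ 5.0% below 0.05, KS ≈ 0.02), and
with 10% planted |log2FC| = 2 the test attains ≈ 0.96 sensitivity at
≈ 0.05 empirical FDR over 20 replicate simulations.

## Pathway enrichment

One-sided hypergeometric upper-tail tests (over-representation only, no
gene weighting): p = P(X ≥ k) with X ~ Hypergeom(N, K, n), where the
universe N is the *annotated* gene set — mirroring resources in which
only ~35% of genes carry pathway annotations — k the annotated DE genes
in the pathway, K the pathway size, n the annotated DE total. DE input
is the FDR < 0.05 set, both directions pooled. Two modes:

* **separate** — independent universes and BH corrections per species;
* **merged** — per pathway, both species' member lists are concatenated
  *without* cross-species deduplication (homology links between the two
  annotation namespaces are unavailable in real data, so a gene DE in
  both species contributes twice); the universe likewise concatenates
  and may double-count, which is recorded in the output metadata. A
  `dedup_by_stem` option collapses homolog pairs on synthetic data where
  the link is known (off by default).

Significant pathways (adjusted p < 0.05) are summarised as pairwise Venn
counts across annotation sets and top-20 tables ordered by adjusted p
(ties: raw p, then pathway id).

## qPCR (2^−ΔΔCt)

Technical triplicates are averaged per biological replicate (SD > 0.5
cycles flagged; < 3 replicates flagged, ≥ 1 required; samples missing a
reference-gene Ct are excluded with a warning). Per replicate,
ΔCt = Ct(target) − Ct(reference); ΔΔCt is the difference of condition
means (no per-replicate pairing — the design has none), and
fold = 2^−ΔΔCt. Significance uses Welch's two-sided t-test on the two
ΔCt replicate sets at α = 0.05 — chosen for robustness to unequal
variances at n = 3 — with an exact/Monte-Carlo permutation test behind a
flag. Amplification-efficiency correction (Pfaffl) is out of scope. The
construction is invariant to any global Ct shift, and the reference gene
tested against itself gives fold = 1 identically.

## Synthetic-data generator

The generator emulates the study's data structure, not its biology:

* **Genomes** — per-gene contigs (default 500 gene pairs, 1000 bp bodies,
  100 bp flanks), genome B derived from A by iid point substitutions at
  rate 0.02 (typical congeneric coding divergence; valid range [0, 0.25]).
* **Genotypes** — the cultivar carries no introgression; each IL carries
  one contiguous interval of ~10% of genes with B alleles, mirroring
  single-segment ILs.
* **Counts** — NB with lognormal baselines, dispersion φ = 0.1, expected
  library size 20,000 fragments/sample (a desk-scale stand-in for
  multi-million-read libraries; DE calibration simulations use 200
  expected counts/gene, matching realistic per-gene depth). Planted
  effects (default 10% of genes at |log2FC| = 2, balanced signs) are
  split symmetrically across conditions so the condition ratio is exactly
  2^±L while both conditions keep the same expected library size.
* **Fragments** — 150 nt single-end, uniform starts within the gene
  body, substitution errors at 0.001/base; alignment scores against each
  genome are matches − 2·mismatches (penalty configurable); candidate
  records for both genomes (plus optional equal-score paralog records at
  a configurable fraction, default 0) carry `NH`/`AS`. Fragment counts
  per sample equal the rounded true-count column sums.
* **Annotation** — ~35% of genes annotated, 20 pathways shared by name
  across species; two pathways draw 70% of their members from planted-DE
  genes so the enrichment stage has true positives to find.
* **Ct tables** — Ct = 30 − log2(expression) + N(0, σ), σ = 0.2 cycles,
  three technical replicates, zero-expression wells capped at 40 and
  flagged.

Identical config + seed reproduces byte-identical FASTA/GTF/SAM/TSV
outputs (per-sample RNG streams are derived from the seed and a stable
string hash of the sample name).

**Not modelled** (hence not validated by passing tests): indels and
structural variation, splice junctions, GC/positional bias, quality
scores, isoform-level expression, batch effects, and real KEGG topology.
Origin-recovery results in particular assume divergence is the *only*
systematic difference between the genomes; real paralogy and reference
bias will inflate the ambiguous fraction beyond what the simulation
shows.

## Numerical choices and degenerate inputs

* Integer `AS` comparisons; no floating-point tie logic in partitioning.
* EM equivalence classes (fragments with identical candidate sets are
  pooled) for speed; singleton classes reproduce integer counts exactly.
* Heatmap rows with zero variance z-score to zeros; heatmap ranking is
  ascending FDR with (raw p, gene id) tie-breaks for determinism; column
  order is controls first.
* All-gene filtering, empty bundles, missing matrices, mismatched gene
  universes, zero-expression reference genes and impossible
  hypergeometric overlaps raise typed errors naming the offender.
* Report tables are byte-deterministic given identical inputs; no RNG
  after the generator.

## Known limitations

* The QL machinery supports one-factor (two-group) designs only; no
  batch covariates or multi-factor contrasts.
* Dispersion shrinkage uses a global (infinite-span) consensus rather
  than an abundance-trended prior; with strongly mean-dependent
  dispersion a trended version would be preferable.
* The merged enrichment mode inherits the double-counting caveat by
  construction; its p-values are not strictly exchangeable with the
  separate mode's.
* Welch's t at n = 3 has limited power; the permutation alternative has
  a granularity floor of 1/C(6,3) = 0.05 for two-sided tests at
  triplicate depth.
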