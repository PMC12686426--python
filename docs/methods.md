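# Methods

This note documents the statistical models, the conventions chosen where the
procedure leaves room, and what the synthetic-data tests do and do not
establish.

## Background-noise model (ZIBB)

Per variant, the alt-read count X of a cell with coverage n is modeled under
the null (no true heteroplasmy) as a zero-inflated beta-binomial,

    P(X = x | n) = π·1{x = 0} + (1 − π)·BetaBin(x; n, μ, ρ),

parameterized by the mixture weight π ∈ [0,1], the beta-binomial mean
μ ∈ (0,1) and overdispersion ρ ∈ (0,1) with α = μ(1−ρ)/ρ and
β = (1−μ)(1−ρ)/ρ. The point mass sits at x = 0 only — the simplest model
consistent with zero inflation; low counts are left to the beta-binomial
component. Parameters are fitted by maximum likelihood on *reference cells*
(non-epithelial populations assumed free of the somatic variant) with
coverage > 0, by bounded L-BFGS-B from five deterministic starting points
(π ∈ {0.3, 0.5, 0.7, 0.9, 0.99}, μ from a method-of-moments start); ties are
resolved by log-likelihood, then by the lower π. Fewer than 50 informative
reference cells is an error; an all-zero variant returns π at its upper
bound, flagged degenerate.

**Identifiability.** At shallow coverage the point mass and the
beta-binomial's own zero probability are confounded: at coverage ≈ 20 and
μ = 0.01, BetaBin puts ~87% of its mass at zero, and the profile likelihood
in π is nearly flat over [0.5, 0.9]. With 5,000 reference cells the MLE of π
has a seed-to-seed SD of roughly 0.1–0.3, occasionally collapsing to the
π → 0 boundary. This barely affects the *tail test* (the quantity that
matters downstream is P(X ≥ x), which is stable along the ridge), but point
estimates of π at low coverage should not be over-interpreted.

**Per-cell test.** p = P(X ≥ x) under the fitted mixture; p = 1 whenever
x = 0. The default tail uses the beta-binomial component (`tail_model=
"zibb"`); `"zib"` substitutes a plain binomial tail with success probability
μ for the same fitted zero split.

## Empirical, coverage-stratified FDR

Reference-cell p-values provide the null. Test (epithelial) cells are binned
by quantiles of their coverage (default 4 bins; bins holding fewer than 20
null cells are merged with a neighbor), because attainable p-values depend
strongly on coverage. Within a bin, for each observed test p-value t,

    FDR(t) = [ (#null p ≤ t) / N_null · N_test ] / max(1, #test p ≤ t),

and a cell's q-value is the minimum FDR over thresholds at or above its own
p (step-up), clipped to [0,1]. A cell is significant at q ≤ 0.05. A variant
is *reported* when s − ⌈0.05·s⌉ ≥ 3 where s is its number of significant
cells — the expected false positives at the FDR level are deducted before
the three-cell rule; this accounting is echoed into the provenance file.

## Variant threshold filter

Strict inequalities throughout: mean coverage > 5 (over all assayed cells),
mean base quality > 27 (over covered cells; quality is NaN — never 0 — when
coverage is 0), and AF > 0.25 in more than 1% of epithelial cells, where the
denominator is epithelial cells with coverage > 0 at the variant (AF is
undefined otherwise; this convention is recorded in output metadata).
Variants selected in two or more patients are removed everywhere. Variants
with AF > 0.9 in ≥ 90% of covered cells are flagged homoplasmic (germline)
and excluded from somatic clone calling rather than silently dropped.

## Clone clustering

Cells × significant-variants AF matrix (0 with a missing-flag where coverage
is 0; features unscaled — cosine distance is invariant to per-cell scaling).
k = 10 cosine nearest neighbors (self included), shared-nearest-neighbor
Jaccard weights pruned below 1/15, Leiden optimization of
Reichardt–Bornholdt configuration-null modularity at a resolution parameter,
seeded and therefore deterministic. Cells whose profile is all zero carry no
lineage information and receive the sentinel label −1 instead of being
imputed into a clone.

**Resolution is graph-scale dependent.** A dense community of size n resists
splitting only while the total graph weight 2m exceeds roughly
γ(n−1)²·w (γ the resolution, w the typical internal edge weight). The
published resolution of 3.0 presumes biopsy-scale graphs with many clusters;
on a small two-cluster graph any γ ≥ 2n/(n−1) ≈ 2 shatters the clusters
(eventually to singletons). The desk-scale demo therefore runs at resolution
1.0, documented in its provenance; the pipeline default remains 3.0.

## Clone phylogeny and support calibration

Neighbor joining (classic Saitou–Nei Q-criterion) on cosine distances
between per-cluster mean AF profiles; negative branch lengths are clamped to
zero with the raw value kept as node metadata. Bootstrap: cells are
resampled with replacement *within* each cluster (sizes preserved),
centroids, distances and the tree recomputed; the support of each base-tree
bipartition is the fraction of replicates containing it, with a bipartition
and its complement identified. Trivial (single-leaf) bipartitions have
support 1 by convention and are excluded from null maxima.

Centroid trees can show high support by chance — random cell groupings have
accidentally distinct centroids that persist across bootstrap replicates —
so supports are calibrated: 100 permutations reassign cells between clusters
(sizes preserved), each permutation undergoes the full bootstrap analysis
(depth independently configurable; desk-scale default 200), and the 95th
percentile of the per-permutation maximum supports is the significance
threshold. An edge is flagged only if its own support and its parent edge's
support both strictly exceed the threshold. "Parent" requires a root: the
default policy is midpoint rooting (an outgroup policy is available); edges
whose parent is the root, or whose parent edge is a trivial split, satisfy
the parent condition vacuously and are flagged as such.

## Nuclear SNV concordance

Records with fewer than 3 informative reads are dropped, then SNVs expressed
(alt > 0) in fewer than 4 remaining cells. The control group is restricted
to non-clone cells from the (sample, cell-type) strata present in the clone.
Per SNV, Otsu's threshold on the VAF distribution — fixed 256-bin histogram
on [0,1], the image-processing convention; an exact sorted-cut variant is
available — splits cells at vaf > t; cells with zero informative reads at an
SNV are excluded from its 2×2 table (VAF undefined), not counted low.
Fisher's exact test is two-sided by point-probability summation; a zero
margin yields p = 1. BH adjustment runs across SNVs. The permutation null
reshuffles clone/control labels within each (sample, cell-type) stratum,
preserving per-stratum group sizes, and reruns Otsu + Fisher per iteration;
reported per SNV is the fraction of null p-values at or below the observed.

## Clonal differential expression

Expression is library-size normalized to 10,000 per cell; log2FC is
log2(mean₁+1) − log2(mean₂+1) on normalized means (pseudocount 1; the
convention is recorded in output metadata). Genes are tested only if
detected in ≥ min.pct of either group (0.1 single-pass, 0.25 bootstrap) and
|log2FC| > 0.25 (positive only in the bootstrap); rank-sum p-values use the
normal approximation with tie and continuity correction, switching to the
exact null for groups of ≤ 8 tie-free values; BH runs within each
iteration over that iteration's tested genes. The bootstrap subsamples the
larger group *without replacement* to the smaller group's size (a
with-replacement flag exists) and recomputes normalization on the subsample.
Aggregation over iterations: mean log2FC over all iterations, mean adjusted
p with untested iterations counted as 1, significance frequency out of all
iterations. Robust = frequency ≥ 0.5 and |mean log2FC| > 0.25. Top-overlap
selection intersects the significant genes of the tissue-level and clonal
analyses and ranks by the clonal mean adjusted p (ties: |mean log2FC|
descending, then gene id).

**Power at desk scale.** With a 30-cell clone, each iteration's tested set
contains tens of null genes passing the |log2FC| filter by chance, which
inflates the BH adjustment several-fold; genes whose raw rank-sum p sits
near 0.005–0.02 then hover at adjusted p ≈ 0.05 and fail the 50%-frequency
robustness bar. Measured sensitivity for planted |log2FC| ∈ [1, 2] effects
at 30 vs 500 cells is ~60–70% (specificity ≥ 99%); treat "robust" as a
high-precision, moderate-recall call at this group size.

## Synthetic data: what it emulates, and what not

Clone cells draw alt counts from BetaBin(n, mean_AF, ρ) at their carried
variants; all other (cell, variant) pairs — and reference cells everywhere —
draw from the ZIBB background (defaults π₀ = 0.7, μ₀ = 0.005, ρ₀ = 0.05;
plausible contamination levels, not measurements). Coverage is negative
binomial per (cell, variant) (mean 20, size 5) so the coverage-stratified
FDR has real variation to stratify. Clones may span tissues (crossing
lineages) and be biased across biopsies. Nuclear SNVs are carried by clone
cells with a dropout rate (carriers with reads always show ≥ 1 alt read);
decoy SNVs scatter alt reads independently of clones. Expression is
negative binomial (size 2) with log-normal gene means (~2–6 counts/cell),
log-normal cell size factors, and planted clone-specific fold changes.

Not emulated: doublets, ambient-RNA expression contamination, cell-type
expression programs, mtDNA copy-number variation between cell types,
heteroplasmy drift within clones, or index-hopping artifacts. A green test
therefore establishes that the *statistical machinery* behaves as specified
under its own model assumptions — not that those assumptions exhaust real
tissue data.

## Numerical and reproducibility choices

One global seed fans out to named per-stage substreams (CRC-derived
SeedSequence), so stages are individually reproducible and reruns are
byte-identical. Optimizer bounds keep (π, μ, ρ) in (10⁻⁶, 1−10⁻⁶);
beta-binomial likelihoods come from `scipy.stats.betabinom`. Bootstrap
replicates in which a resampled centroid loses all signal are skipped (they
cannot support any split). Leiden uses 2 iterations with a fixed seed;
cluster labels are renumbered by size then first occurrence. Modularity ties
and neighbor ties at equal distance are broken deterministically by index.
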