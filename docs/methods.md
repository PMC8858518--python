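# Methods

## Model and procedure

`csdnet` compares the co-expression structure of two sample groups.  For a
gene pair with Spearman correlations ρ₁, ρ₂ in the two conditions and
bootstrap variances σ₁², σ₂² of those correlations, the scores

- C = |ρ₁ + ρ₂| / √(σ₁² + σ₂²),
- S = ||ρ₁| − |ρ₂|| / √(σ₁² + σ₂²),
- D = (|ρ₁| + |ρ₂| − |ρ₁ + ρ₂|) / √(σ₁² + σ₂²)

measure conserved, condition-specific and sign-flipped co-expression on a
common variance-normalized scale.  All three are non-negative and satisfy
the triangle identity C + D = (|ρ₁| + |ρ₂|) / √(σ₁² + σ₂²): when ρ₁ and ρ₂
share a sign D is exactly zero, and when they have opposite signs C = S.
The scores are signal-to-noise ratios, not calibrated test statistics; the
method ranks pairs, it does not assign p-values.

Spearman correlation is used because expression measures are only assumed
monotone in the underlying signal; it is computed as the Pearson
correlation of the within-gene observational ranks (average ranks at ties).
Ranking each gene once and correlating the whole rank matrix with a single
standardized matrix product replaces per-pair correlation loops and is the
dominant cost of the pipeline.

## Bootstrap estimation

σ₁² and σ₂² are estimated by bootstrapping: each replicate draws
`n_samples` sample indices with replacement (every replicate as large as
the original sample) and correlates the resampled rank matrix.  Replicates
stream through a Welford mean/variance accumulator applied element-wise to
the correlation matrix, which is numerically stable and needs no replicate
history.  The reported ρ₁, ρ₂ are the bootstrap means; passing
`use_full_sample_rho=True` substitutes the full-sample correlations while
keeping the bootstrap variances, for users who prefer the point estimate.

By default the ranks are computed once on the full sample and replicates
resample rows of that precomputed rank matrix.  Duplicated samples in a
replicate would, strictly speaking, create ties that re-ranking would
average; `rerank=True` enables that slower exact behaviour.  The two agree
to well within bootstrap noise on continuous data (covered by a test), and
the precomputed-rank path is the default because it turns the inner loop
into pure row indexing plus one matrix product.

The variance requires at least 2 iterations; the default is 1000, which
keeps the Monte-Carlo error of the mean near σ/30 and gives stable top-edge
rankings (see the overlap experiment below).  All draws come from
`numpy.random.default_rng(seed)`; the seed is recorded in the result, and
condition 2 of a pipeline run uses `seed + 1` so the two replicate streams
are distinct but fully determined.  Results are bit-identical for a fixed
`(data, n_iterations, seed)` triple regardless of thread count, because
RNG streams are tied to seeds, never to scheduling.

## Degenerate inputs

- Missing or non-numeric values abort with the offending gene and sample
  named; imputation is deliberately out of scope.
- A gene with constant expression (in the full sample or within a
  replicate) has no defined correlation; its pairs are marked NaN, a
  warning lists the genes, and such pairs are excluded from scoring and
  selection.  Silently emitting 0 would fabricate signal.
- A pair with zero pooled variance — e.g. a gene duplicated under two
  names, correlating deterministically in every replicate — would receive
  an infinite score and dominate every network.  Such pairs are unscored.
  "Zero" is judged against a floor of 1e-24 because replicate correlations
  of deterministically related columns differ by round-off (~n·ε, variance
  ~1e-26), while genuine bootstrap variances of correlations are many
  orders of magnitude larger.
- Correlation matrices are clipped to [−1, 1] to absorb round-off; the
  D numerator keeps an outer absolute value for the same reason even
  though it is non-negative analytically.

## Edge selection

The per-type edge count is either explicit (`n_edges`) or derived from an
importance level `p` as `floor(p · n_genes(n_genes−1)/2)` with a minimum of
one edge (on 20,645 genes, `p = 10⁻⁶` gives 213 of the 213,097,690 pairs).
Selection partitions the score array around the k-th largest value
(`numpy.argpartition`) and sorts only the candidate top, yielding exactly
the same result as a full descending sort truncated at k.  Ties at the
boundary are broken by `(gene_a, gene_b)` lexicographic order so output is
reproducible across runs and thread counts.  The three type selections are
independent: a pair may appear in more than one network, and the combined
`*_CSD.tsv` file keeps one row per (pair, link type).

## Synthetic data generator

The generator emulates exactly the statistical structure the scores probe.
Background genes are independent standard normals.  A planted pair is drawn
from a bivariate normal whose Pearson parameter is set through
ρ_P = 2·sin(π·ρ_S/6), the bivariate-normal relation between Pearson and
Spearman correlation, so the population Spearman equals the requested
target exactly — the reason a Gaussian copula was chosen over, say,
resampling real data.  Targets (t, t) plant conserved pairs, (t, 0)
specific pairs, (t, −t) differentiated pairs.  Independent Gaussian noise
with standard deviation `noise_sd` (default 0.1, latent signals have unit
variance) attenuates planted correlations by the factor 1/(1 + noise_sd²),
about 1% at the default.

What the generator does *not* emulate: count overdispersion, library-size
and batch effects, heavy-tailed expression, correlated background modules.
Tests passing on this generator therefore demonstrate that the estimator
and ranking machinery recover known population structure; they do not
certify behaviour on raw RNA-seq counts, which must be normalized before
use as with any correlation-based method.

Default study conditions used by the recovery tests: 200 genes, 150 + 120
samples, 1000 bootstrap iterations, planted targets at magnitude 0.9
against an uncorrelated background — sizes at which a correlation of 0.9
stands ~10 null standard deviations (1/√(n−1) ≈ 0.08) above background, so
recovery failures indicate implementation defects rather than sampling bad
luck.

## Seed-robustness experiment

`seed_overlap_experiment` quantifies how reproducible the top-ranked edges
are: one dataset, `n_parallels` pipeline runs differing only in bootstrap
seed, and for each rank cutoff r the fraction of the top-r pairs shared by
every parallel.  The bundled desk-scale benchmark
(`overlap_benchmark_spec`) plants 20 pairs of each type with strengths
tapered from 0.3 to 0.85 among 200 genes so that planted pairs straddle
any cutoff and the overlap is informative rather than saturating at 1.
With 10 parallels at 1000 iterations the band-averaged overlap orders
C > D > S: specific pairs depend on a near-zero correlation in one
condition whose rank is most easily perturbed by resampling noise, while
conserved pairs pool signal from both conditions and are most stable.

## Numerical and design choices

- Welford variance uses the n−1 (sample) normalizer.
- Gene alignment across conditions is the sorted intersection of labels;
  fewer than 2 shared genes is an error.
- `threads` parallelizes across the two conditions only; the correlation
  products inside one condition are left to the BLAS.  Scaling saturates
  quickly because the rank-matrix product is memory-bandwidth bound.
- Timing tests and the heavier recovery tests run at a few hundred genes
  and a few hundred iterations — sizes chosen so every published invariant
  is exercised while the whole suite stays interactive.

## Known limitations

- Two conditions only; multi-way comparisons are out of scope.
- Scores are uncalibrated ranks; no null model or FDR is provided.
- The full correlation matrices are held in memory (O(n_genes²) doubles),
  so genome-scale inputs need tens of GB; out-of-core computation is not
  implemented.
- The legacy fixed-size disjoint-subsample resampling scheme of earlier
  differential co-expression tools is intentionally not supported;
  bootstrapping supersedes it.
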