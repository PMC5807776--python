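# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions needed to reproduce every
number the package prints.

## Count model and normalization

Gene-level read-pair (fragment) counts are modeled as negative binomial
with variance m + φm², where φ is the gene-wise dispersion. Counts are
never halved or rescaled on input.

- **CPM** = count / (library size × factor) × 10⁶. The detection rule —
  *strictly more than* 1 CPM in at least 6 samples, evaluated per station —
  uses raw library sizes (no normalization factors) by default; a flag
  enables factor-adjusted CPM. The strict inequality matters only for
  counts sitting exactly at 1 CPM but is part of the contract.
- **TMM factors**: the reference sample is the one whose 75th count
  percentile (as a fraction of library size) is closest to the mean of
  those percentiles. Per-gene log2 ratios to the reference (M) are doubly
  trimmed — 30% of the M distribution and 5% of the A distribution from
  each tail — and averaged with inverse binomial-variance weights
  (N_k − y_k)/(N_k y_k) + (N_r − y_r)/(N_r y_r). Factors are re-centred to
  geometric mean 1. Genes zero in either column are excluded from that
  pairwise comparison. Numerical parity with any particular
  implementation of trimmed-mean normalization is not a goal; the unit
  tests pin this implementation against a brute-force reimplementation.
- **FPKM** = count / (length/10³) / (effective library/10⁶), with the
  effective library = library size × TMM factor when factors are given.

## Differential expression

Two engines are deliberately different in mechanics so their consensus is
meaningful.

**Exact conditional test.** Counts are scaled to the geometric-mean
effective library ("pseudo-counts") and rounded group sums are tested
conditionally on each gene's total. If S₁ + S₂ = t and the groups have n₁
and n₂ samples, the null conditional law of S₁ has weights a₁ = n₁/φ,
a₂ = n₂/φ (the NB convolution identity; exactly Binomial(t, n₁/(n₁+n₂))
in the Poisson limit φ → 0, which the unit tests enumerate). The
two-sided p-value follows the minimum-likelihood rule: the total
probability of outcomes no more likely than the observed one, ties
included within a 10⁻⁹ log-scale tolerance that absorbs float noise in
`gammaln` (mirror outcomes of a symmetric law are mathematically equal
but differ in the last bits). Fold changes are log₂ of the pseudo-count
group means with a prior count of 0.125 per sample so zero-count groups
stay finite.

**Wald test.** The two-group NB log-link model y ~ NB(s_j λ_g, φ) is fit
by Newton scoring per group (equivalent to IRLS for this saturated
design; step tolerance 10⁻⁸, 100 iterations max, non-convergence and
boundary cases flagged and excluded from the consensus). Size factors are
median-of-ratios against the geometric-mean reference over genes with no
zeros. The Wald statistic (log λ₂ − log λ₁)/SE uses observed Fisher
information and is referred to the standard normal. A t reference with
n − 2 degrees of freedom is available, but on null NB simulations
(20 × 2000 genes, 6v6) the normal reference rejects at ~1.4% for nominal
p ≤ 0.01 while the t(10) reference rejects at ~0.4%: with plug-in
shrunken dispersions the t correction over-corrects, so normal is the
default.

**Dispersions.** Three estimators: per-gene method of moments (pooled
across groups, using Var(y/s) = μ·mean(1/s) + φμ²; exactly 0 for a
constant gene), a common value maximizing the Cox–Reid-adjusted profile
likelihood, and the default tagwise shrinkage — moment estimates blended
toward the common value with a prior weight of 10 degrees of freedom
against the residual degrees of freedom. The Cox–Reid term matters: plain
profile likelihood underestimates φ by roughly a factor (n − 2)/n.

**Consensus and orientation.** A gene is a DEG iff both p-values are
≤ α = 0.01 (nominal, as the discovery rule; NaN never passes). Reported
fold changes come from the exact engine and are oriented
log₂(second group / first group) with the AI-pregnant group first.

**Empirical FDR.** Labels are permuted uniformly with group sizes
preserved (permutation happens within a station, because stations are
analyzed independently); if fewer distinct assignments exist than
requested permutations, sampling is with replacement and a warning is
emitted. Both engines and the consensus rule are recomputed per
permutation; eFDR = min(1, mean null discoveries / observed discoveries),
undefined when the observed set is empty. Two design points:

1. *Nuisance estimates are label-free inside the eFDR.* TMM factors,
   size factors and the exact-test conditioning are label-free by
   construction; dispersions are estimated once from the pooled samples
   (one-group tagwise estimates). If dispersions were estimated from the
   observed grouping, genes whose within-group variance is small *by
   chance* would receive small dispersions and small p-values, the
   observed labeling would no longer be exchangeable with permuted ones,
   and the eFDR would be biased far below 1 on pure-null data (measured:
   ~0.12). With pooled estimates the null eFDR is ~1, which is the
   calibration the estimator must have; for truly DE genes the pooled
   dispersion absorbs the group signal and is conservative.
2. The per-permutation consensus needs the Wald engine only on genes the
   exact engine already called, which keeps 10,000 permutations on a
   2,000-gene matrix in the minutes range on one core.

eFDR is computed on the consensus set (the reported discovery rule);
per-engine modes are available behind a flag.

## Top-scoring pairs

For genes i, j and binary classes, Δ(i,j) = |P̂(Xᵢ<Xⱼ|C₁) − P̂(Xᵢ<Xⱼ|C₂)|
estimated from within-sample orderings of FPKM with *strict* inequality —
tied values (common with zeros) contribute to neither frequency, and in
classification a tied pair abstains rather than fabricating a vote. The
secondary score Γ(i,j) is |d_i − d_j| where d_g is the difference between
the class means of gene g's within-sample average rank. The ranking is the
total order (Δ desc, Γ desc, lexicographic ids). Both scores live on
discrete grids (multiples of 1/(n₁n₂)), so the implementation orders by
exact integer numerators; ties are exact, the ranking is reproducible,
and the scan provably equals a brute-force double loop (property-tested,
including block-size independence of the streamed kernel).

Ordered-pair accounting is n(n−1), matching how exhaustive pair scans are
usually counted; reports deduplicate mirror pairs and keep the
orientation whose "Xᵢ below Xⱼ" pattern indicates class 1. Pair scoring
streams gene blocks (O(block × genes × samples) memory), so the exact
scan handles ten-thousand-gene inputs; restricting permutation scans to a
candidate pair set is possible but off by default (exactness over speed).

The permutation test records the maximum Δ over all pairs for each label
permutation and reports the add-one estimator
p = (1 + #{null max ≥ observed max}) / (1 + n_perm), floored at
1/(n_perm + 1) and never zero. Classification is majority vote over the
top-k pairs with abstention and vote ties resolved toward the larger
class (class 1 on a size tie); the overall score of a pair list on
labeled data is the top pair's Δ on those labels. Ratio features are
log₂((FPKMᵢ + ε)/(FPKMⱼ + ε)) with ε = 1 so zero FPKM stays finite.

**A design-size caveat.** With 5–6 samples per class, a pair of genes
with overlapping distributions flips perfectly by chance with probability
around 2·(1/2)^(n₁+n₂) ≈ 5·10⁻⁴; among millions of pairs every label
permutation then contains perfect pairs and the permutation null of the
*maximum* score saturates at 1. The test is informative for small panels
or larger groups; the acceptance setup therefore uses 16 animals per
group (where the observed labeling is essentially never redrawn among
5,000 permutations and the reported p reaches its 1/5001 floor), and the
worked example uses 8 per group.

## Clustering and enrichment

Samples are clustered from the k × n matrix of top-pair log-ratios using
correlation distance (1 − Pearson between sample feature vectors) and
average linkage by default — the common defaults for expression heatmap
dendrograms — with Euclidean distance and complete linkage available.
Constant sample columns make correlation distance undefined and are an
error on observed data; inside bootstrap replicates they are treated as
maximally uninformative instead of aborting the resample.

Cluster support is the plain bootstrap proportion: the k feature rows are
resampled with replacement, the tree rebuilt, and BP(node) = fraction of
bootstrap trees containing the node's leaf set as a cluster (the root is
always 1). Multiscale/approximately-unbiased corrections are out of
scope; for the perfect-separation case BP and AU agree at support 1.
Dendrograms serialize to Newick with BP as internal-node labels.

Enrichment of a cluster for an outcome is the exact upper-tail
hypergeometric probability P(X ≥ k), X ~ Hypergeom(N, K, n) — no normal
approximation; the unit tests pin it against explicit binomial
coefficients. The canonical check: a cluster of 12 samples containing 10
of 12 positives among 23 gives p = 3763/1352078 ≈ 0.0028.

## qPCR statistics

ΔCT = CT_target − CT_reference per sample; ΔΔCT is the group-2-minus-
group-1 difference in mean ΔCT and the fold change is 2^(−ΔΔCT),
matching the RNA-seq orientation (second group over first). The math
assumes amplification efficiency 2 per cycle; measured efficiencies are
accepted as metadata only. The reference gene must be measured in every
sample, and its stability between groups is checked with a two-sample
t-test (pass iff p exceeds a configurable threshold, default 0.5;
identical constants pass with p = 1). Group comparisons of ΔCT use the
pooled-variance t-test by default (Welch optional) at α = 0.1.

The power of that design comes from the noncentral t: df = 2n − 2,
noncentrality d√(n/2), with the one-sided threshold by default because
the design question is directional; at n = 6, d = 1, α = 0.1 this gives
0.65 (the two-sided version gives 0.49). A 100,000-replicate Monte-Carlo
t-test cross-checks the formula in the test suite.

Concordance between qPCR and RNA-seq fold changes is Spearman's rank
correlation over shared genes (≥ 3 required), with an exact two-sided
permutation p-value from full enumeration for panels of ≤ 10 genes and
the usual t-approximation above.

## Synthetic data

The generator emulates one station of the study design: two outcome
groups (default 6 + 6), NB counts with lognormal relative baselines
(location 2.0, scale 1.5 on the natural-log scale — a typical bulk
dynamic range), gene-wise dispersions drawn from Gamma(shape 2, mean 0.1)
unless fixed, uniform library sizes, and gene lengths lognormal around
1.5 kb (floor 100 bp). The desk-scale defaults (2,000 genes, 2–4 × 10⁵
read pairs) preserve per-gene counting depth while keeping the full
pipeline, including permutation error control, in the minutes range.

Planted signal:

- **DE genes** split their fold change symmetrically (×2^(−fc/2) in group
  1, ×2^(+fc/2) in group 2) so overall library composition stays stable.
- **Reversal pairs** are planted on the length-normalized (FPKM) scale,
  because that is the scale on which the pair analysis orders genes
  within samples: the partner's normalized mean is placed within a stated
  gap (default 1.3–2×) of the anchor and the two normalized means are
  swapped in group 2. Any third gene whose normalized mean falls inside a
  swapped band (±10%) is relocated just outside it — otherwise it would
  itself form a perfect reversal with either pair member and planted
  truth would not be identifiable.
- **qPCR tables** derive from the same truth: CT = intercept − log₂(true
  relative expression) + Gaussian noise (default intercept 25, noise 0.2
  cycles), with a designated reference gene required to be non-DE.

Everything is driven by one integer seed through `numpy`'s Generator;
identical configurations are bit-identical. What the generator does *not*
emulate: sequencing-level artifacts, batch or station effects beyond
independent baselines, correlated genes/pathways, GC or length biases,
and station-specific detectability (the station-exclusive detected-gene
counts of a real two-station design arise only if the two stations are
simulated with different gene activity, which is off by default). Tests
passing on this generator therefore certify the statistical machinery
under its stated model, not robustness to those real-data complications.

## Numerical conventions and degenerate inputs

- Exact-test supports are enumerated fully per gene (no saddlepoint or
  normal approximation); lookup tables make permutation reuse O(1).
- Newton fits clip steps to ±5 on the log scale; groups with zero total
  count are boundary cases: flagged non-converged, p = NaN, excluded from
  the consensus, fold change reported with the prior count.
- Detection filtering with `min_samples` larger than the number of
  samples, empty input tables, unknown outcome labels, duplicate ids,
  gene-set mismatches across count files, missing gene lengths, zero
  library sizes, and infeasible planting configurations are all explicit
  errors, not silent coercions.
- All stochastic stages (simulation, eFDR, TSP permutations, bootstrap,
  qPCR noise) take explicit integer seeds; the pipeline config refuses to
  run without them.

## Problem sizes used by the checks

The acceptance checks run at desk scale by design: 2,000-gene null and
planted simulations for type-I and eFDR calibration (500 permutations,
10 null replicates), 100 recovery simulations at 60 genes × 16 samples,
exhaustive pair-scan oracles up to 8 genes × 10 samples, full enumeration
of conditional binomial tests for totals ≤ 30, a 100,000-replicate power
simulation, and a 5,000-permutation maximum-score null on a 40-gene,
32-sample matrix. Quantities that depend on the original sequencing data
(specific DEG lists and counts, station eFDR values of 0.02/0.05,
published fold-change tables, the 0.94 qPCR concordance, pair counts of
surviving top pairs) are covered by these property-level checks instead,
since no public accession exists to recompute them from.
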