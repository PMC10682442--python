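# Methods

This note documents the models, numerical choices and known limitations
of `cernapipe`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Pipeline overview

The pipeline analyses a multi-subtype expression cohort covering four
RNA classes (mRNA, lncRNA, circRNA, miRNA) in six chained stages:
preprocessing → per-subtype primary ceRNA network inference →
common/specific network algebra → Markov-cluster module detection (+
gene-set over-representation) → survival screen → differential-expression
biomarker selection with SVM validation. Every stage reads and writes
plain-text artifacts under one output directory, so a monolithic run and
stage-by-stage runs are interchangeable and bit-identical given the same
seed.

## Synthetic cohorts: the stated world

The generator produces the structure the analysis assumes, with known
ground truth. Defaults (all configurable in `GeneratorConfig`):

| parameter | default | meaning |
|---|---|---|
| subtype sizes | 88 / 100 / 76 / 252 / 42 | five subtypes, unequal cohorts |
| genes per class | 200 mRNA, 60 lncRNA, 60 circRNA, 60 miRNA | |
| baseline log-mean per class | 4.0 / 2.5 / 1.5 / 3.0 | circRNAs least abundant |
| baseline log-sd | 1.0 | spread of per-gene baselines |
| per-sample noise log-sd | 0.5 | biological variation of background genes |
| planted triplets | 3 common + 4 specific per subtype | strength 0.7 |
| planted log-sd | 0.4 | deviation sd of planted genes (all subtypes) |
| biomarkers | 2 per subtype, log2FC = 2 | scaled only in their subtype |
| NB dispersion | 0.2 | counts layer (gamma–Poisson around expression) |
| survival effect | 0.8 | log-hazard per expression z-score |
| censor rate | 0.3 | uniform censoring, horizon solved by root-finding |
| outliers | 3 per subtype, scale 5 | scaled + gene-shuffled profiles |

**Expression model.** Gene g has one global baseline
μ_g ~ N(class mean, 1) shared by all subtypes; a sample's log-expression
adds N(0, 0.5²) noise. Because all samples share the μ_g profile,
sample–sample correlation across genes is high for genuine samples —
which is what makes distortion-based outliers detectable.

**Correlation planting.** A triplet draws latent miRNA activity
m ~ N(0, 1) per sample; member genes deviate from baseline by
τ·(s·m + σ·ε)/√(1+σ²) with τ = 0.4, s = −1 for the miRNA, +1 for the
sponges. The screen computes Pearson r on the *expression* scale, so σ
is solved from the exact bivariate-lognormal correlation identity
corr = (e^{ρₙv} − 1)/(e^v − 1), v = τ²: the sponge–sponge expression
correlation hits the configured strength exactly in expectation
(ρₙ = log(1 + ρ(e^v − 1))/v, σ² = 1/ρₙ − 1). The negative miRNA arms
attenuate asymmetrically (≈ −0.62 at strength 0.7) but still clear the
0.4 screen comfortably at n = 100. Outside a triplet's scoped subtype
the same genes keep the identical marginal (sd τ, independent noise), so
planted genes are null for differential expression unless also planted
as biomarkers. Planted baselines are clamped to μ_g ≥ 1 so the
abundance filter cannot delete ground truth. Triplet sponge classes
cycle through (mRNA,lncRNA), (circRNA,mRNA), (circRNA,circRNA),
(circRNA,lncRNA); only non-circRNA sponges deposit (miRNA, target) pairs
into the interaction database, exercising both inference routes.

**Counts.** Sequencing-like counts are sampled per cell as
gamma–Poisson (NB) around the continuous expression value. The *total*
overdispersion therefore exceeds the NB layer's 0.2, because the
lognormal expression noise sits underneath — which is why the DE stage
estimates dispersion from data by default (below).

**Survival.** Event times are exponential with rate
λ₀·exp(0.8·z), z the z-scored expression of one designated mRNA sponge
per subtype. Censoring times are Uniform(0, H) with H solved by Brent's
method so the expected censored fraction equals the configured rate.

**Outliers.** An outlier sample is its own profile multiplied by 5 with
gene order shuffled — distant from all genuine samples under
1 − Pearson distance without changing the library-scale summary
dramatically.

**What the generator does not emulate:** batch effects, isoform
structure, count–length biases, correlated miRNA programs beyond single
triplets, non-proportional hazards. A green test therefore establishes
correctness of the machinery on the assumed structure, not performance
on TCGA-scale heterogeneity.

## Preprocessing

1. **Abundance filter**: drop genes whose mean over the pooled samples
   of all subtypes is < 0.5 (strict), keeping one shared gene space.
2. **Variance filter**: drop genes with pooled population variance below
   1e-8 (and exactly constant genes at any threshold).
3. **Outlier removal** per subtype: average-linkage agglomerative
   clustering of samples under 1 − Pearson distance on log1p expression;
   cut the dendrogram at h* = median(merge heights) + k·1.4826·MAD
   (k = 5); samples outside the largest cluster are removed.

The robust cut is deliberate. A mean + 2·sd rule is unusable here twice
over: in a homogeneous cohort the maximum of ~n merge heights routinely
exceeds mean + 2·sd (spurious removals), and with genuine outliers the
extreme merge heights inflate the sd and mask themselves. Median/MAD is
insensitive to the very merges the rule must catch; behaviour is stable
for k anywhere in [4, 8]. Linkage, distance and k are configurable.

## Primary ceRNA networks

All correlations are sample Pearson coefficients with two-sided p from
t = r·√((n−2)/(1−r²)) against t(n−2). Thresholds are strict:
|r| > 0.4 and p < 0.05. Genes constant within a subtype are excluded
from that subtype's inference with a logged warning. The db route
(mRNA/lncRNA pairs, including mRNA–mRNA and lncRNA–lncRNA) requires a
shared miRNA with database-validated interactions to both endpoints and
the correlation signature; the correlation-only route covers every pair
involving a circRNA (circRNA–circRNA, circRNA–mRNA, and — by design
choice, since circRNAs have no database coverage — circRNA–lncRNA) with
any miRNA as mediator. Edge weight is r(u, v); all supporting miRNAs
are retained. Isolated nodes are removed after edge construction.

## Network algebra

Common network: node and edge intersections across all subtypes; a
common edge's weight is the mean of the per-subtype weights and its
supporting-miRNA list the union. Specific network: the subtype's edges
minus the common edges, with nodes defined as the endpoints of the
surviving edges (a pure node-set difference would orphan specific edges
incident to shared hubs; the naive difference count is still reported as
a graph attribute `node_difference_count`).

## Markov clustering

Column-stochastic matrix over the (symmetric, weighted) adjacency with
self-loops at each node's maximum incident weight; iterate expansion
(matrix power 2) and inflation (entry-wise power 2.0, renormalize),
pruning entries < 1e-5, until the maximum entry change is < 1e-8 or 100
iterations (non-convergence returns the state with a warning flag).
Clusters are read from attractor structure: attractors (positive
diagonal) sharing limit-matrix mass form attractor systems; every node
joins the system of its highest-attraction attractor, ties resolved to
the lexicographically first. Nodes are processed in sorted order, so
results are invariant to input order. Modules with at least one lncRNA
or circRNA member are retained for downstream screens.

## Enrichment

Over-representation of each (module, gene set) pair by the
hypergeometric upper tail P[X ≥ k], sets intersected with the universe
(all genes surviving preprocessing, miRNAs excluded) before testing;
Benjamini–Hochberg correction spans all (module, set) pairs within a
subtype; FDR < 0.05 is significant.

## Survival screen

For each mRNA in the union of a subtype's retained modules, samples
split at the gene's mean expression (strictly greater = high group;
degenerate splits are skipped with a warning). Kaplan–Meier
product-limit curves per group and the standard two-group log-rank test:
χ² = (ΣO − ΣE)²/ΣV with hypergeometric tie-corrected variance, p from
χ²(1). P-values are reported raw (no multiplicity correction at this
screen), flagged at α = 0.05.

## Differential expression and biomarkers

Counts are normalized with TMM (trimmed mean of M-values, 30% M-trim, 5%
A-trim, inverse-variance weights, reference = sample with
upper-quartile CPM closest to the mean; factors scaled to geometric
mean 1). Normalization factors and the dispersion estimate always come
from the **full** count matrices even when only module genes are tested
— normalizing on a ~15-gene subset would let the planted fold changes
masquerade as library-size differences.

Per gene, the two group totals at equal effective library sizes are
compared with a conditional NB exact test: if per-sample counts are
NB(μ, φ), the group-A total conditional on the combined total t follows
BetaBinomial(t, n_A/φ, n_B/φ), independent of μ; φ = 0 degenerates to
Binomial(t, n_A/(n_A+n_B)). The two-sided p doubles the smaller tail
(observed point included), capped at 1. By default φ is the pooled
method-of-moments estimate median[(s² − μ̂)/μ̂²] over genes and groups
(clipped at 0), which absorbs biological variation beyond the count
layer; a fixed φ can be supplied instead. log2FC uses a prior count of
0.5 per group mean; positive means up in the focal subtype.

A gene enters the pairwise DE set when FDR < 0.05 (BH within the
comparison) and |log2FC| > 0.5, both strict; the subtype's biomarker set
is the intersection across all four comparisons, reported with mean/sd
of |log2FC| and FDR.

**SVM validation**: features are the biomarker genes' expression over
all retained samples, z-scored with training-fold statistics only;
one-vs-rest labels; stratified 5-fold CV with a fixed seed; RBF kernel,
C = 1 (both exposed); per-fold ROC from decision scores, trapezoidal
AUC.

## Numerical and degenerate-input conventions

- |r| = 1 maps to p = 0; correlation matrices are clipped to [−1, 1].
- Conditional-test tail probabilities are clipped at 0 before doubling
  (floating-point cancellation can yield −1e-16).
- Log-rank with no events, or zero variance, returns (0, 1) with a
  warning; genes whose mean split empties a group are skipped.
- All-zero genes in both DE groups get p = 1, log2FC = 0; all-zero
  samples are an error.
- BH uses a stable mergesort, so ties are order-preserving.
- Every stochastic step consumes a `numpy.random.Generator` seeded from
  the run seed; set iteration never feeds the RNG (hash randomization
  would silently break cross-process reproducibility).

## Known limitations

- The DE test uses one pooled dispersion; no per-gene empirical-Bayes
  shrinkage (out of scope by design), so it is less powerful than
  edgeR's tagwise machinery on heteroskedastic data and is validated
  statistically (calibration, recovery), not for numeric parity.
- The correlation screen applies no multiple-testing correction (as in
  the original procedure); at cohort scale the strict 0.4/0.05 pair is
  the operative control.
- MCL granularity is fixed at inflation 2.0 by default; very dense
  specific networks may cluster coarsely.
- The enrichment stage is a generic over-representation test against a
  supplied GMT, not a GO-graph-aware method.
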