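# Methods

`dcnet` analyses two-condition (reference/disease, canonically
normal/cancer) gene-expression studies through the lens of *differential
connectivity*: not only which genes change in mean expression, but which
genes lose or gain co-expression partners between conditions.

## Co-expression network inference

For each phenotype group separately, every gene pair (i, j) is scored by the
Spearman rank correlation ρ_ij — the Pearson correlation of mid-ranks, which
captures monotone, possibly non-linear association. Under no association and
for group size m_g > 10, z = ρ √(m_g − 1) is asymptotically standard normal,
giving a two-sided p-value p_ij = 2(1 − Φ(|ρ| √(m_g − 1))). An edge is drawn
when p_ij < α (default 0.05) **and** the Benjamini–Hochberg adjusted value,
computed jointly over all n(n−1)/2 unordered pairs of that network, is below
the FDR ceiling q (default 0.20). The result is an undirected, unweighted
graph per phenotype: symmetric binary adjacency, zero diagonal.

Choices worth noting:

* The plain normal approximation is used (no continuity correction, no
  t-approximation variant); its accuracy at m = 12 is verified against the
  exact permutation distribution of ρ in the test suite (absolute error of
  the p-value below 0.05 for |ρ| ≤ 0.8).
* BH is applied once per network over all pairs, treating the correlation
  screen as one family. A per-gene family would change edge counts
  asymmetrically between hubs and leaves.
* The minimum group size (default 11) is a parameter. Lowering it is only
  sensible for exhaustive toy analyses (e.g. enumerating all label
  assignments of a 3+3 study in a test); the asymptotic p-values are not
  trustworthy there and are only used as a fixed edge-calling rule.
* Computation is dense (n² correlation entries); a full-transcriptome run
  (~20k genes) needs cluster-scale memory, so analyses here operate on gene
  subsets. The method is unchanged by subsetting.

## Differential connectivity

The degree k_i = Σ_j a_ij counts a gene's co-expression partners. The
differential connectivity of gene i is

    Δk_i = k_i(normal) − k_i(cancer),

so positive Δk means loss of connectivity in disease. Per gene, `dcnet` also
counts edges *lost* (present only in normal) and *gained* (present only in
cancer); Δk ≡ lost − gained holds exactly and is property-tested.

Significance: patients are randomly reassigned to the two groups (group
sizes preserved — both per-group asymptotic tests keep their operating
characteristics), and the **entire** edge-calling procedure, including the
per-permutation BH adjustment, is re-run on both pseudo-groups B times
(default B = 1000; tests and desk-scale runs use B = 200). Then

    p_i = #{b : |Δk_i^(b)| ≥ |Δk_i|} / B.

No +1 pseudo-count is added: p = 0 is a legal, reportable outcome for genes
whose observed |Δk| exceeds every permuted value. BH across genes gives the
DC FDR column. Under the exchangeable null this p-value is sub-uniform
(conservative), because many genes have observed Δk = 0, which every
permutation ties; the calibration test asserts exactly this one-sided
behaviour.

Degree distributions are compared with the two-sample Kolmogorov–Smirnov
test (asymptotic p): one-sided (normal stochastically greater) for the
loss-of-connectivity claim, two-sided against Erdős–Rényi null graphs
matched in node count and average degree (each pair connected independently
with p = k̄/(n−1); one replicate by default, seeded). Whether the KS
comparison should be one- or two-sided is genuinely ambiguous in this kind
of analysis; both are exposed and the defaults follow the direction of the
scientific claim being tested.

The DC/DE interplay report computes Spearman associations between (i) the
DC p-value and lost-edge counts (left tail — more losses should mean
smaller p), (ii) the DE p-value and gained-edge counts (tail chosen by the
observed sign), (iii) the two p-value vectors (two-sided), plus the degree
ratio (k_cancer + 1)/(k_normal + 1). The +1 pseudo-counts keep the ratio
defined for isolated genes; constant inputs are reported as not-computable
with a reason rather than as a number.

## Differential expression and the gene score

DE uses the classic pooled-variance two-sample Student t (df = m₁ + m₂ − 2,
two-tailed, BH across genes). The set-level score is the normal-quantile
transform of t,

    s_i = |Φ⁻¹(F_df(t_i))|,

computed through the upper tail for numerical stability. Folding by absolute
value makes up- and down-regulated genes contribute alike, so
mixed-direction pathways are not self-cancelling; a signed variant is
available (`de_score(..., signed=True)`) for direction-aware uses. s is
monotone in |t| and N(0,1)-distributed under the null before folding.

## Random-set enrichment (DE mode)

A set S of m genes in a universe of G is scored by the restandardized mean

    Z_S = ( mean_{i∈S} s_i − μ̂ ) / ( σ̂ √((G − m) / (m (G − 1))) ),

where μ̂ and σ̂ are the mean and population standard deviation of all G
scores. The factor √((G−m)/(m(G−1))) is the exact standard error of the mean
of a size-m sample drawn without replacement, so Z has mean 0 and variance 1
over all same-size subsets — verified exactly by exhaustive enumeration in
the tests. Significance against the phenotype comes from sample-label
permutations: t, s and Z are recomputed inside each permutation (the
restandardization is not frozen at the observed data), and
p = #{Z^(b) ≥ Z}/B, BH across sets. Sets are first restricted to the
dataset's gene universe; sets smaller than 2 genes after restriction are
excluded and logged.

## The DEC statistic and its enrichment

Per gene, the DE and DC p-values are combined as

    u_i = max( −log₁₀ max(p_DE,i, ε), −log₁₀ max(p_DC,i, ε) ),

with floor ε = 1/B by default — algebraically the −log₁₀ of the floored
minimum p. u is large when a gene is differentially expressed **or**
differentially connected, which is the intended semantics: the two
phenomena can dissociate, and either is evidence of involvement. (A
Fisher-style additive combination would instead demand joint evidence;
the max/min-p form is the package's choice and the additive form can be
built from `stats.fisher_combined` if wanted.) A set's DEC score is the
mean u of its members, judged against n_draws (default 1000) uniformly
drawn same-size gene sets; p is the exceedance proportion, BH across sets.
All empirical p-values in the package follow the same convention: raw
proportion on the grid {0, 1/R, …, 1}, zeros allowed, floored only when
entering logarithms or Fisher combination.

Across independent studies (tissues), per-set p-values are combined with
Fisher's method (−2 Σ ln p ~ χ²_{2k}) after flooring at 1/R.

## Core-set validation

Given a curated core set C of disease pathways inside a scored collection,
each metric gets a weighted recovery score

    S = Σ_{j∈C} max(0, 1 − p_j / α),   α = 0.01:

weight 1 at p = 0, linearly to 0 at and above α — a smoothed count of core
pathways significant at α. The difference D = S_DEC − S_DE is referred to
the distribution of the same difference over random pathway subsets of size
|C| (default 10000 draws); p = #{D_random ≥ D}/draws. The linear weight is
the package's choice of a continuous counting rule anchored at the 0.01
level; it reduces to plain counting when significant p-values are near 0.

## Synthetic data: what it emulates, what it does not

The generator plants known structure so every stage is testable end to end:

* **Modules.** Each of `n_blocks` modules is driven by a latent factor:
  module gene x = √ρ·f_b + √(1−ρ)·ε per sample (f_b, ε standard normal), so
  within-module Pearson correlation is exactly ρ and marginal variance 1.
  Background genes are independent noise. The latent-factor construction is
  positive definite at any size, unlike an arbitrary explicit covariance.
* **Loss of connectivity.** In the cancer condition a fraction
  `dc_fraction` of module genes (sampled once, recorded in the truth
  object) are detached: pure noise, factor weight 0 — their correlations
  with former partners vanish while their marginal distribution is
  unchanged.
* **Differential expression.** A fraction `de_fraction` of all genes gains
  a mean shift of `effect_size` within-group standard deviations in the
  cancer group only. DE and DC planting are independent draws; their
  overlap is allowed and recorded, so the two phenomena can be decoupled
  or coupled at will.

Defaults are the package's reference study conditions: 200 genes, two
40-gene modules, ρ = 0.7, 30 + 30 samples, dc_fraction = 0.25,
de_fraction = 0.10, effect_size = 1.0. Group size 30 sits inside the
14–58 per-group range typical of two-condition microarray cohorts; the DE
prevalence and one-SD effect are ordinary for such data.

Not emulated: probe-level and batch effects, count-data noise, scale-free
topology, and between-module correlation. Passing tests therefore
demonstrate the statistical machinery behaves correctly under a clean
block-correlation model — not that real microarray preprocessing artefacts
are handled. One property of the model worth knowing: because each
condition draws its own factor values, a module's sample-mean can differ
between conditions by O(√(ρ/m)), so a large correlated set can show mild
set-level DE signal even without planted shifts. This mimics the real
phenomenon that co-regulated modules move together, but it means set-level
DE nulls on module genes are only approximately calibrated (gene-level DE
nulls are exact).

## Determinism and seeds

Every stochastic component takes an explicit seed. The pipeline spawns one
child seed per stage from the root seed via `numpy.random.SeedSequence`, so
a full run is byte-reproducible and stages can be re-run individually from
the written intermediates. Artifact headers echo the package version, a
hash of the scientific configuration (output directory excluded) and the
seed.

## Numerical notes

* Spearman matrices are computed as rank-then-Pearson with mid-ranks;
  values are clipped to [−1, 1] before the normal transform.
* The quantile score is computed through the t upper tail and the
  complementary normal quantile, retaining precision for |t| up to the
  underflow limit (s ≈ 37.5 at the double-precision floor).
* Gene tables are written at %.17g so a write/read round trip is exact;
  row order is descending |Δk| with ties broken by gene symbol.
* BH adjustment delegates to `statsmodels` (`fdr_bh`); KS to
  `scipy.stats.ks_2samp` with the asymptotic p-value. Both are checked
  against literal reference implementations in the tests.

## Known limitations

* The dense n² correlation pass bounds practical universe size (~a few
  thousand genes per run on a laptop).
* Duplicate gene symbols (e.g. multiple probesets per gene) must be
  collapsed upstream; the loader rejects them.
* The permutation DC test is conservative for genes with small observed
  |Δk| (ties at zero), which is inherent to the discrete statistic.
* Exact small-sample null distributions for the Spearman and KS tests are
  not implemented; the asymptotic forms are used and their accuracy is
  oracle-tested at the sample sizes the package recommends.
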