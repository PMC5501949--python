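# Methods

`convergetrend` implements a meta-analytic test of a simple hypothesis
about disease gene sets: if candidate sets are ordered by the average
effect size of the variants that nominated them, genuinely disease-related
functional signals should grow stronger along that ordering, while
study-design artifacts should not. This note describes the model, the
statistical machinery, the synthetic data the package is validated on, and
the numerical choices and limitations a user should know about.

## The analysis model

**Effect sizes and ranks.** Each candidate gene set carries an average
effect size expressed as an odds ratio. For de novo variant classes this
is the ratio of (damaging : silent) mutation-count odds between probands
and unaffected siblings (`compute_odds_ratio`); for association studies it
is the average per-SNP odds ratio. Sets are ranked ascending by odds
ratio. Control sets (sibling mutations, silent variants) have no defined
effect and are all tied at the average of the lowest ranks — with four
controls, each gets rank 2.5. Ties among equal odds ratios are broken by a
user-supplied key encoding the expected false-positive burden (a set with
fewer expected false positives ranks higher); sets equal on both are
average-tied. Ranks are invariant to any monotone transform of the odds
ratios.

**Functional tests.** Three test families assess a gene set against a
functional property:

* *Annotation sets*: one-sided (upper-tail) hypergeometric enrichment of
  the overlap.
* *Gene scores* (intolerance scores such as RVIS, haploinsufficiency,
  pLI): one-sided Mann-Whitney-Wilcoxon rank-sum of candidate scores
  against all other scored genes. Each score's known risk direction is
  configured per property (`greater` or `less`); exact enumeration is used
  for small untied samples, otherwise the tie-corrected normal
  approximation.
* *Weighted networks*: a modularity test. For each candidate gene, the
  global degree (sum of incident weights over the whole network) and the
  internal degree (sum of weights to other candidate genes) are computed,
  along with the same quantities for many random same-size gene sets. A
  zero-intercept line `internal = beta * global` is fitted over the pooled
  genes (an identity-line variant is available behind `null_line`),
  residuals are standardized by the pooled spread, and a one-sided
  rank-sum test compares candidate residuals with null-set residuals.

**Downsampled convergence.** Every test's p-value depends on the set
size, so sets of different sizes are made comparable by downsampling: the
test is recomputed on `iters` uniform subsamples of a common size `k`
(default `min(25, smallest set size)`, 1000 iterations) and aggregated by
the geometric mean of the per-subsample p-values (floored at 1e-300
before taking logs). The result — the "functional convergence" — equals
the raw p exactly when `k` equals the set size. All properties of one
analysis are assessed on the same subsample pool per set, so differences
between properties are not driven by sampling noise.

**Trend, null, FDR.** For each property, the per-set significances
`s = -log10(convergence p)` are Spearman-correlated with the effect
ranks (ties mid-ranked). Any monotone decreasing transform of p gives the
same |r_s|; the -log10 orientation makes a positive trend mean "more
significant at higher effect size". The two-sided trend p uses the
t-approximation `t = r sqrt((n-2)/(1-r^2))` with `n-2` degrees of
freedom, which handles the tied control ranks; |r| = 1 maps to p = 0.
Properties are filtered before trend testing: the strict regime keeps
properties where at least one set converges below 0.05, the loose regime
below 0.5, and `none` keeps every property with a computable trend.
Benjamini-Hochberg adjustment is applied within each regime, and
significant-trend counts are reported at FDR 0.01 and 0.05. An empirical
null is available by permuting the set labels (equivalently the rank
vector) and recomputing every trend; for distinct ranks its standard
deviation matches the analytic `1/sqrt(n-1)`. Properties can be
clustered by complete-linkage agglomeration on the Euclidean distance
between their column-ranked significance profiles; the default cut
produces six flat clusters, and an explicit cut height is accepted.

**Controls and harnesses.** Matched control sets are sampled to share a
target set's attribute-rank distribution (CDS length, GO
multifunctionality, or a user-supplied disease-multifunctionality score):
sampling is stratified by attribute-rank decile and accepted when the
Kolmogorov-Smirnov statistic between the rank distributions is within
tolerance (default 0.1, 1000 retries; failures report the best achieved
distance). Multifunctionality is the number of distinct annotation sets a
gene belongs to. The leave-class-out harness removes an entire variant
class, re-ranks the survivors (controls re-tied) and recomputes the trend
battery; because convergence values do not depend on the ranking, the
pipeline reuses the cached matrix and only recomputes trends. The
trait-swap harness substitutes alternative trait gene lists (with at
least `min_genes` genes, default 27) into the sets flagged as swappable —
by default both association-study slots — and ranks traits by their
resulting count of significant trends.

## The synthetic scenario generator

Real inputs (exome calls, expression atlases, annotation databases) are
not required: `synthetic_data` generates complete scenarios with the
statistical structure the analysis assumes, plus ground-truth labels.

A scenario has a universe of `n_genes` (default 8000) with log-normal CDS
lengths and multifunctionality computed from the generated annotation
sets; a latent disease core of `core_size` genes (550); and the default
11-set collection mirroring a rare/common/control study design (sizes 27
to 1339, odds ratios 1.06-4.1, four controls). A candidate set at effect
rank `r` draws a fraction `q = signal_base + signal_slope * (r - r_min)`
of its genes from the core (defaults 0.08 + 0.08 per rank unit, capped at
0.95), so the weakest candidate sits just above the controls' chance
overlap (550/8000 ≈ 0.07) and the signal concentrates in the strong
sets — the study's working hypothesis. The core count is realized exactly
(`round(q * size)`) rather than binomially thinned: shared binomial draws
can scramble the whole planted gradient in one unlucky scenario, a
failure mode of the simulation rather than of the method under study;
which genes are drawn remains random, so set-property overlaps keep their
natural hypergeometric noise. Controls sample uniformly.

Properties: planted annotation sets (14 of 92 by default, sizes 150-300)
draw 95% of their members from the core; planted gene scores (2 of 8)
shift core genes by 1.0 over N(0,1) noise; null properties are uniform
draws / pure noise. The network has three 100-gene modules of core genes
at within-weight 0.5 over a U(0, 0.04) background, plus a 300-gene
"artifact module" of non-core genes at weight 0.3. With
`control_artifact` on, every set — controls included — draws
`artifact_rate` (0.25) of its genes from the artifact module, emulating
ascertainment tilted toward hub genes (long, highly expressed, highly
studied); this reproduces the confound phenomenology where network
convergence appears even in control data without any effect-size trend.

Planted-signal strength was set so that planted properties reach trend
correlations around 0.9-0.97 — the magnitude the analysis is designed to
flag — while remaining weak enough that removing any variant class
measurably thins the significant battery; both behaviours were verified
across many generator seeds before the defaults were frozen.

## Experiment designs (the `experiments` module)

* *Ranking*: the default 11-set odds ratios and classes are pushed
  through `rank_gene_sets` and compared against the expected rank column.
* *Null calibration* uses 11 equal-size sets of 200 genes over a
  16,000-gene universe with slope 0 and 1000 GO-scale annotation
  properties (50-200 genes). Equal sizes make the sets exchangeable —
  the correct design for a type-I check (see Limitations for why the
  heterogeneous default sizes are not used here).
* *Signal recovery* runs the default planted scenario end to end (k=25,
  1000 downsampling iterations, 200 connectivity null sets) and reports
  planted recovery at FDR 0.01, the planted-vs-null trend separation, and
  leave-class-out counts.
* *Confound demonstration* runs a slope-0, artifact-on scenario with
  equal-size sets and reports the network property's convergence in
  controls and its (absent) trend.

## Numerical choices

* p-values are floored at 1e-300 before logs; convergence values are
  clipped into (0, 1].
* Spearman correlations are computed as Pearson on mid-ranked data;
  correlations are clipped into [-1, 1] before the t map.
* Co-expression edge weights are signed Spearman correlations
  rank-standardized to (0, 1] over all gene pairs (ties mid-ranked;
  correlations rounded to 12 decimals first so analytically equal values
  tie exactly). Constant-expression genes correlate 0 with everything and
  land at the mid rank. Aggregation is the element-wise mean of
  standardized weights, re-standardized.
* Network matrices are stored densely with lexicographic node order;
  symmetry validation can be skipped for construction-guaranteed matrices.
* Uniform without-replacement index sets are drawn by duplicate-rejection
  when the subsample is small relative to the pool, otherwise by random
  keys; both are exact.
* One `numpy` Generator seeded from the run configuration threads through
  every stage; outputs carry the seed and a config hash, and identical
  configurations are bit-identical.

## Limitations

* **Set-size variance asymmetry.** Downsampling equalizes the *mean* of
  `-log p` across set sizes but not its *variance*: a 27-gene set
  subsampled at k=25 yields essentially one draw, while a 1339-gene set's
  geometric mean concentrates tightly. With the right-skewed `-log p`
  distribution, small sets tend to land at the bottom of the significance
  ordering; because set size is anti-correlated with effect rank in the
  default design, the null trend under those sizes is biased negative
  (mean r_s ≈ -0.1 rather than 0). A dedicated test documents this bias.
  The label-permutation null does not remove it either (it is symmetric
  around 0 by construction), which makes positive-trend detection
  slightly conservative under the default sizes. Type-I calibration is
  therefore checked on equal-size sets, and the confound demonstration
  also uses them so a flat trend is not masked by the same asymmetry.
* **Connectivity p-values are scores, not literal error rates.**
  Residuals of a gene set are positively correlated through shared
  within-set edges, so the rank-sum statistic is over-dispersed and its
  tails exceed nominal. The trend stage consumes these values only
  through their ranking across sets and carries its own permutation null,
  so trend inference is unaffected; the marginal connectivity p should
  not be quoted as a calibrated significance.
* **t-approximation at n = 11.** The trend p from the t map deviates
  from the exact permutation null by up to a factor of ~2 in the far tail
  (the statistic is discrete at 11 sets with tied controls); a test pins
  the agreement to within that factor.
* **What passing on synthetic data shows.** The generator plants
  rank-linear membership gradients with independent annotation
  properties, exact core counts and clean module structure. Real
  annotation corpora are hierarchical and strongly overlapping, real
  effect-size estimates are noisy and study-confounded, and real networks
  have heavy-tailed degree distributions. Green tests demonstrate that
  the machinery detects the structure it is designed to detect and stays
  calibrated under exchangeable nulls — not that any particular real
  dataset would yield the same counts.
* The analysis consumes gene-level sets and pre-propagated annotations;
  no variant calling, ontology propagation, or differential-expression
  preprocessing is included.
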