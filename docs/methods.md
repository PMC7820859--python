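# Methods

This note documents the models, statistics and numerical choices behind
gsebench: what each component assumes, which parameters matter, and what the
synthetic data can and cannot tell you about real expression studies.

## Data model

An `ExpressionDataset` is a genes × samples matrix with a binary group
vector (each group ≥ 2 samples), an optional blocking vector (pairing or
batches), and a kind tag: `log_intensity` (microarray-style values, any
reals), `counts` (non-negative integers) or `tpm` (non-negative reals).
Gene identifiers are opaque strings matched exactly and case-sensitively
against gene set collections; datasets are assumed pre-summarized to gene
level, so probe-to-gene mapping and identifier conversion are out of scope.
Gene sets are intersected with a dataset's measured genes at method-run
time, not at load time, so one collection serves many datasets. Collections
are conventionally filtered to sizes 5–500 before testing
(`filter_by_size` defaults).

All gene-level contrasts are first-appearing group minus second-appearing
group; only absolute values and two-sided p-values enter the benchmark, so
the sign convention is internal bookkeeping.

## Gene-level statistics

For log-scale data with groups of sizes n₁, n₂ (pooled variance s², degrees
of freedom d = n₁+n₂−2, standard error se):

* **ordinary_t** — pooled-variance Student t; p from t(d).
* **moderated_t** — empirical-Bayes variance moderation. The gene variances
  are modeled as scaled-F around a prior variance s₀² with prior degrees of
  freedom d₀, fitted by method-of-moments on the log sample variances
  (digamma/trigamma moment equations; the trigamma equation is inverted by
  Newton iteration). Posterior variances `(d₀ s₀² + d s²)/(d₀ + d)` replace
  s²; p from t(d + d₀). When the log variances show no excess spread the
  prior is effectively infinite; we then collapse every variance to the
  geometric mean of the observed variances (no unbiasing factor), which
  makes the equal-variances case reduce *exactly* to the ordinary t — a
  deliberate choice of limit behavior over strict distribution-theory
  bookkeeping in a regime where the two differ by a vanishing constant.
* **sam_t** — `diff / (se + s₀)` with the fudge constant s₀ set to the
  median gene-wise standard error. The original percentile search for s₀ is
  intentionally not implemented; the median is a standard, deterministic
  simplification.
* **s2n** — signal-to-noise `(μ₁−μ₂)/(σ₁+σ₂)` (the classic GSEA ranking
  statistic).
* **logfc** — mean difference on the log2 scale.

With a blocking vector, statistics are computed on within-block mean
differences (one-sample analogues). Zero-variance genes get `nan`, are
flagged, and are removed before any method runs (with a warning).

`bh_adjust` implements Benjamini–Hochberg step-up natively (it is part of
the benchmark surface and is cross-checked in the tests against a
brute-force step-up and against statsmodels). DE calls use |log2 FC| > 1
and BH-adjusted p < 0.05 by default; a p-only criterion and nominal
thresholds are available.

## RNA-seq variance stabilization

Count matrices are transformed to moderated log2 counts-per-million before
any t-like statistic: for sample s with library size `L_s` and mean library
size `L̄`, a count c maps to
`log2((c + p·L_s/L̄) / (L_s + 2p·L_s/L̄) · 10⁶)`. The prior count p defaults
to `0.5 / φ̂` where φ̂ is the common negative-binomial dispersion, estimated
by method-of-moments: counts are scaled to the mean library size, each
gene/group contributes `(v − m)/m²` (from `var = μ + φμ²`), and the
estimates are averaged over genes with scaled mean > 5 — the mean threshold
keeps the Poisson noise term 1/m from dominating — then clipped at zero.
When φ̂ ≈ 0 (Poisson-like data) the prior falls back to 0.5, where no
moderation is needed. TPM input is log2(TPM+1)-transformed instead; raw
counts fed to any method are transformed automatically. The alternative
route of embedding count-model DE tools inside each permutation is not
implemented; the transformation route is the supported path.

## Enrichment methods

All methods share: intersection with the dataset universe (emptied sets
dropped with a warning), removal of constant genes, the empirical p-value
convention `p = (b+1)/(B+1)` (never exactly zero), block-restricted label
permutation when blocks are present, and a deterministic output ranking
(ascending p, ties by descending |set statistic|, then set id). Output
weights are the tie-aware rank weights computed from the p-value column.

* **ORA** — one-sided hypergeometric tail `P(X ≥ k)` for the overlap k of a
  DE gene list with each set, against the measured-gene universe. The
  registry adapter derives the DE list with the standard thresholds; if
  nothing passes, it falls back to nominal p < 0.05 (logged) so ORA stays
  applicable on weak datasets — an empty DE list as direct input is an
  error. Blocks enter only through the paired gene statistics.
* **GSEA** — genes ranked by s2n; ES is the maximum-deviation value of the
  weighted Kolmogorov–Smirnov running sum (hit increments ∝ |stat|^q,
  default q = 1 and exposed as a parameter; misses decrement 1/(N−N_hit);
  q = 0 gives the unweighted KS statistic). Significance is the two-sided
  sample-permutation p of |ES| — one consistent p per set rather than the
  original split positive/negative normalization, because the benchmark
  consumes a single ranking per method. If every member statistic is
  exactly zero the hit weights fall back to unweighted.
* **SAFE** — two-layer permutation framework; the local (per-gene)
  statistic is pluggable among the registered statistics, the global
  statistic is the Wilcoxon rank sum of the set genes' |local| values among
  all genes (midranks for ties). Upper-tail permutation p. A set spanning
  the whole universe has no background and is rejected.
* **PADOG** — gene weights `w_g = 1 + sqrt((f_max − f_g)/(f_max − f_min))`
  down-weight genes appearing in many sets (all 1 when frequencies are
  equal; genes outside every set get the maximal weight 2 by convention,
  though they never enter a set statistic). Set statistic: mean of
  `w_g·|moderated t|` over the set. Observed and per-permutation statistics
  are standardized across sets (mean 0, SD 1; skipped for < 2 sets) before
  the upper-tail p; fewer than 20 permutations triggers an instability
  warning.
* **CAMERA** — moderated t mapped through its CDF to normal z; set
  statistic is a two-sample t of set z-values vs background z-values with
  the set side inflated by `VIF = 1 + (m−1)ρ̄`; two-sided p from t(N−2).
  ρ̄ is fixed (default 0.01) or `"estimate"` — the mean pairwise correlation
  of within-group-centered residuals in the set, floored just above
  −1/(m−1) to keep the VIF positive. Singleton sets get VIF 1.
* **SAMGS** — sum over set genes of squared sam_t, upper-tail permutation
  p. The statistic is non-decreasing in set size on fixed data, which is
  exactly why self-contained tests exhibit set-size dependency. (Some
  descriptions label this statistic a Hotelling T²; the implemented form is
  the sum of squares of the regularized t statistics, which ignores the
  inter-gene covariance a full T² would invert.)

GLOBALTEST, GSA, ROAST and GSVA are registry stubs that raise
`NotImplementedError`: the registry shows how additional methods plug in
without pretending to implement them.

## Synthetic data

`simulate_expression` draws, in log-intensity mode, gene baselines
μ_g ~ N(7, 1) with unit Gaussian noise; DE genes (a rounded fraction of the
genes, at least one when the fraction is positive) get a mean shift
±effect_size with random sign. Count mode draws gene means log-normal
(meanlog 5, sdlog 1.5 — median ≈ 150 counts with a long right tail) and
counts NB(μ, φ) via gamma–Poisson mixing with a single common dispersion φ,
matching the common-dispersion estimator; the DE effect multiplies the
case-group mean by 2^(±effect_size). Defaults — 2000 genes, 15 samples per
group, DE fraction 0.3, effect size 1.0 (the conventional |log2 FC| = 1
threshold), φ = 0.1 — are chosen to sit inside the ranges reported for real
disease compendia, where DE fractions from near zero up to ~70% occur;
0.3 is a representative mid-range signal level, and assays that need a null
simply set the DE fraction to 0.

Within-block correlation: genes are partitioned into consecutive blocks
(default 20 genes) sharing a per-sample latent factor with loading
sqrt(ρ), giving pairwise correlation ρ within a block (exact on the
Gaussian scale; approximate, acting multiplicatively on log2 means, for
counts). The blocks are recorded in the truth object so tests can align
gene sets with correlated blocks — without this, correlation-aware behavior
(CAMERA's VIF) would be untestable.

`make_scenario` designates a fraction of sets as truly enriched (each
drawing 70% of members from the DE pool by default) and builds the
relevance ranking `S_p = 10·f_DE + |ε|` with half-normal noise (scale 1 by
default, i.e. 10% of the score scale), keeping scores non-negative like
real literature-derived composites. Zero noise makes the relevance order
exactly the true DE-fraction order; the noise model is a declared stand-in
— the error structure of real curated relevance rankings is unknown, so
nothing here is fitted to one.

What the generator does **not** emulate: array-specific noise (spatial,
saturation), library-size and GC biases, gene-length effects (relevant to
ORA on RNA-seq), single-cell zero inflation, and realistic pathway overlap
topology. Passing benchmarks on this data shows the machinery is correct
and calibrated under its stated model, not that any method is best on a
particular real study.

## Relevance scoring

Weights: `w = 1 − r*`, where r* is the fraction of sets whose ranking
statistic is at least as extreme ("smaller is extreme" for p-values,
"larger" for scores); tie-free this is `1 − r_A/N` and the weights sum to
(N−1)/2. The relevance score is `X = Σ w(i)·S_p(i)` over the sets shared
between the method ranking and the relevance ranking — sets present in only
one are dropped and weights recomputed on the intersection, since the sum
is defined over a single indexed universe and no other reconciliation rule
is canonical. The optimum `O_p` applies the same weight transformation to
S_p itself (so S_p ties are handled identically) and `X̄ = X/O_p`; a zero
optimum yields X̄ = 0 with a warning. An optional `top_fraction` restricts
evaluation to the top of the ranking by zeroing the weights below the
cutoff, leaving surviving weights unchanged.

Random-ranking null: scores of uniformly random orderings with tie-free
weights; enumerated exhaustively whenever `N! ≤ 10⁴` (deterministic and
strictly more accurate), otherwise sampled with the `(b+1)/(B+1)`
convention. The exact mean over all orderings is `((N−1)/(2N))·ΣS_p`,
verified by enumeration in the tests. Label-permutation null: the method is
re-run on label-shuffled data (within blocks) and each resulting ranking
scored; a failing permutation is dropped with a warning, more than 10%
failures aborts.

## Assays and aggregation

* **Type-I error**: shuffle group labels n times (default assay sizes:
  2000 genes × 30 samples, 100 random sets of 20 genes, 200 shuffles with
  100 internal permutations per shuffle — sizes chosen so the full
  six-method panel completes in a few minutes on one core while Monte-Carlo
  standard errors stay below ~0.5 percentage points); record the fraction
  of sets at nominal p < 0.05 per shuffle.
* **Set-size dependency**: random sets of sizes {5, 10, 25, 50, 100, 250,
  500}, 100 per size, run with true labels; the fraction significant per
  size exposes the self-contained size trend.
* **Runtime**: wall-clock around a single run; reported, never asserted.
* **Aggregation**: median and IQR of X̄ by method or by hypothesis type,
  with pairwise two-sided Wilcoxon rank-sum tests.

## Numerical conventions and degenerate inputs

* Empirical p-values always use `(b+1)/(B+1)`; parametric p-values are
  clipped to [0, 1]; CAMERA's t→z map clips tail probabilities at 10⁻¹⁵.
* Ranking order is fully deterministic (p, then |statistic|, then set id);
  seeded permutation methods are bitwise reproducible.
* All-equal statistics give all-zero weights (every set is "last"); a
  relevance evaluation against such a ranking scores 0.
* Degenerate sets: emptied by intersection → dropped with one counted
  warning per run; equal to the universe → error for competitive
  background-based methods; singleton → defined (CAMERA VIF 1).

## Limitations

Exact numerical parity with the original implementations of each method is
a non-goal (and not asserted anywhere): the re-implementations follow the
published statistics with the simplifications documented above. Pre-ranked
execution modes, rotation and single-sample scoring, network-based methods,
and real-compendium loaders are out of scope; the plugin registry is the
intended extension point. Raw relevance scores are not comparable across
phenotypes — only X̄ is.
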