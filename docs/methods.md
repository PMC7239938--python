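# Methods

This note records the models, defaults and numerical choices behind
`microvar`, and what the synthetic-cohort tests do and do not establish
about real data.

## Synthetic cohort generator

The generator emulates a two-visit amplicon cohort: `n_hosts` (default 185)
hosts sampled at `n_timepoints` (default 2) time points, `n_taxa` (default
200) taxa of which `n_core_taxa` (default 30) form a prevalent core, and
per-sample read depth uniform on `depth_range` (default 10,000–60,000, the
depth range after which real tables are typically rarefied to 10,000).

Counts are Dirichlet-multinomial. A log-scale composition is assembled per
sample from four pieces:

* a base abundance per taxon — core taxa uniform on log(1.5%)–log(5%), so
  the core accounts for the large majority of reads, matching the empirical
  observation that a few dozen core genera carry ≥75% of sequences; rare
  taxa log-normal around 0.08%;
* a host × taxon signature, normal with SD `host_sd` (default 1.0) for rare
  taxa and `host_sd × core_stability` (default factor 0.35) for core taxa —
  prevalent taxa are the stable ones, rare taxa carry the inter-host
  variability, which reproduces the between-host ≫ within-host divergence
  pattern;
* a per-taxon time shift at the second visit, normal with SD
  `time_shift_sd` (default 0.3, attenuated for core taxa);
* a presence indicator for rare taxa: present at baseline with probability
  `rare_prevalence` (default 0.4) and flipped between visits with
  probability `rare_turnover` (default 0.3) — the high-turnover rare
  fraction.

The softmax of the sum is perturbed by a Dirichlet draw with concentration
`overdispersion` (default 150; `inf` disables compositional noise) and
sampled multinomially at the drawn depth. One global seed expands through
`numpy` seed sequences into independent streams for counts, tree and
phenotypes, so stages can be regenerated independently; everything is
bit-reproducible under a fixed seed.

The phylogeny is a pure-birth (Yule) tree from `dendropy` with leaves
relabelled to the table's taxon ids. Host kinship is block-diagonal by
breed: 1 on the diagonal, 0.25 within breed — breed is the only genetic
structure in the design, so this is the natural one-parameter kinship.

Phenotypes are drawn from the microbiability model itself: the microbial
effect uses the kernel computed from the *generated* table (so estimation is
correctly specified), with variances scaled so σ²_m : σ²_H : σ²_e =
`true_m2` : `true_h2` : remainder (total 1). Behaviour-frequency versions
map the standardized latent value through a logistic link into (0, 1); the
distributional form of behaviour indicators is a modelling convenience —
downstream analysis consumes the continuous scale.

What the generator does **not** emulate: sequencing error and chimeras,
compositional correlations between specific taxa pairs, phylogenetic
signal in abundances (tree and abundances are independent), seasonal or
dietary covariates, and hosts entering/leaving the cohort. Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated model, not robustness to those real-data features.

## Feature-table operations

* **Rarefaction** is an exact multivariate-hypergeometric subsample (without
  replacement) to the target depth; samples below depth are dropped and
  logged, never silently removed.
* **CSS-log**: per sample the scaling factor s_j is the cumulative count up
  to the sample's median nonzero count (quantile configurable); values are
  log2(count / s_j · S + 1) with S the across-sample median of s_j.
  The fixed 0.5 quantile (rather than the adaptive quantile search of the
  original CSS method) is chosen for reproducibility; the pre-pseudocount
  form count/s_j is exactly invariant to per-sample scaling, and the +1
  pseudocount keeps zeros at exactly 0.
* **Core detection** defaults to detection 0.1% and prevalence 99% per time
  point, intersected across time points. The stricter 99.9% prevalence is
  available as an argument; with a few hundred hosts, 99% vs 99.9% is the
  difference between tolerating one low sample per taxon or none.
* **Aggregation** pools taxa unclassified at the requested rank into one
  `unclassified_<parent>` bucket per deepest classified parent and conserves
  total reads.

## Diversity

Shannon entropy uses the natural log. Chao1 is the bias-corrected form
S + F1(F1−1)/(2(F2+1)), defined also for doubleton-free samples. Fisher's α
solves S = α·ln(1 + N/α) by bracketed Brent root-finding (xtol 1e-12); when
every read is its own taxon there is no finite solution and `inf` is
returned with a warning. Bray–Curtis on an all-zero pair is undefined and
reported as 0 with a warning. UniFrac (unweighted, and weighted in the
normalized [0,1] variant by default) is delegated to scikit-bio over a
rooted tree; on a star tree with equal branch lengths the weighted
normalized form reduces exactly to Bray–Curtis on relative abundances,
which the tests assert to 1e-9.

Group dispersion embeds the distance matrix by principal coordinates
keeping negative eigenvalues; squared distances to the group centroid are
corrected by subtracting the "imaginary" axes' contribution (clipped at 0),
the standard treatment for non-Euclidean dissimilarities. The F statistic
on those distances is tested by recomputing centroids and distances under
full label permutations (999 by default). The statistic agrees with
scikit-bio's `permdisp(test="centroid")` to machine precision.

## Permutation inference

All permutation p-values use the add-one estimator
(1 + #{perm ≥ obs}) / (1 + n_perm) and lie in (0, 1].

* **PERMANOVA** partitions the trace of the Gower-centered squared-distance
  matrix by *sequential* (Type-I) sums of squares in the user's term order;
  pseudo-F uses the residual mean square; effect sizes SS_term/SS_total plus
  the residual sum to 1. Permutations (default 10,000) act on sample labels,
  optionally within strata — for repeated measures, permuting time within
  host is the exchangeable scheme. Permutations are evaluated in vectorized
  batches (one einsum per cumulative design basis), so 999 permutations on a
  20-sample matrix cost ~8 ms. Term order matters under sequential SS; put
  nuisance terms (breed) before the term of interest (time).
* **ANOSIM** uses midrank-tied distance ranks; R = (r̄_between −
  r̄_within) / (n(n−1)/4). Equality with an exhaustive pair-by-pair oracle is
  asserted on all instances with n ≤ 8.
* **SIMPER** averages |x_ik − x_jk| / Σ_m(x_im + x_jm) over between-group
  pairs and normalizes contributions to sum to 1.
* **NMDS** minimizes Kruskal stress-1 by alternating isotonic (pool-adjacent-
  violators) regression of configuration distances on dissimilarity order
  with a Guttman update; best of 20 random starts (vegan-comparable
  robustness), stress trajectory exposed and non-increasing; non-convergence
  is flagged on the result, not raised.
* **Covariate fitting** follows the envfit convention: r² of the covariate
  regressed on the ordination scores (continuous) or 1 − SS_within/SS_total
  of the scores by level (categorical), permutation p per covariate and BH
  adjustment across the covariates of one call. The reported combined effect
  size is the sum of r² over covariates with adjusted p < 0.05; r² of
  correlated covariates are not additive, so this sum is labelled
  non-orthogonal and should be read as an upper summary, not a variance
  decomposition.
* **Cross-correlation** computes the full genera × phenotype Pearson (or
  Spearman) grid with one BH family over all defined cells; cells with < 3
  complete pairs or zero variance are excluded from the family and flagged.

## Enterotyping

PAM is the BUILD + best-improvement SWAP algorithm with ties broken by
lowest sample index; because SWAP is a local search, the BUILD start is
supplemented by 9 seeded random restarts and the best local optimum kept —
on all instances with n ≤ 7 the result matches exhaustive enumeration over
medoid subsets. Silhouettes use the usual (b−a)/max(a,b) with s(i) = 0 for
singleton clusters; k is selected over 2–10 by maximum mean silhouette, and
SC > 0.5 is the "reasonable structure" rule — structure-free communities
stay below it in ≥95% of seeds, the qualitative no-enterotype outcome.

## Microbiability

The kernel is M = WW′/k from the column-centered CSS-log matrix W, rescaled
to mean diagonal 1 so σ²_m is on the phenotypic-variance scale; a minimal
diagonal jitter is recorded if round-off produces a negative eigenvalue.

The Gibbs sampler draws, in turn: fixed effects from their flat-prior
normal conditional; the microbial effect in the eigenbasis of M, where its
full conditional is diagonal (components with zero eigenvalue are pinned at
0); the host effect (when a kinship is supplied) from its joint normal
conditional via a Cholesky solve at host level; and the variances from
their conditionals. Without a kinship the whole model is rotated once into
the eigenbasis, making a full sweep O(n); the unrotated route is retained
and the two agree within Monte-Carlo error (tested).

**Variance priors.** The default prior on each variance component is flat
(uniform on σ²), giving conditionals σ² = quad/χ²_(df−2). With ~100
informative kernel eigencomponents and hundreds of residual degrees of
freedom the posterior is proper and data-dominated. A scaled-inverse-χ²
prior is available via `MixedModelSpec(nu=..., prior_var_fraction=...)`, but
is *not* the default for a measured reason: its density vanishes like
exp(−νS²/2σ²) as σ² → 0, so any scale S² of the order of var(y) forbids
posteriors near zero — under a true m² = 0 the posterior mean then cannot
drop below ~0.1, i.e. the null becomes unestimable. With the flat prior,
null cohorts (n = 300) give posterior means ≈ 0.04 and recovery at true
m² ∈ {0.1, 0.25, 0.4} (n = 400, 100 taxa) is unbiased to within ~0.03 with
95%-interval coverage at nominal level. The sampler guards the flat prior
by requiring ≥5 informative components.

Chain defaults are 30,000 iterations, 2,000 burn-in, thinning 10.
Diagnostics are the effective sample size and split-chain R̂ of the m²
chain (one chain split in half, via arviz); an ESS below 100 is logged as a
warning. The degenerate case M = I (microbial and residual variance
unidentifiable — only their sum is) manifests exactly there: the fit
completes but reports a very low ESS rather than failing silently.

Two m² definitions are computed from the same draws: `total`
(σ²_m over the total phenotypic variance; bounded in [0, 1]; the default)
and `exclusive` (σ²_m/(σ²_H + σ²_e), a heritability-style ratio that can
exceed 1). The bounded form is the default because a "fraction of
phenotypic variance" reading requires the full denominator.

Repeated measures enter the model as two records per host with time as a
fixed effect; the per-host correlation induced by the shared microbiome is
carried by M itself. When a host-genetic signal is of interest, supply the
kinship; otherwise host-level variance not captured by M is absorbed into
the residual.

## Problem sizes used in the checks

The end-to-end recovery experiments use cohorts of 400 samples × 100 taxa
(10 replicates per m² level) and 300 samples for the null — large enough
that the kernel carries real information about the variance ratio, small
enough that the full suite completes in minutes. Permutation-test
calibration uses 500 structure-free replicates at 999 permutations each;
the enterotype null uses 100 seeds at 50 samples. The recovery and null
experiments simulate with `true_h2 = 0`: they measure recovery of the
microbial component in isolation, since host-genetic variance shared by a
host's two samples is partially absorbed by the microbial kernel when the
kinship term is omitted — mixing the two effects would confound the bias
measurement. The kinship path is exercised separately.
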