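# microvar

Statistics for longitudinal gut-microbiota cohorts: from a samples × taxa
count table and host metadata to core-microbiota detection, α/β-diversity
dynamics, permutation-based community inference, enterotype (community-type)
clustering, taxon–phenotype association, and Bayesian estimation of
**microbiability** — the fraction of host phenotypic variance attributable to
gut community composition.

The package is written for animal-cohort studies of the kind where ~200
hosts are sampled at two time points by 16S amplicon sequencing and scored
for behavioural and hematological phenotypes. Because such cohorts are rarely
re-distributable, `microvar` ships a synthetic-cohort generator with known
ground truth (host-specific signatures, core/rare taxon structure, a time
shift, and phenotypes drawn from the microbiability model itself), so that
every stage of the pipeline — including recovery of the true m² — is testable
without any download.

## The model at the core

Phenotypes are analysed under the linear mixed model

```
y = Xβ + u_m + u_g + ε,
u_m ~ N(0, σ²_m M),   u_g ~ N(0, σ²_H K),   ε ~ N(0, σ²_e I)
```

where `X` holds the fixed effects (intercept, breed, discipline, time point),
`M` is the **microbial relationship matrix** — the sample × sample covariance
of the CSS-normalized, log-transformed count table, scaled to mean diagonal 1
— and `K` an optional host kinship. Posterior draws of the variance
components come from a Gibbs sampler (default 30,000 iterations, 2,000
burn-in, thinning 10) run in the eigenbasis of `M`, where the microbial
effect's full conditional is diagonal and one sweep costs O(n). Per draw,

```
m² = σ²_m / (σ²_m + σ²_H + σ²_e)
```

so every m² draw is a variance fraction in [0, 1]; the heritability-style
ratio σ²_m / (σ²_H + σ²_e) is available as `definition="exclusive"`.

Around that core, the package implements the standard community-ecology
toolkit at the variants used in cohort practice: rarefaction and CSS-log
normalization, core detection by joint detection/prevalence thresholds
(default 0.1% detection in ≥99% of samples per time point, intersected),
observed/Chao1/Shannon/Fisher-α diversity, Bray–Curtis and UniFrac distances,
betadisper-style dispersion, PERMANOVA with sequential sums of squares and
within-host permutation strata, ANOSIM, SIMPER, NMDS (Kruskal stress-1),
envfit-style covariate fitting, Δ(T2−T1) construction, genera × phenotype
cross-correlation with Benjamini–Hochberg correction, and PAM enterotyping
with silhouette-based selection of k (SC > 0.5 = "reasonable structure").

## Worked example

```python
import microvar as mv

cfg = mv.CohortConfig(n_hosts=60, n_taxa=100, n_core_taxa=20,
                      depth_range=(10_000, 20_000), true_m2=0.25, seed=42)
cohort = mv.simulate_cohort(cfg)

core = mv.core_microbiota(cohort.table, groups=cohort.metadata["timepoint"])
dm = mv.bray_curtis(mv.relative_abundance(cohort.table))
host_effect = mv.anosim(dm, cohort.metadata["host_id"], n_perm=999, seed=0)
best, _ = mv.select_k(dm, range(2, 8))
report = mv.run_microbiability(cohort.table, cohort.metadata,
                               ["behaviour"], seed=1)
```

prints, through the obvious `print` statements:

```
core genera detected: 18 (designated: 20)
ANOSIM by host: R = 0.727, p = 0.0010
PERMANOVA timepoint: R2 = 0.0268, p = 0.0010
enterotyping: best k = 2, SC = 0.040, reasonable structure = False
microbiability: m2 = 18.8% +/- 11.7% (95% CI 1.9-45.9%), ESS = 428
```

Reading the output: 18 of the 20 taxa designated as core by the generator
pass the strict detection/prevalence rule in this 120-sample cohort; the
strong host signature (ANOSIM R = 0.73) coexists with a small but significant
time shift (PERMANOVA R² ≈ 0.03); the silhouette coefficient stays far below
0.5, i.e. the samples do not fall into enterotype-like clusters; and the
posterior mean m² of 18.8% brackets the simulated truth of 25% within a wide
credible interval — at 120 samples the kernel carries limited information
about a variance ratio, which is exactly what the interval says.

Every stage is also exposed as a CLI (`microvar simulate|features|diversity|
infer|enterotype|microbiability`); outputs are plain TSV and byte-identical
under a fixed `--seed`.

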