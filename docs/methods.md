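# Methods notes

## Scope and model

The package implements the analysis chain of a multi-cohort methylome-wide
association study (MWAS) of a binary phenotype. The unit of evidence is a
per-probe standardized mean difference between cases and controls,
estimated per cohort and pooled by fixed-effect inverse-variance
meta-analysis stratified by array generation. Downstream consumers of the
pooled table are region calling, threshold-indexed methylation scores, a
proteomic association scan, heterogeneity diagnostics and bidirectional
two-sample Mendelian randomization (MR).

All association models run on M values, log2 of the methylated/
unmethylated intensity ratio; M = logit2(β) for a methylation fraction β.
On the M scale probe variances are approximately stable across the (0,1)
β range, which justifies homoscedastic least squares.

### Cohort association model

For each probe, M values are regressed on case status with covariates:

* `basic` — age (years), sex, batch (one-hot, first level reference),
  optional methylation principal components, and blood-cell proportions.
  Granulocytes are dropped from the five estimated proportions because
  compositions sum to one; their effect is absorbed by the intercept and
  the four retained proportions.
* `ahrr` — adds the M value of the smoking-responsive AHRR probe
  (cg05575921), a validated proxy for current smoking. When that probe is
  itself the outcome it is removed from its own covariate set.
* `complex` — adds BMI (kg/m²) and weekly alcohol units; cohorts lacking
  them raise an error rather than silently downgrading the model.

The phenotype t statistic is converted to Cohen's d by
`d = t·(n1+n2)/(√(n1·n2)·√df)`, `se(d) = d/t` (the multiplier itself at
t = 0). The conversion makes effect sizes comparable across cohorts with
different sizes and case fractions; p-values come from the t distribution
with the model's residual degrees of freedom, so `p` recomputed from
`d/se(d)` with the same df matches the regression p exactly.

Zero-variance probes are skipped and listed in the result's
`attrs["skipped_probes"]`; a design matrix with condition number above
1e10 (after column standardization) is an error naming the offending
columns. Genomic inflation is summarized as
λ = median(χ²₁(1−p))/0.4549364.

### Meta-analysis

Stage 1 pools studies within each array after probe filtering; stage 2
pools the two array summaries. Because inverse-variance weighting is
associative, the staged result equals a single pooled pass — this identity
is tested to 1e-12 — and the staging exists only so the availability
filters can be applied per array:

* presence — kept if available in strictly more than half of the array's
  studies ("more than half" is read literally: 3 of 6 fails, 4 of 6
  passes);
* sample size — kept if its summed analyzed n is at least 80% of the
  array's maximum possible n (inclusive ≥ by default; `n_rule_strict`
  switches to a strict reading of "over 80%");
* records with se > 0.5 are removed before either test. The study count
  and maximum n in the denominators come from the *unfiltered* study set:
  a study censored by the se ceiling still counts toward "half of the
  studies using the given array".

No genomic-control correction is applied at either stage. Bonferroni uses
m = the number of probes in the final pooled table; BH-FDR q-values are
computed over the same family via `statsmodels.stats.multitest`.

### DMR calling

Candidates are maximal runs of position-sorted probes on one chromosome
with consecutive gaps ≤ 500 bp, all pooled p < 0.05, one effect sign. The
500 bp figure bounds the gap between consecutive probes (the convention of
region-callers built on summary statistics); a span-based mode is available
behind `span_mode=True`. Minimum region size defaults to 2 probes.

Members are pooled by generalized least squares with covariance
`se_i·se_j·ρ_ij`. With identity ρ this reduces exactly to IVW; with ρ → 1
between identical members the pooled statistic degenerates to the single
member (no information gain), both verified in tests. ρ is estimated as
the Pearson correlation of member probes across samples of a supplied
M-value matrix, shrunk by 0.1% toward the identity so sampling noise
cannot break positive-definiteness; with no matrix supplied the identity
is used.

The multiple-testing family counts each multi-probe region plus every
probe not absorbed into one — i.e. the whole pooled table participates as
either a regional or a single-site test. This matters: region members are
*selected* at nominal significance, so a two-probe null candidate already
has pooled p < 0.0056 by construction, and correcting only over candidates
and sub-threshold singletons would inflate the region-level family-wise
error severely. Correcting over the full table keeps null consortia clean
(tested: ≥19/20 null runs with zero significant DMRs). The stricter count
treating 2-probe regions as single sites is reported in
`attrs["m_tests_gt2"]` since region-size conventions differ between
tools.

### Methylation scores and the proteomic arm

Weights are pooled effect sizes at five inclusion thresholds
(1, 0.01, 0.001, 1e-6, 5e-8); weight sets are nested by construction. The
score is Σ_j w_j·M_js over available weighted probes (missing probes are
skipped with a logged count; zero overlap is an error). For evaluation the
score is residualized on age, sex and the AHRR probe and standardized;
association with diagnosis is reported three ways: the linear-model
coefficient with the score as dependent variable (the orientation used
when a score is profiled against a diagnosis), the Mann–Whitney AUC of the
residualized score, and the two-group Cohen's d. Cell proportions are not
included in the evaluation model by default; callers can add any covariate
column.

Proteins with strictly more than 40% of samples below the assay's lower
limit of detection are removed ("over 40%" is strict, so a protein at
exactly the boundary is retained). Retained abundances are rank-based
inverse-normal transformed with Blom offsets, Φ⁻¹((r−3/8)/(n+1/4)), with
average ranks for ties, residualized on technical covariates, regressed on
the score, and BH-FDR corrected across retained proteins.

### Heterogeneity

Leave-one-out repeats the full array-stratified meta-analysis k times; the
IVW recombination of (left-out study, pooled rest) reproduces the full
result to 1e-10, which is the module's internal consistency check. The age
meta-regression is a mixed-effects model of study-level d estimates on
cohort mean age with known sampling variances se² and a residual
between-study variance τ² estimated by restricted maximum likelihood
(bounded scalar optimization of the REML criterion); the moderator is
tested with a normal Wald statistic, and at τ² = 0 the fit reduces to
inverse-variance weighted least squares. Concordance metrics are
effect-direction agreement (zero effects count as non-concordant and are
logged) and pairwise Pearson correlations of effect sizes over a top-k
probe list chosen from a reference study by p with probe-id tie-break.

### Mendelian randomization

Forward: the instrument for a CpG is the most significant cis mQTL within
1 Mb at p < 5 × 10⁻⁸, ties broken by larger |β| then SNP id. The causal
estimate is the Wald ratio β_out/β_exp with first-order delta-method
standard error se_out/|β_exp|; the second-order variant propagating the
exposure se is available (`second_order=True`) but not default, matching
the common single-instrument convention. Reverse: trait GWAS records are
greedily clumped by ascending p (kept unless an already-kept SNP within
1 Mb has r² > 0.001; deterministic under ties and invariant to input
order), and per-SNP ratios on each CpG are pooled by fixed-effect IVW,
which reduces to the plain Wald ratio for a single instrument. Allele
harmonization flips swapped labels (negating the outcome β), resolves
strand complements, and drops palindromic SNPs with effect-allele
frequency in [0.42, 0.58] — the band where strand cannot be resolved.
Every estimate is invariant to flipping any record's allele labels with
its β sign, verified exactly.

## Synthetic data: what it emulates and what it does not

Defaults reproduce the shape of an 18-study depression methylation
consortium: 24,754 samples, 5,443 cases, per-study sizes 186–9,502, case
prevalences 6–86%, mean ages 15–59, eight 450K and ten EPIC studies, with
the EPIC probe set a strict superset of the 450K set. Three studies lack
BMI/alcohol so the fully adjusted model runs on a reduced consortium, as
in real consortia. The probe dimension is reduced to a few thousand so a
full run takes seconds to minutes; every structural feature that the
pipeline's correctness depends on (arrays, filters, confounding,
correlated regions) is preserved at that scale.

M values are Gaussian: baseline_j + d_j·σ·case + Σ_c loading_cj·covariate
+ ε, ε ~ N(0, σ²), with each confounder loading on a random 10% of probes
with random sign. Smoking liability is N(0,1) + 0.3·case, and the
designated AHRR-like probe tracks −liability, so smoking is a genuine
confounder whose adjustment is consequential. Probes in planted DMR blocks
share a noise factor (ρ = 0.6 by default) and a common effect. Genotypes
are binomial(2, MAF) under Hardy–Weinberg; the mQTL module plants linear
SNP→CpG and CpG→liability slopes with genomic positions placed inside or
outside the 1 Mb cis window on request. The protein generator censors a
configured fraction of proteins so that strictly more than 40% of their
values sit below a limit of detection (22 of 92 by default, leaving 70
after filtering).

A single master seed spawns one stream for the shared probe universe and
loadings plus one stream per cohort, so each cohort is reproducible
independent of cohort order; identical (config, seed) reproduces
byte-identical output.

Not emulated: realistic beta-value distributions (bimodality, probe-type
chemistry), chip/plate layouts, family relatedness, population structure,
unmeasured (surrogate-variable-style) confounding, LD beyond the supplied
r² matrix, and non-linear dose effects. Passing tests therefore
demonstrate the pipeline's arithmetic, filtering, error control and power
under the planted linear-Gaussian conditions — not robustness to the
full messiness of array data.

## Numerical choices and toy-scale caveats

* Principal components are exact SVD below 500 samples/probes and
  deterministic randomized SVD (scikit-learn, fixed random_state, 7 power
  iterations) above; the component sign is fixed by making the
  largest-magnitude loading positive.
* At desk-scale probe counts, PCs estimated from the analyzed matrix
  absorb a noticeable share of per-probe noise and any planted correlated
  block (a 3-probe block is a leading variance direction among a few
  thousand probes, which it never is among 763,265). Simulation studies in
  the test-suite and the acceptance run therefore adjust for the measured
  confounders directly (`n_pcs=0`) — the generator plants no unmeasured
  structure for PCs to capture. The PC path has its own unit tests
  (orthogonality, variance ordering, factor-subspace recovery).
* Pooled p-values are floored at the smallest positive double; Bonferroni
  caps at 1.
* Region correlation matrices are shrunk 0.1% toward the identity before
  Cholesky.
* Monte-Carlo tests assert at binomial critical values rather than point
  expectations: a ±2·se coverage claim is tested at ≥16/20 (the lower tail
  of binomial(20, 0.95)), and the null family-wise error claim at ≤3/20
  runs with any hit (one-sided binomial(20, 0.05) test), because 20
  replicates estimate a 5% rate with large sampling error.
* Problem sizes in the acceptance script — 18 cohorts at full sample
  sizes, 3,600 probes, 15 planted probes at d = 0.2, three 3-probe blocks
  at d = 0.25, mQTL chain at n = 50,000 — were chosen so every stage shows
  non-trivial behaviour (partial power, non-empty filters) while a full
  run stays under a minute on one CPU.

## Known limitations

* Fixed-effect pooling only; no random-effects model, Cochran's Q or I².
* The Wald-ratio se ignores exposure uncertainty by default
  (weak-instrument bias is not corrected; instruments in the simulations
  are strong).
* The clumping loop is quadratic in the number of significant records and
  expects a dense r² matrix; it is not meant for genome-wide GWAS input.
* `reverse_mr` pools per-SNP ratios by IVW, which assumes instrument
  independence — guaranteed by clumping at r² ≤ 0.001, not re-checked.
* The score classifier reports association statistics, not a calibrated
  risk model; no penalized training is implemented.
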