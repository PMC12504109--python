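# ewaskit

A meta-analysis toolkit for methylome-wide association studies (MWAS) of a
binary phenotype, built around the design used by large DNA-methylation
consortia for major depression: many case–control cohorts of very different
sizes and case prevalences, profiled on two Illumina array generations
(450K and EPIC), analysed per cohort and pooled by fixed-effect
inverse-variance meta-analysis, with downstream region calling, methylation
risk scores, proteomic follow-up, heterogeneity diagnostics and
bidirectional Mendelian randomization.

It is aimed at epigenetic epidemiologists who want a tested, reproducible
implementation of this pipeline, and at methodologists who want to study
its operating characteristics on synthetic consortia with known ground
truth.

## What it computes

**Cohort MWAS** (`ewaskit.mwas`). For each probe j in cohort s, ordinary
least squares of M values (M = log2 β/(1−β)) on case status with covariates
(age, sex, batch, cell proportions, optionally methylation PCs, the
smoking-responsive AHRR probe cg05575921, BMI and alcohol). The phenotype
t statistic is converted to a standardized mean difference,

    d = t (n1 + n2) / (√(n1 n2) √df),   se(d) = d / t,

so effect sizes are comparable across cohorts.

**Meta-analysis** (`ewaskit.meta`). Per array, probes are kept if present
in more than half of that array's studies or carrying ≥80% of its maximum
sample size; records with se > 0.5 are dropped. Fixed-effect
inverse-variance pooling (w_i = 1/se_i², β = Σwβ/Σw, se = 1/√Σw) runs
within each array and then across the two array summaries — associativity
makes this equal to a single pooled pass. No genomic-control correction is
applied. Bonferroni (α/m over the pooled table) and Benjamini–Hochberg
q-values are reported; at the full 450K+EPIC methylome (m = 763,265) the
family-wise threshold is 6.55 × 10⁻⁸.

**DMR calling** (`ewaskit.dmr`). Runs of probes within 500 bp of each
other, all at meta p < 0.05 with one effect sign, are pooled by generalized
inverse-variance weighting with covariance se_i·se_j·ρ_ij (ρ estimated from
an M-value matrix when available), Bonferroni-corrected over regions and
remaining single sites together.

**Methylation scores** (`ewaskit.score`). Per-individual weighted sums of M
values using meta-analysis effect sizes as weights at five p-value
thresholds (1, 0.01, 0.001, 10⁻⁶, 5 × 10⁻⁸), evaluated out of sample by
Mann–Whitney AUC, two-group Cohen's d and a covariate-adjusted linear
model; plus a protein-wide association scan against a multiplex panel with
a lower-limit-of-detection filter, rank-based inverse-normal transform and
FDR correction.

**Heterogeneity** (`ewaskit.heterogeneity`). Leave-one-out re-pooling,
REML mixed-effects meta-regression of study effects on cohort mean age,
effect-direction concordance and pairwise between-study effect-size
correlations.

**Mendelian randomization** (`ewaskit.mr`). Forward: per CpG, the most
significant cis mQTL (±1 Mb, p < 5 × 10⁻⁸) instruments the Wald ratio
β_outcome/β_exposure with delta-method se. Reverse: trait GWAS hits are
LD-clumped (p ≤ 5 × 10⁻⁸, 1 Mb, r² ≤ 0.001) and per-SNP ratios pooled by
IVW. Alleles are harmonized (swaps flipped, ambiguous palindromic SNPs
dropped); FDR across tested CpGs.

**Synthetic consortia** (`ewaskit.synthetic`). A generator emulating an
18-study consortium (24,754 samples, 5,443 cases, prevalences 6–86%, mixed
450K/EPIC) with planted case–control effects, correlated DMR blocks,
additive confounding (age, sex, batch, cell composition, smoking, BMI,
alcohol), SNP→CpG→liability chains and a 92-plex protein panel — every
planted parameter is returned as ground truth.

## Worked example

```python
import ewaskit as ek
from ewaskit.synthetic import CohortSpec, SimulationConfig, simulate_consortium

config = SimulationConfig(
    cohorts=tuple(
        CohortSpec(f"study{i}", 800, 0.3, "A450" if i % 2 else "EPIC")
        for i in range(6)
    ),
    n_probes_shared=2000, n_probes_epic_only=400,
    n_causal_probes=10, effect_size_d=0.3, seed=7,
)
cohorts, truth = simulate_consortium(config)
stats = [ek.run_probe_regression(c, model="ahrr", n_pcs=0) for c in cohorts]
meta = ek.two_stage_meta(stats)
hits = meta[meta["p"] < 0.05 / len(meta)].sort_values("p")
```

The top of `hits` for this seed:

```
     probe chr     pos      beta       se            p  p_bonferroni  n_total  k_studies direction
cg00001565   3 1271520  0.331289 0.031716 1.536049e-25  3.686517e-22     4800          6    ++++++
cg05575921   7   10162 -0.327826 0.031696 4.506575e-25  1.081578e-21     4800          6    ------
cg00000441   9  431138  0.327231 0.031716 5.867970e-25  1.408313e-21     4800          6    ++++++
cg00000836  19  650186  0.316377 0.031716 1.953620e-23  4.688688e-20     4800          6    ++++++
cg00001208  11  913229  0.315216 0.031716 2.822927e-23  6.775025e-20     4800          6    ++++++
```

Eleven probes pass the Bonferroni threshold: all ten planted probes
(estimates near the planted d = 0.3, consistent '+' direction in all six
studies), plus the AHRR smoking-proxy probe cg05575921 — negative, because
the generator couples smoking liability to case status, so the
smoking-responsive probe is genuinely hypomethylated in cases. `beta` is on
the Cohen's d scale, `se` its standard error, `p_bonferroni` the
family-wise adjusted p over the 2,400 pooled probes, and `direction` the
per-study effect signs.

A command-line interface wraps the same stages:

```bash
ewaskit run-all --seed 7 --out-dir runs/demo      # simulate → mwas → meta → dmr/score/het/mr
ewaskit simulate --seed 7 --out-dir runs/cohorts  # cohort TSVs + ground-truth JSON
```

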