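"""Between-study heterogeneity: leave-one-out, age meta-regression and
effect-size concordance.

Leave-one-out repeats the full array-stratified meta-analysis k times,
dropping one study per iteration, to expose results that hinge on a single
cohort.  The age meta-regression fits a mixed-effects model of study-level
standardized coefficients on the cohort mean age, with known sampling
variances and a between-study variance (tau^2) estimated by restricted
maximum likelihood.  Concordance between two sets of summary statistics is
reported as matching effect directions and as Pearson correlations of
effect sizes over a top-k probe list from a reference study.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .meta import MetaConfig, two_stage_meta

__all__ = [
    "MetaRegressionResult",
    "leave_one_out_meta",
    "meta_regression_age",
    "direction_concordance",
    "top_probes",
    "pairwise_effect_correlation",
]

logger = logging.getLogger(__name__)


@dataclass
class MetaRegressionResult:
    """Moderator fit of study effects on cohort mean age."""

    coefficient: float  # per year of mean age
    se: float
    p: float
    tau2: float  # REML between-study variance
    k: int


def leave_one_out_meta(
    stats_by_study, probes=None, config: MetaConfig | None = None
) -> pd.DataFrame:
    """Re-pool the consortium k times, leaving each study out once.

    Returns one row per (probe, left-out study) with the pooled beta, se
    and p of the remaining studies; exactly k rows per probe that survives
    filtering in every iteration.
    """
    if len(stats_by_study) < 2:
        raise ValueError("leave-one-out requires at least 2 studies")
    frames = []
    for i, left_out in enumerate(stats_by_study):
        rest = [s for j, s in enumerate(stats_by_study) if j != i]
        pooled = two_stage_meta(rest, config)
        if probes is not None:
            pooled = pooled[pooled["probe"].isin(probes)]
        pooled = pooled[["probe", "beta", "se", "p"]].copy()
        pooled["left_out"] = left_out["study_id"].iloc[0]
        frames.append(pooled)
    out = pd.concat(frames, ignore_index=True)
    return out[["probe", "left_out", "beta", "se", "p"]]


def _reml_neg_loglik(tau2, y, v, x) -> float:
    w = 1.0 / (v + tau2)
    xtwx = x.T @ (w[:, None] * x)
    beta = np.linalg.solve(xtwx, x.T @ (w * y))
    r = y - x @ beta
    sign, logdet = np.linalg.slogdet(xtwx)
    return 0.5 * (np.sum(np.log(v + tau2)) + logdet + np.sum(w * r**2))


def meta_regression_age(
    per_study_beta, per_study_se, mean_ages
) -> MetaRegressionResult:
    """Mixed-effects meta-regression of study effects on cohort mean age.

    Sampling variances are taken as known (``se^2``); the residual
    between-study variance tau^2 is estimated by REML and the moderator
    coefficient tested with a normal (Wald) z statistic.  With tau^2 at
    zero the fit reduces to weighted least squares with inverse-variance
    weights.
    """
    y = np.asarray(per_study_beta, dtype=float)
    s = np.asarray(per_study_se, dtype=float)
    ages = np.asarray(mean_ages, dtype=float)
    k = len(y)
    if k < 3:
        raise ValueError("meta-regression requires at least 3 studies")
    if np.all(ages == ages[0]):
        raise ValueError("zero moderator variance: mean ages are all equal")
    if np.any(s <= 0):
        raise ValueError("all standard errors must be > 0")
    v = s**2
    x = np.column_stack([np.ones(k), ages])

    upper = max(10.0 * float(np.var(y)), 10.0 * float(np.max(v)), 1e-6)
    res = optimize.minimize_scalar(
        _reml_neg_loglik, bounds=(0.0, upper), args=(y, v, x), method="bounded"
    )
    tau2 = float(res.x) if res.x > 1e-12 else 0.0

    w = 1.0 / (v + tau2)
    xtwx = x.T @ (w[:, None] * x)
    cov = np.linalg.inv(xtwx)
    beta = cov @ (x.T @ (w * y))
    coef = float(beta[1])
    se = float(np.sqrt(cov[1, 1]))
    z = coef / se
    p = float(max(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny))
    return MetaRegressionResult(coefficient=coef, se=se, p=p, tau2=tau2, k=k)


def direction_concordance(stats_a: pd.DataFrame, stats_b: pd.DataFrame, probes) -> tuple[int, float]:
    """Count matching effect directions over a probe list.

    Returns ``(n_concordant, percent)`` with the percentage rounded to one
    decimal place.  A zero effect size in either table counts as
    non-concordant and is logged.
    """
    a = stats_a.set_index("probe")["beta"]
    b = stats_b.set_index("probe")["beta"]
    missing = [p for p in probes if p not in a.index or p not in b.index]
    if missing:
        raise ValueError(f"probes absent from one table: {missing[:5]}")
    n_conc = 0
    for probe in probes:
        sa, sb = np.sign(a[probe]), np.sign(b[probe])
        if sa == 0 or sb == 0:
            logger.warning("zero effect size at %s; counted non-concordant", probe)
            continue
        if sa == sb:
            n_conc += 1
    percent = round(100.0 * n_conc / len(probes), 1)
    return n_conc, percent


def top_probes(stats: pd.DataFrame, k: int) -> list[str]:
    """The k most significant probes of one study, p ranking with probe-id
    tie-break, for deterministic top-k comparisons."""
    ranked = stats.sort_values(["p", "probe"], kind="stable")
    return ranked["probe"].head(k).tolist()


def pairwise_effect_correlation(
    stats_by_study, probe_list
) -> tuple[pd.DataFrame, int, int, float]:
    """Pearson correlations of effect sizes between every unordered study
    pair over a fixed probe list.

    Pairs use complete-case overlap; a pair with fewer than 3 overlapping
    probes is reported missing (NaN) and excluded from the counts.
    Returns ``(correlation matrix, n_pairs, n_positive, percent_positive)``.
    """
    if len(stats_by_study) < 2:
        raise ValueError("need at least 2 studies")
    betas = {}
    for df in stats_by_study:
        study = df["study_id"].iloc[0]
        betas[study] = df.set_index("probe")["beta"].reindex(probe_list)
    studies = list(betas)
    corr = pd.DataFrame(np.eye(len(studies)), index=studies, columns=studies)
    n_pairs = n_positive = 0
    for a, b in combinations(studies, 2):
        pair = pd.concat([betas[a], betas[b]], axis=1).dropna()
        if len(pair) < 3:
            corr.loc[a, b] = corr.loc[b, a] = np.nan
            logger.warning("pair (%s, %s): overlap < 3 probes, reported missing", a, b)
            continue
        r = float(np.corrcoef(pair.iloc[:, 0], pair.iloc[:, 1])[0, 1])
        corr.loc[a, b] = corr.loc[b, a] = r
        n_pairs += 1
        if r > 0:
            n_positive += 1
    percent = 100.0 * n_positive / n_pairs if n_pairs else float("nan")
    return corr, n_pairs, n_positive, percent
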