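"""Per-cohort probe-wise association of M values with case status.

Each probe's M values are regressed on the binary phenotype under one of
three nested covariate models:

``basic``
    age, sex, batch indicators, methylation principal components and
    blood-cell proportions (granulocytes dropped to break the sum-to-one
    singularity);
``ahrr``
    basic plus the M value of the smoking-responsive AHRR probe
    (cg05575921), a validated smoking proxy;
``complex``
    ahrr plus BMI and alcohol consumption.

The ordinary-least-squares t statistic for the phenotype term is converted
to a standardized mean difference (Cohen's d) so that effect sizes are
comparable across cohorts of different size and case balance.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CohortDataset, SUMMARY_STAT_COLUMNS

__all__ = [
    "beta_to_m",
    "m_to_beta",
    "compute_methylation_pcs",
    "run_probe_regression",
    "t_to_cohens_d",
    "genomic_inflation",
]

MODELS = ("basic", "ahrr", "complex")

#: Null median of a 1-df chi-square, the denominator of the inflation factor.
CHI2_NULL_MEDIAN = 0.4549364231195724


def beta_to_m(beta_value):
    """Convert a methylation beta value (fraction in (0,1)) to an M value.

    ``m = log2(beta / (1 - beta))``; the logit2 transform stabilizes the
    heteroscedastic variance of beta values near 0 and 1.
    """
    b = np.asarray(beta_value, dtype=float)
    if np.any(b <= 0) or np.any(b >= 1):
        raise ValueError("beta values must lie strictly in (0, 1)")
    out = np.log2(b / (1.0 - b))
    return out if out.ndim else float(out)


def m_to_beta(m_value):
    """Inverse of :func:`beta_to_m`: ``beta = 2^m / (2^m + 1)``."""
    m = np.asarray(m_value, dtype=float)
    out = 1.0 / (1.0 + np.exp2(-m))
    return out if out.ndim else float(out)


def compute_methylation_pcs(m_values: pd.DataFrame, k: int) -> pd.DataFrame:
    """First ``k`` principal-component scores of the samples.

    Samples are observations, probes are variables; probes are centred
    before the SVD.  Scores come back variance-ordered, with each
    component's sign fixed so that its largest-magnitude probe loading is
    positive.

    Returns a samples x k frame with columns ``pc1`` ... ``pck``.
    """
    x = m_values.to_numpy(dtype=float).T  # samples x probes
    x = x - x.mean(axis=0, keepdims=True)
    if min(x.shape) <= 500:
        rank = np.linalg.matrix_rank(x)
        if k > rank:
            raise ValueError(f"k={k} exceeds matrix rank; at most k={rank} achievable")
        u, s, vt = np.linalg.svd(x, full_matrices=False)
    else:
        # truncated randomized SVD: exact factors are overkill when only the
        # top k components enter the design matrix
        from sklearn.utils.extmath import randomized_svd

        u, s, vt = randomized_svd(x, n_components=k, n_iter=7, random_state=0)
        tol = max(x.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
        rank = int(np.sum(s > tol))
        if k > rank:
            raise ValueError(f"k={k} exceeds matrix rank; at most k={rank} achievable")
    scores = u[:, :k] * s[:k]
    # sign convention: largest-|loading| probe positive per component
    for j in range(k):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            scores[:, j] *= -1.0
    return pd.DataFrame(
        scores, index=m_values.columns, columns=[f"pc{j + 1}" for j in range(k)]
    )


def t_to_cohens_d(
    t: float, n_case: int, n_control: int, df: int
) -> tuple[float, float]:
    """Convert a regression t statistic to Cohen's d and its standard error.

    ``d = t * (n1 + n2) / (sqrt(n1 * n2) * sqrt(df))`` — the standard
    conversion for a two-group contrast embedded in a linear model.  The
    standard error is ``d / t``, which for ``t = 0`` reduces to the
    multiplier itself.
    """
    if df <= 0:
        raise ValueError(f"df must be positive, got {df}")
    if n_case <= 0 or n_control <= 0:
        raise ValueError("group counts must be positive")
    scale = (n_case + n_control) / (math.sqrt(n_case * n_control) * math.sqrt(df))
    d = t * scale
    se_d = d / t if t != 0 else scale
    return d, se_d


def genomic_inflation(p_values) -> tuple[float, int]:
    """Genomic inflation factor lambda of a vector of p-values.

    ``lambda = median(chi2_quantile(1 - p, df=1)) / 0.4549...``; values
    near 1 indicate well-calibrated test statistics, values above 1
    inflation from confounding or polygenicity.

    Returns ``(lambda, n_probes_used)``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_NULL_MEDIAN), int(p.size)


def _model_covariate_columns(data: CohortDataset, model: str) -> list[str]:
    cols = ["age", "sex"]
    # granulocytes dropped: compositional collinearity
    cols += ["cd8t", "cd4t", "nk", "bcell"]
    if model in ("ahrr", "complex"):
        cols.append("smoking_proxy")
    if model == "complex":
        for c in ("bmi", "alcohol"):
            if c not in data.covariates.columns:
                raise ValueError(
                    f"{data.study_id}: complex model requires covariate '{c}'"
                )
        cols += ["bmi", "alcohol"]
    missing = [c for c in cols if c not in data.covariates.columns]
    if missing:
        raise ValueError(f"{data.study_id}: missing covariates {missing}")
    return cols


def _design_matrix(
    data: CohortDataset, model: str, n_pcs: int
) -> tuple[np.ndarray, list[str]]:
    cov = data.covariates
    cols = _model_covariate_columns(data, model)
    parts = [np.ones((data.n_samples, 1)), data.phenotype.to_numpy()[:, None]]
    names = ["intercept", "phenotype"]
    parts.append(cov[cols].to_numpy(dtype=float))
    names += cols
    if "batch" in cov.columns:
        dummies = pd.get_dummies(cov["batch"], prefix="batch", drop_first=True)
        if dummies.shape[1]:
            parts.append(dummies.to_numpy(dtype=float))
            names += list(dummies.columns)
    if n_pcs > 0:
        pcs = compute_methylation_pcs(data.m_values, n_pcs)
        parts.append(pcs.to_numpy())
        names += list(pcs.columns)
    x = np.column_stack(parts)
    return x, names


def _check_condition(x: np.ndarray, names: list[str]) -> None:
    # standardize non-intercept columns so the condition number reflects
    # collinearity, not units
    z = x.copy()
    sd = z.std(axis=0)
    nonconst = sd > 0
    z[:, nonconst] = (z[:, nonconst] - z[:, nonconst].mean(axis=0)) / sd[nonconst]
    cond = np.linalg.cond(z)
    if cond > 1e10:
        offenders = [names[j] for j in np.where(~nonconst)[0] if names[j] != "intercept"]
        corr = np.corrcoef(z[:, nonconst], rowvar=False)
        idx = np.array(names)[nonconst]
        for a in range(corr.shape[0]):
            for b in range(a + 1, corr.shape[0]):
                if abs(corr[a, b]) > 0.9999:
                    offenders += [str(idx[a]), str(idx[b])]
        raise ValueError(
            f"design matrix ill-conditioned (cond={cond:.3g}); "
            f"offending columns: {sorted(set(offenders)) or 'unidentified'}"
        )


def run_probe_regression(
    data: CohortDataset, model: str = "ahrr", n_pcs: int = 20
) -> pd.DataFrame:
    """Probe-wise OLS of M values on case status for one cohort.

    Returns a summary-statistics frame (one row per analyzed probe) with
    effect sizes on the Cohen's d scale; see
    :data:`ewaskit.containers.SUMMARY_STAT_COLUMNS`.  Probes with zero
    variance are skipped and listed in ``result.attrs["skipped_probes"]``.
    When the smoking-proxy probe itself is the outcome it is removed from
    its own covariate set.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    n_pcs = min(n_pcs, max(0, min(data.m_values.shape) - 1))
    x, names = _design_matrix(data, model, n_pcs)
    _check_condition(x, names)

    m = data.m_values.to_numpy(dtype=float)
    probe_sd = m.std(axis=1)
    analyzed = probe_sd > 0
    skipped = list(data.m_values.index[~analyzed])

    y = m[analyzed].T  # samples x probes
    n, p = x.shape
    df = n - p
    if df <= 0:
        raise ValueError(f"{data.study_id}: residual df <= 0 (n={n}, p={p})")

    xtx_inv = np.linalg.inv(x.T @ x)
    coef = xtx_inv @ (x.T @ y)  # p x probes
    resid = y - x @ coef
    sigma2 = (resid**2).sum(axis=0) / df
    j = names.index("phenotype")
    beta_raw = coef[j]
    se_raw = np.sqrt(sigma2 * xtx_inv[j, j])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se_raw > 0, beta_raw / se_raw, 0.0)

    n_case, n_control = data.n_case, data.n_control
    scale = (n_case + n_control) / (math.sqrt(n_case * n_control) * math.sqrt(df))
    d = t * scale
    se_d = np.full_like(d, scale)
    nonzero = t != 0
    se_d[nonzero] = d[nonzero] / t[nonzero]
    p_val = 2.0 * stats.t.sf(np.abs(t), df)
    p_val = np.clip(p_val, np.finfo(float).tiny, 1.0)

    probes = data.m_values.index[analyzed]
    ann = data.manifest.set_index("probe").loc[probes]
    out = pd.DataFrame(
        {
            "probe": probes,
            "chr": ann["chr"].to_numpy(),
            "pos": ann["pos"].to_numpy(),
            "beta": d,
            "se": se_d,
            "p": p_val,
            "n": n,
            "n_case": n_case,
            "n_control": n_control,
            "study_id": data.study_id,
            "array": data.array,
            "model": model,
        }
    ).reset_index(drop=True)

    # the smoking proxy cannot adjust for itself
    proxy = "smoking_proxy" in names and "cg05575921" in set(probes)
    if proxy:
        proxy_id = "cg05575921"
        keep = [c for c in names if c != "smoking_proxy"]
        x2 = x[:, [names.index(c) for c in keep]]
        yv = data.m_values.loc[proxy_id].to_numpy(dtype=float)
        res = _single_ols(x2, yv, keep.index("phenotype"))
        df2 = n - x2.shape[1]
        d2, se2 = t_to_cohens_d(res["t"], n_case, n_control, df2)
        row = out["probe"] == proxy_id
        out.loc[row, ["beta", "se", "p"]] = (
            d2,
            se2,
            float(np.clip(2.0 * stats.t.sf(abs(res["t"]), df2), np.finfo(float).tiny, 1.0)),
        )

    out = out[SUMMARY_STAT_COLUMNS]
    out.attrs["skipped_probes"] = skipped
    return out


def _single_ols(x: np.ndarray, y: np.ndarray, j: int) -> dict:
    """One-probe OLS used for the smoking-proxy refit and as a test oracle."""
    xtx_inv = np.linalg.inv(x.T @ x)
    coef = xtx_inv @ (x.T @ y)
    resid = y - x @ coef
    df = len(y) - x.shape[1]
    sigma2 = resid @ resid / df
    se = math.sqrt(sigma2 * xtx_inv[j, j])
    t = coef[j] / se if se > 0 else 0.0
    return {"beta": coef[j], "se": se, "t": t, "df": df}
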