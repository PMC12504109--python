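"""Methylation risk scores, out-of-sample classification and proteomics.

A methylation score is a per-individual weighted sum of M values with
meta-analysis effect sizes as weights, built at a ladder of p-value
inclusion thresholds (1, 0.01, 0.001, 1e-6, 5e-8).  For evaluation the
score is residualized against age, sex and the smoking-proxy probe and
standardized; association with case status is reported as the linear-model
coefficient (score as dependent variable, diagnosis as predictor), the
Mann-Whitney AUC of the residualized score, and the two-group Cohen's d.

The proteomic arm tests the score against a multiplex protein panel:
proteins with more than 40% of samples below the assay's lower limit of
detection are removed, abundances are rank-based inverse-normal
transformed and residualized against technical covariates, and each
protein is regressed on the score with BH-FDR across retained proteins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import ProteinPanel
from .meta import bh_fdr

__all__ = [
    "ScoreWeights",
    "DEFAULT_THRESHOLDS",
    "build_weights",
    "compute_scores",
    "residualize",
    "classify_case_control",
    "auc_mann_whitney",
    "rank_inverse_normal",
    "filter_proteins_by_detection",
    "pwas",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (1.0, 0.01, 0.001, 1e-6, 5e-8)


@dataclass
class ScoreWeights:
    """Probe weights (pooled effect sizes) at one p-value threshold."""

    threshold: float
    weights: pd.Series  # index = probe, value = meta beta


def build_weights(
    meta: pd.DataFrame, thresholds=DEFAULT_THRESHOLDS
) -> list[ScoreWeights]:
    """One weight set per threshold; probes with meta p <= threshold enter
    with their pooled beta as weight.  Weight sets are nested across
    decreasing thresholds by construction."""
    if meta.empty:
        raise ValueError("meta-analysis table is empty")
    out = []
    for t in thresholds:
        if not 0.0 < t <= 1.0:
            raise ValueError(f"threshold must be in (0, 1], got {t}")
        sel = meta[meta["p"] <= t]
        out.append(
            ScoreWeights(
                threshold=float(t),
                weights=pd.Series(
                    sel["beta"].to_numpy(), index=sel["probe"], name="weight"
                ),
            )
        )
    return out


def compute_scores(m_values: pd.DataFrame, weights: ScoreWeights) -> pd.Series:
    """Weighted sum of M values per sample over the available weighted probes.

    Weighted probes missing from the matrix are skipped with a logged
    count; zero overlap is an error.
    """
    probes = weights.weights.index
    present = probes.intersection(m_values.index)
    n_missing = len(probes) - len(present)
    if len(present) == 0:
        raise ValueError("no weighted probe overlaps the methylation matrix")
    if n_missing:
        logger.warning(
            "%d of %d weighted probes missing from matrix; skipped",
            n_missing,
            len(probes),
        )
    w = weights.weights.loc[present].to_numpy()
    scores = w @ m_values.loc[present].to_numpy(dtype=float)
    out = pd.Series(scores, index=m_values.columns, name="score")
    out.attrs["n_probes_used"] = int(len(present))
    out.attrs["n_probes_missing"] = int(n_missing)
    return out


def residualize(values, covariates: pd.DataFrame) -> np.ndarray:
    """OLS residuals of ``values`` on the covariates, standardized to mean 0
    and unit variance.  Degenerate (all-zero-residual) input is an error."""
    y = np.asarray(values, dtype=float)
    x = np.column_stack(
        [np.ones(len(y)), covariates.to_numpy(dtype=float)]
    )
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("covariate matrix is rank-deficient")
    if len(y) != x.shape[0]:
        raise ValueError("values and covariates have different lengths")
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    sd = resid.std(ddof=0)
    if sd <= 1e-10 * max(float(np.std(y)), 1.0):
        raise ValueError("degenerate residuals: values are exactly linear in covariates")
    return (resid - resid.mean()) / sd


def auc_mann_whitney(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney pair count.

    ``AUC = (concordant + 0.5 * tied) / (n_case * n_control)``; midranks
    handle ties exactly.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def classify_case_control(
    scores, phenotype, covariates: pd.DataFrame
) -> dict:
    """Association of a methylation score with case status.

    Fits a linear model with the score as dependent variable and diagnosis
    plus covariates as predictors, reporting the diagnosis coefficient and
    its two-sided p; the classification view is reported as the
    Mann-Whitney AUC of the covariate-residualized score and the two-group
    Cohen's d.
    """
    y = np.asarray(scores, dtype=float)
    case = np.asarray(phenotype, dtype=float)
    if len(np.unique(case)) < 2:
        raise ValueError("phenotype has a single class")
    x = np.column_stack(
        [np.ones(len(y)), case, covariates.to_numpy(dtype=float)]
    )
    fit = sm.OLS(y, x).fit()
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    p = float(max(fit.pvalues[1], np.finfo(float).tiny))

    resid_score = residualize(y, covariates)
    auc = auc_mann_whitney(resid_score, case)
    a, b = resid_score[case == 1], resid_score[case == 0]
    pooled_sd = np.sqrt(
        ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
        / (len(a) + len(b) - 2)
    )
    d = float((a.mean() - b.mean()) / pooled_sd) if pooled_sd > 0 else 0.0
    return {"beta": beta, "se": se, "p": p, "auc": auc, "cohens_d": d}


def rank_inverse_normal(values) -> np.ndarray:
    """Rank-based inverse-normal transform with Blom offsets.

    ``Phi^-1((rank - 3/8) / (n + 1/4))`` with average ranks for ties;
    preserves rank order and is invariant to monotone transforms of the
    input.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 values")
    if np.all(x == x[0]):
        raise ValueError("constant vector: all values tied")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 3.0 / 8.0) / (len(x) + 0.25))


def filter_proteins_by_detection(
    panel: ProteinPanel, max_below_fraction: float = 0.40
) -> tuple[ProteinPanel, pd.DataFrame]:
    """Drop proteins with strictly more than ``max_below_fraction`` of
    samples below the lower limit of detection ("over 40%" is strict, so a
    protein at exactly the boundary is retained).

    Returns ``(filtered panel, retention report)``.
    """
    frac = panel.below_llod.mean(axis=0)
    keep = frac <= max_below_fraction
    report = pd.DataFrame(
        {
            "protein": frac.index,
            "below_llod_fraction": frac.to_numpy(),
            "retained": keep.to_numpy(),
        }
    )
    filtered = ProteinPanel(
        abundance=panel.abundance.loc[:, keep],
        below_llod=panel.below_llod.loc[:, keep],
        metadata=dict(panel.metadata),
    )
    return filtered, report


def pwas(
    score,
    panel: ProteinPanel,
    residualize_covariates: pd.DataFrame,
    model_covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Protein-wide association of panel abundances with a methylation score.

    Each protein's abundance is rank-based inverse-normal transformed,
    residualized against ``residualize_covariates`` (age, sex, genetic PCs,
    assay array), then regressed on the score together with any
    ``model_covariates`` (e.g. methylation-array indicator, smoking-proxy
    probe).  Two-sided p-values are BH-FDR corrected across proteins.
    """
    s = np.asarray(score, dtype=float)
    if len(s) != panel.n_samples:
        raise ValueError(
            f"score length {len(s)} != panel samples {panel.n_samples}"
        )
    extra = (
        model_covariates.to_numpy(dtype=float)
        if model_covariates is not None
        else np.empty((len(s), 0))
    )
    x = np.column_stack([np.ones(len(s)), s, extra])
    xtx_inv = np.linalg.inv(x.T @ x)
    df = len(s) - x.shape[1]
    rows = []
    for protein in panel.proteins:
        y = rank_inverse_normal(panel.abundance[protein].to_numpy())
        y = residualize(y, residualize_covariates)
        coef = xtx_inv @ (x.T @ y)
        resid = y - x @ coef
        sigma2 = resid @ resid / df
        se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
        t = coef[1] / se
        p = float(max(2.0 * stats.t.sf(abs(t), df), np.finfo(float).tiny))
        rows.append({"protein": protein, "beta": float(coef[1]), "se": se, "p": p})
    out = pd.DataFrame(rows)
    out["q_fdr"] = bh_fdr(out["p"].to_numpy())
    return out
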