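"""Array-stratified fixed-effect inverse-variance meta-analysis.

Pooling runs in two stages: studies profiled on the same array generation
are pooled first (the probe universes differ between 450K and EPIC), then
the two array-level summaries are pooled per probe.  Because
inverse-variance weighting is associative, the two-stage result equals a
single pooled pass over all retained records; the staging exists so that
the probe-inclusion filters can be applied per array, where probe
availability is defined.

Probe-inclusion filters, applied per array after dropping records with
excessive standard errors (se > 0.5 by default):

* presence rule — the probe is available in strictly more than half of the
  array's studies, or
* sample-size rule — its summed analyzed n reaches 80% of the array's
  maximum possible n.

No genomic-control correction is applied at either stage.  Family-wise
error is controlled by Bonferroni over all probes in the pooled table;
Benjamini-Hochberg q-values are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MetaConfig",
    "ivw_fixed_effect",
    "filter_probes",
    "two_stage_meta",
    "bonferroni_adjust",
    "bonferroni_threshold",
    "bh_fdr",
]

META_RESULT_COLUMNS = [
    "probe", "chr", "pos", "beta", "se", "z", "p",
    "p_bonferroni", "q_fdr", "n_total", "k_studies", "direction",
]


@dataclass
class MetaConfig:
    """Probe-inclusion thresholds and the family-wise level.

    ``presence_fraction`` is a strict lower bound ("more than half": 3 of 6
    fails, 4 of 6 passes).  ``n_fraction_of_max`` is inclusive by default
    (``>=``); set ``n_rule_strict`` for a strict reading of "over 80%".
    """

    se_max: float = 0.5
    presence_fraction: float = 0.5
    n_fraction_of_max: float = 0.80
    alpha: float = 0.05
    n_rule_strict: bool = False

    def validate(self) -> None:
        if self.se_max <= 0:
            raise ValueError("se_max must be > 0")
        for name in ("presence_fraction", "n_fraction_of_max", "alpha"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


def ivw_fixed_effect(betas, ses) -> tuple[float, float, float, float]:
    """Fixed-effect inverse-variance pooling of per-study estimates.

    Weights are ``1/se^2``; returns ``(beta, se, z, p)`` with a two-sided
    normal p-value.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size == 0:
        raise ValueError("nothing to pool: empty input")
    if b.shape != s.shape:
        raise ValueError("betas and ses must have equal length")
    if np.any(s <= 0):
        raise ValueError("all standard errors must be > 0")
    w = 1.0 / s**2
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return beta, se, z, max(p, np.finfo(float).tiny)


def bonferroni_adjust(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value: ``min(1, p * m)``."""
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must be in (0, 1], got {p}")
    return min(1.0, p * m)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold ``alpha / m``."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    return alpha / m


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Order-preserving and elementwise >= the input p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _study_records(stats_by_study) -> pd.DataFrame:
    frames = []
    for i, df in enumerate(stats_by_study):
        if df.empty:
            continue
        sub = df.copy()
        sub["_order"] = i
        frames.append(sub)
    if not frames:
        raise ValueError("no study summary statistics supplied")
    return pd.concat(frames, ignore_index=True)


def filter_probes(
    stats_by_study, config: MetaConfig | None = None
) -> tuple[dict[str, set[str]], pd.DataFrame]:
    """Apply the per-array probe-inclusion rules.

    Returns ``(retained, report)`` where ``retained`` maps each array label
    to its retained probe set and ``report`` states, per (array, probe),
    which rule retained or dropped it.  Study records with ``se > se_max``
    are removed before the presence test.
    """
    config = config or MetaConfig()
    config.validate()
    all_records = _study_records(stats_by_study)
    records = all_records[all_records["se"] <= config.se_max]

    retained: dict[str, set[str]] = {}
    rows = []
    for array, arr_all in all_records.groupby("array"):
        # the study count and max n come from the unfiltered study set: a
        # study whose record fails the se ceiling still counts toward "half
        # of the studies using the given array"
        k_array = arr_all["study_id"].nunique()
        max_n = float(arr_all.groupby("study_id")["n"].max().sum())
        arr_records = records[records["array"] == array]
        if arr_records.empty:
            retained[array] = set()
            continue
        keep: set[str] = set()
        grouped = arr_records.groupby("probe")
        presence = grouped["study_id"].nunique()
        summed_n = grouped["n"].sum()
        for probe in presence.index:
            by_presence = presence[probe] / k_array > config.presence_fraction
            frac = summed_n[probe] / max_n if max_n > 0 else 0.0
            by_n = frac > config.n_fraction_of_max if config.n_rule_strict else frac >= config.n_fraction_of_max
            if by_presence:
                rule = "presence"
            elif by_n:
                rule = "n_rule"
            else:
                rule = "dropped"
            if rule != "dropped":
                keep.add(probe)
            rows.append(
                {
                    "array": array,
                    "probe": probe,
                    "n_studies_present": int(presence[probe]),
                    "n_studies_on_array": k_array,
                    "summed_n": int(summed_n[probe]),
                    "max_n": int(max_n),
                    "rule": rule,
                }
            )
        retained[array] = keep
    report = pd.DataFrame(rows)
    return retained, report


def _pool_table(records: pd.DataFrame) -> pd.DataFrame:
    """Vectorized IVW over a long table grouped by probe."""
    w = 1.0 / records["se"] ** 2
    records = records.assign(_w=w, _wb=w * records["beta"])
    g = records.groupby("probe", sort=True)
    sw = g["_w"].sum()
    beta = g["_wb"].sum() / sw
    se = 1.0 / np.sqrt(sw)
    n_total = g["n"].sum()
    k = g.size()
    first = g[["chr", "pos"]].first()
    return pd.DataFrame(
        {
            "probe": beta.index,
            "chr": first["chr"].to_numpy(),
            "pos": first["pos"].to_numpy(),
            "beta": beta.to_numpy(),
            "se": se.to_numpy(),
            "n": n_total.to_numpy(),
            "k": k.to_numpy(),
        }
    ).reset_index(drop=True)


def two_stage_meta(
    stats_by_study, config: MetaConfig | None = None
) -> pd.DataFrame:
    """Two-stage, array-stratified fixed-effect meta-analysis.

    Stage 1 pools within each array after probe filtering; stage 2 pools
    the array-level summaries per probe (probes present on one array pass
    through).  Returns one row per retained probe with pooled beta/se, z,
    two-sided p, Bonferroni-adjusted p over the full table, BH q-value,
    summed n, study count and a per-study direction string ('+', '-', '?')
    in input study order.
    """
    config = config or MetaConfig()
    config.validate()
    records = _study_records(stats_by_study)
    study_order = (
        records.drop_duplicates("study_id").sort_values("_order")["study_id"].tolist()
    )
    records = records[records["se"] <= config.se_max]
    retained, _ = filter_probes(stats_by_study, config)

    stage1 = []
    for array, arr_records in records.groupby("array"):
        keep = arr_records["probe"].isin(retained.get(array, set()))
        arr_kept = arr_records[keep]
        if arr_kept.empty:
            continue
        pooled = _pool_table(arr_kept)
        stage1.append(pooled)
    if not stage1:
        return pd.DataFrame(columns=META_RESULT_COLUMNS)

    stage1_all = pd.concat(stage1, ignore_index=True)
    stage2 = _pool_table(stage1_all)
    # stage-2 k counts arrays, not studies; recover the per-study count
    stage2["k"] = stage2["probe"].map(stage1_all.groupby("probe")["k"].sum())

    # direction string over the retained per-study records, stable order
    kept_records = []
    for array, arr_records in records.groupby("array"):
        kept_records.append(
            arr_records[arr_records["probe"].isin(retained.get(array, set()))]
        )
    kept = pd.concat(kept_records, ignore_index=True)
    sign_map = {
        (row.probe, row.study_id): "+" if row.beta > 0 else ("-" if row.beta < 0 else "?")
        for row in kept.itertuples()
    }
    directions = [
        "".join(sign_map.get((probe, s), "?") for s in study_order)
        for probe in stage2["probe"]
    ]

    z = stage2["beta"] / stage2["se"]
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    m = len(stage2)
    out = pd.DataFrame(
        {
            "probe": stage2["probe"],
            "chr": stage2["chr"],
            "pos": stage2["pos"],
            "beta": stage2["beta"],
            "se": stage2["se"],
            "z": z,
            "p": p,
            "p_bonferroni": np.minimum(1.0, p * m),
            "q_fdr": bh_fdr(p),
            "n_total": stage2["n"].astype(int),
            "k_studies": stage2["k"].astype(int),
            "direction": directions,
        }
    )
    return out.reset_index(drop=True)
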