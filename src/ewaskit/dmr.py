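"""Differentially methylated region calling from meta-analysis statistics.

A candidate region is a maximal run of position-sorted probes on one
chromosome where every consecutive gap is at most 500 bp, every member has
a nominally significant pooled p-value (< 0.05) and all member effects
share one sign.  Sub-threshold probes that cannot be joined to a neighbour
are kept as singletons.  Member statistics are pooled by generalized
inverse-variance weighting with covariance ``se_i * se_j * rho_ij``; when
no inter-probe correlation is available the identity is used and the
pooling reduces to plain fixed-effect IVW.  Bonferroni correction is
applied over regions and singletons together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .meta import ivw_fixed_effect

__all__ = [
    "DMRCandidate",
    "find_candidate_regions",
    "meta_analyze_region",
    "call_dmrs",
    "write_dmr_bed",
]

DMR_COLUMNS = [
    "chr", "start", "end", "n_probes", "probes",
    "beta", "se", "z", "p", "p_bonferroni", "m_tests", "significant",
]


@dataclass
class DMRCandidate:
    """A run of nearby, same-direction, sub-threshold probes."""

    chr: str
    start: int  # 1-based inclusive
    end: int
    probe_ids: list[str]
    betas: np.ndarray
    ses: np.ndarray
    ps: np.ndarray = field(default=None)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)


def find_candidate_regions(
    meta: pd.DataFrame,
    manifest: pd.DataFrame,
    max_gap: int = 500,
    p_threshold: float = 0.05,
    min_size: int = 2,
    span_mode: bool = False,
) -> tuple[list[DMRCandidate], list[DMRCandidate]]:
    """Group sub-threshold probes into candidate regions and singletons.

    ``max_gap`` bounds the distance between consecutive member probes; with
    ``span_mode=True`` it instead bounds the total span of the region.
    Returns ``(regions, singletons)`` where regions have at least
    ``min_size`` members.
    """
    ann = manifest.set_index("probe")
    missing = set(meta["probe"]) - set(ann.index)
    if missing:
        raise ValueError(f"probes missing from manifest: {sorted(missing)[:5]}")

    sub = meta[meta["p"] < p_threshold].copy()
    sub["chr"] = sub["probe"].map(ann["chr"]).astype(str)
    sub["pos"] = sub["probe"].map(ann["pos"]).astype(int)

    regions: list[DMRCandidate] = []
    singletons: list[DMRCandidate] = []
    for chrom, group in sub.groupby("chr"):
        group = group.sort_values(["pos", "probe"]).reset_index(drop=True)
        run: list[int] = []
        for i in range(len(group)):
            if not run:
                run = [i]
                continue
            prev = group.iloc[run[-1]]
            cur = group.iloc[i]
            anchor = group.iloc[run[0]]["pos"] if span_mode else prev["pos"]
            close = cur["pos"] - anchor <= max_gap
            same_sign = np.sign(cur["beta"]) == np.sign(prev["beta"]) != 0
            if close and same_sign:
                run.append(i)
            else:
                _flush(run, group, chrom, regions, singletons, min_size)
                run = [i]
        _flush(run, group, chrom, regions, singletons, min_size)
    return regions, singletons


def _flush(run, group, chrom, regions, singletons, min_size) -> None:
    if not run:
        return
    members = group.iloc[run]
    cand = DMRCandidate(
        chr=str(chrom),
        start=int(members["pos"].min()),
        end=int(members["pos"].max()),
        probe_ids=list(members["probe"]),
        betas=members["beta"].to_numpy(),
        ses=members["se"].to_numpy(),
        ps=members["p"].to_numpy(),
    )
    if len(run) >= min_size:
        regions.append(cand)
    else:
        singletons.append(cand)


def meta_analyze_region(
    candidate: DMRCandidate, correlation: np.ndarray | pd.DataFrame | None = None
) -> tuple[float, float, float]:
    """Pool member statistics with generalized inverse-variance weighting.

    With member covariance ``Sigma_ij = se_i * se_j * rho_ij`` the pooled
    estimate is the GLS mean ``(1' Sigma^-1 b) / (1' Sigma^-1 1)`` with
    standard error ``(1' Sigma^-1 1)^{-1/2}``.  ``correlation=None`` means
    identity, i.e. plain IVW.
    """
    b = candidate.betas
    s = candidate.ses
    k = len(b)
    if correlation is None:
        beta, se, _, p = ivw_fixed_effect(b, s)
        return beta, se, p
    rho = np.asarray(
        correlation.loc[candidate.probe_ids, candidate.probe_ids]
        if isinstance(correlation, pd.DataFrame)
        else correlation,
        dtype=float,
    )
    if rho.shape != (k, k):
        raise ValueError(f"correlation must be {k}x{k}, got {rho.shape}")
    sigma = np.outer(s, s) * rho
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as err:
        raise ValueError("member correlation matrix is not positive-definite") from err
    ones = np.ones(k)
    si_b = np.linalg.solve(chol.T, np.linalg.solve(chol, b))
    si_1 = np.linalg.solve(chol.T, np.linalg.solve(chol, ones))
    denom = ones @ si_1
    beta = float(ones @ si_b / denom)
    se = float(1.0 / np.sqrt(denom))
    z = beta / se
    p = float(max(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny))
    return beta, se, p


def _region_correlation(
    candidate: DMRCandidate, m_values: pd.DataFrame | None
) -> pd.DataFrame | None:
    """Pearson correlation of member probes across samples, if a matrix is
    available; otherwise None (identity pooling)."""
    if m_values is None:
        return None
    present = [p for p in candidate.probe_ids if p in m_values.index]
    if len(present) < len(candidate.probe_ids):
        return None
    sub = m_values.loc[candidate.probe_ids]
    rho = np.corrcoef(sub.to_numpy())
    # shrink slightly toward identity so sampling noise cannot break PD-ness
    rho = 0.999 * rho + 0.001 * np.eye(len(rho))
    return pd.DataFrame(rho, index=candidate.probe_ids, columns=candidate.probe_ids)


def call_dmrs(
    meta: pd.DataFrame,
    manifest: pd.DataFrame,
    correlation_source: pd.DataFrame | None = None,
    alpha: float = 0.05,
    max_gap: int = 500,
    min_size: int = 2,
) -> pd.DataFrame:
    """Identify candidate regions, pool each, and Bonferroni-correct.

    ``correlation_source`` is an M-value matrix (probes x samples) from
    which member correlations are estimated; identity pooling otherwise.
    The correction family (``m_tests``) counts every multi-probe region
    plus every probe not absorbed into one — the whole pooled table is one
    family of regional and single-site tests, which keeps the region-level
    family-wise error controlled despite members being selected at nominal
    significance.  ``attrs["m_tests_gt2"]`` reports the stricter count
    that treats 2-probe regions as pairs of single sites.  Significance is
    two-sided Bonferroni-corrected p < ``alpha``.
    """
    regions, singletons = find_candidate_regions(
        meta, manifest, max_gap=max_gap, min_size=min_size
    )
    n_probes_total = meta["probe"].nunique()
    in_regions = sum(r.n_probes for r in regions)
    m_tests = len(regions) + (n_probes_total - in_regions)
    big = [r for r in regions if r.n_probes > 2]
    m_tests_gt2 = len(big) + (n_probes_total - sum(r.n_probes for r in big))

    rows = []
    for cand in regions:
        rho = _region_correlation(cand, correlation_source)
        beta, se, p = meta_analyze_region(cand, rho)
        rows.append((cand, beta, se, p))
    for cand in singletons:
        rows.append((cand, float(cand.betas[0]), float(cand.ses[0]), float(cand.ps[0])))

    out = pd.DataFrame(
        {
            "chr": [c.chr for c, *_ in rows],
            "start": [c.start for c, *_ in rows],
            "end": [c.end for c, *_ in rows],
            "n_probes": [c.n_probes for c, *_ in rows],
            "probes": [";".join(c.probe_ids) for c, *_ in rows],
            "beta": [r[1] for r in rows],
            "se": [r[2] for r in rows],
            "p": [r[3] for r in rows],
        }
    )
    out["z"] = out["beta"] / out["se"]
    out["p_bonferroni"] = np.minimum(1.0, out["p"] * max(m_tests, 1))
    out["m_tests"] = m_tests
    out["significant"] = (out["p_bonferroni"] < alpha) & (out["n_probes"] >= min_size)
    out = out[DMR_COLUMNS].sort_values(["chr", "start"]).reset_index(drop=True)
    out.attrs["m_tests_gt2"] = m_tests_gt2
    out.attrs["n_regions"] = len(regions)
    out.attrs["n_singletons"] = len(singletons)
    return out


def write_dmr_bed(dmrs: pd.DataFrame, path) -> None:
    """Export regions as BED (0-based half-open) with pooled z as score."""
    bed = pd.DataFrame(
        {
            "chrom": dmrs["chr"],
            "chromStart": dmrs["start"] - 1,
            "chromEnd": dmrs["end"],
            "name": [
                f"dmr_{c}_{s}" for c, s in zip(dmrs["chr"], dmrs["start"])
            ],
            "score": dmrs["z"],
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)
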