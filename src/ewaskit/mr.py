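"""Bidirectional two-sample Mendelian randomization with mQTL instruments.

Forward direction (methylation -> trait): for each CpG the most significant
cis mQTL (within 1 Mb, p < 5e-8) is the instrument; its trait-GWAS record
is harmonized to the same effect allele and the causal effect is the Wald
ratio, outcome beta over exposure beta, with the first-order delta-method
standard error.  Reverse direction (trait -> methylation): trait GWAS hits
are clumped (p <= 5e-8, 1 Mb window, r^2 <= 0.001), per-SNP Wald ratios on
each CpG are combined by fixed-effect inverse-variance weighting.  BH-FDR
is applied across tested CpGs in each direction.

Summary-statistics tables carry the columns ``snp, chr, pos, a1, a2, freq,
beta, se, p, n`` (effect allele a1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .meta import bh_fdr, ivw_fixed_effect

__all__ = [
    "Instrument",
    "select_cis_instrument",
    "clump",
    "harmonize_alleles",
    "wald_ratio",
    "forward_mr",
    "reverse_mr",
]

ASSOCIATION_COLUMNS = ["snp", "chr", "pos", "a1", "a2", "freq", "beta", "se", "p", "n"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: Effect-allele frequency band inside which a palindromic SNP's strand
#: cannot be resolved; such instruments are dropped.
PALINDROME_FREQ_BAND = (0.42, 0.58)


@dataclass
class Instrument:
    """A harmonized exposure/outcome record pair for one SNP."""

    snp: str
    exposure_beta: float
    exposure_se: float
    outcome_beta: float
    outcome_se: float
    effect_allele: str
    other_allele: str
    flipped: bool  # outcome orientation was reversed during harmonization


def select_cis_instrument(
    mqtls: pd.DataFrame,
    cpg_position: int,
    window: int = 1_000_000,
    p_max: float = 5e-8,
) -> pd.Series | None:
    """Most significant cis mQTL for one CpG, or None.

    Candidates must lie within ``window`` bp of the CpG and reach
    ``p < p_max``.  Ties on p are broken by larger |beta|, then snp id.
    """
    if mqtls.empty:
        return None
    cis = mqtls[
        (np.abs(mqtls["pos"] - cpg_position) <= window) & (mqtls["p"] < p_max)
    ]
    if cis.empty:
        return None
    ranked = cis.assign(_absb=-cis["beta"].abs()).sort_values(
        ["p", "_absb", "snp"], kind="stable"
    )
    return ranked.iloc[0].drop("_absb")


def clump(
    records: pd.DataFrame,
    ld: pd.DataFrame,
    p_max: float = 5e-8,
    window: int = 1_000_000,
    r2_max: float = 0.001,
) -> pd.DataFrame:
    """Greedy LD clumping of association records.

    Records are filtered at ``p <= p_max`` then visited in ascending-p
    order (snp id breaks ties); a record is kept unless an already-kept
    record on the same chromosome lies within ``window`` bp with pairwise
    ``r^2 > r2_max``.  The result is invariant to input row order.  ``ld``
    is a square r^2 frame indexed by snp id; a missing entry for a
    within-window pair is an error naming the pair.
    """
    sig = records[records["p"] <= p_max]
    if sig.empty:
        return sig.copy()
    ranked = sig.sort_values(["p", "snp"], kind="stable")
    kept_rows = []
    for _, row in ranked.iterrows():
        independent = True
        for kept in kept_rows:
            if kept["chr"] != row["chr"]:
                continue
            if abs(int(kept["pos"]) - int(row["pos"])) > window:
                continue
            try:
                r2 = float(ld.loc[row["snp"], kept["snp"]])
            except KeyError as err:
                raise ValueError(
                    f"missing LD entry for pair ({row['snp']}, {kept['snp']})"
                ) from err
            if np.isnan(r2):
                raise ValueError(
                    f"missing LD entry for pair ({row['snp']}, {kept['snp']})"
                )
            if r2 > r2_max:
                independent = False
                break
        if independent:
            kept_rows.append(row)
    return pd.DataFrame(kept_rows).reset_index(drop=True)


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def harmonize_alleles(
    exposure: pd.Series, outcome: pd.Series
) -> tuple[Instrument | None, str]:
    """Orient an outcome record to the exposure's effect allele.

    Returns ``(instrument, reason)``; the instrument is None when the pair
    is dropped.  Swapped allele labels flip the outcome beta; strand
    complements are re-labelled; palindromic SNPs with effect-allele
    frequency inside the ambiguity band are dropped, as are mismatched
    allele sets.
    """
    if exposure["snp"] != outcome["snp"]:
        raise ValueError("records refer to different SNPs")
    e1, e2 = str(exposure["a1"]), str(exposure["a2"])
    o1, o2 = str(outcome["a1"]), str(outcome["a2"])

    if _is_palindromic(e1, e2):
        lo, hi = PALINDROME_FREQ_BAND
        freq = float(exposure.get("freq", np.nan))
        if np.isnan(freq) or lo <= freq <= hi:
            return None, "palindromic SNP with ambiguous allele frequency"

    def build(out_beta: float, flipped: bool) -> Instrument:
        return Instrument(
            snp=str(exposure["snp"]),
            exposure_beta=float(exposure["beta"]),
            exposure_se=float(exposure["se"]),
            outcome_beta=out_beta,
            outcome_se=float(outcome["se"]),
            effect_allele=e1,
            other_allele=e2,
            flipped=flipped,
        )

    if (o1, o2) == (e1, e2):
        return build(float(outcome["beta"]), False), "ok"
    if (o1, o2) == (e2, e1):
        return build(-float(outcome["beta"]), True), "ok: alleles swapped"
    c1, c2 = _COMPLEMENT.get(o1), _COMPLEMENT.get(o2)
    if (c1, c2) == (e1, e2):
        return build(float(outcome["beta"]), False), "ok: strand flipped"
    if (c1, c2) == (e2, e1):
        return build(-float(outcome["beta"]), True), "ok: strand flipped and swapped"
    return None, f"allele mismatch ({e1}/{e2} vs {o1}/{o2})"


def wald_ratio(
    b_outcome: float,
    se_outcome: float,
    b_exposure: float,
    se_exposure: float | None = None,
    second_order: bool = False,
) -> tuple[float, float, float]:
    """Single-instrument causal estimate: outcome effect per unit exposure.

    ``beta = b_outcome / b_exposure``; the default standard error is the
    first-order delta method ``se_outcome / |b_exposure|``.  With
    ``second_order=True`` (requires ``se_exposure``) the exposure
    uncertainty is propagated as well.
    """
    if b_exposure == 0:
        raise ValueError("exposure effect is zero; Wald ratio undefined")
    beta = b_outcome / b_exposure
    if second_order:
        if se_exposure is None:
            raise ValueError("second-order se requires se_exposure")
        se = np.sqrt(
            se_outcome**2 / b_exposure**2
            + b_outcome**2 * se_exposure**2 / b_exposure**4
        )
    else:
        se = se_outcome / abs(b_exposure)
    z = beta / se
    p = float(max(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny))
    return float(beta), float(se), p


def forward_mr(
    cpg_list,
    mqtl_stats: pd.DataFrame,
    trait_gwas_stats: pd.DataFrame,
    cpg_positions: dict[str, int] | None = None,
    window: int = 1_000_000,
    p_max: float = 5e-8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Causal effect of methylation on the trait, one Wald ratio per CpG.

    ``mqtl_stats`` must carry a ``cpg`` column (and ``cpg_pos`` unless
    ``cpg_positions`` is given) on top of the association columns.  Returns
    ``(results, untested)`` where ``untested`` lists CpGs without a valid
    instrument and the reason.
    """
    cpg_list = list(cpg_list)
    if not cpg_list:
        raise ValueError("empty CpG list")
    gwas = trait_gwas_stats.set_index("snp")
    rows, skipped = [], []
    for cpg in cpg_list:
        records = mqtl_stats[mqtl_stats["cpg"] == cpg]
        if records.empty:
            skipped.append({"cpg": cpg, "reason": "no mQTL records"})
            continue
        pos = (
            cpg_positions[cpg]
            if cpg_positions is not None
            else int(records["cpg_pos"].iloc[0])
        )
        instrument = select_cis_instrument(records, pos, window=window, p_max=p_max)
        if instrument is None:
            skipped.append({"cpg": cpg, "reason": "no cis instrument at threshold"})
            continue
        if instrument["snp"] not in gwas.index:
            skipped.append({"cpg": cpg, "reason": f"{instrument['snp']} absent from GWAS"})
            continue
        outcome = gwas.loc[instrument["snp"]]
        outcome = pd.Series({"snp": instrument["snp"], **outcome.to_dict()})
        harmonized, reason = harmonize_alleles(instrument, outcome)
        if harmonized is None:
            skipped.append({"cpg": cpg, "reason": reason})
            continue
        beta, se, p = wald_ratio(
            harmonized.outcome_beta, harmonized.outcome_se, harmonized.exposure_beta
        )
        rows.append(
            {
                "cpg": cpg,
                "beta": beta,
                "se": se,
                "p": p,
                "snp": harmonized.snp,
                "chr": instrument["chr"],
                "pos": instrument["pos"],
                "a1": harmonized.effect_allele,
                "a2": harmonized.other_allele,
                "direction": "dnam_to_trait",
            }
        )
    results = pd.DataFrame(rows)
    if not results.empty:
        results["q_fdr"] = bh_fdr(results["p"].to_numpy())
    return results, pd.DataFrame(skipped)


def reverse_mr(
    trait_gwas_stats: pd.DataFrame,
    ld: pd.DataFrame,
    mqtl_outcome_stats: pd.DataFrame,
    cpg_list,
    p_max: float = 5e-8,
    window: int = 1_000_000,
    r2_max: float = 0.001,
) -> pd.DataFrame:
    """Causal effect of the trait on methylation at each CpG.

    Trait GWAS records are clumped to an approximately independent
    instrument set; per CpG the per-SNP Wald ratios (mQTL outcome over
    trait exposure) are pooled by fixed-effect IVW, which for a single
    instrument reduces to the Wald ratio itself.
    """
    instruments = clump(trait_gwas_stats, ld, p_max=p_max, window=window, r2_max=r2_max)
    if instruments.empty:
        raise ValueError("no instruments remain after clumping")
    rows = []
    for cpg in cpg_list:
        ratios, ses = [], []
        for _, exp in instruments.iterrows():
            out = mqtl_outcome_stats[
                (mqtl_outcome_stats["snp"] == exp["snp"])
                & (mqtl_outcome_stats["cpg"] == cpg)
            ]
            if out.empty:
                continue
            outcome = out.iloc[0]
            harmonized, _ = harmonize_alleles(exp, outcome)
            if harmonized is None:
                continue
            b, s, _ = wald_ratio(
                harmonized.outcome_beta, harmonized.outcome_se, harmonized.exposure_beta
            )
            ratios.append(b)
            ses.append(s)
        if not ratios:
            continue
        beta, se, z, p = ivw_fixed_effect(ratios, ses)
        rows.append(
            {
                "cpg": cpg,
                "beta": beta,
                "se": se,
                "p": p,
                "n_instruments": len(ratios),
                "direction": "trait_to_dnam",
            }
        )
    results = pd.DataFrame(rows)
    if not results.empty:
        results["q_fdr"] = bh_fdr(results["p"].to_numpy())
    return results
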