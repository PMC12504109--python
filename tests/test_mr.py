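"""Instrument selection, clumping, harmonization and Wald-ratio estimation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ewaskit.mr import (
    clump,
    forward_mr,
    harmonize_alleles,
    reverse_mr,
    select_cis_instrument,
    wald_ratio,
)
from ewaskit.synthetic import association_records, ld_matrix, simulate_mqtl_study


def _records(rows):
    return pd.DataFrame(
        rows,
        columns=["snp", "chr", "pos", "a1", "a2", "freq", "beta", "se", "p", "n"],
    )


class TestCisSelection:
    BASE = [
        ("rs1", "1", 1_000_000, "A", "G", 0.3, 0.4, 0.05, 1e-9, 5000),
        ("rs2", "1", 1_100_000, "A", "G", 0.2, 0.3, 0.05, 1e-10, 5000),
    ]

    def test_most_significant_wins(self):
        best = select_cis_instrument(_records(self.BASE), cpg_position=1_050_000)
        assert best["snp"] == "rs2"

    def test_outside_window_excluded(self):
        rows = [("rs1", "1", 2_300_000, "A", "G", 0.3, 0.4, 0.05, 1e-9, 5000)]
        assert select_cis_instrument(_records(rows), cpg_position=1_000_000) is None

    def test_sub_threshold_excluded(self):
        rows = [("rs1", "1", 1_000_500, "A", "G", 0.3, 0.4, 0.05, 1e-7, 5000)]
        assert select_cis_instrument(_records(rows), cpg_position=1_000_000) is None

    def test_p_tie_broken_by_larger_effect_then_id(self):
        rows = [
            ("rs9", "1", 1_000_100, "A", "G", 0.3, 0.2, 0.05, 1e-9, 5000),
            ("rs2", "1", 1_000_200, "A", "G", 0.3, -0.5, 0.05, 1e-9, 5000),
        ]
        best = select_cis_instrument(_records(rows), cpg_position=1_000_000)
        assert best["snp"] == "rs2"


class TestClump:
    def _ld(self, entries, snps):
        ld = pd.DataFrame(np.eye(len(snps)), index=snps, columns=snps)
        for a, b, r2 in entries:
            ld.loc[a, b] = ld.loc[b, a] = r2
        return ld

    def test_correlated_pair_keeps_best(self):
        recs = _records(
            [
                ("rs1", "1", 1_000_000, "A", "G", 0.3, 0.4, 0.05, 1e-10, 5000),
                ("rs2", "1", 1_050_000, "A", "G", 0.3, 0.3, 0.05, 1e-9, 5000),
            ]
        )
        ld = self._ld([("rs1", "rs2", 0.5)], ["rs1", "rs2"])
        kept = clump(recs, ld)
        assert kept["snp"].tolist() == ["rs1"]

    def test_distant_pair_both_kept(self):
        recs = _records(
            [
                ("rs1", "1", 1_000_000, "A", "G", 0.3, 0.4, 0.05, 1e-10, 5000),
                ("rs2", "1", 3_100_000, "A", "G", 0.3, 0.3, 0.05, 1e-9, 5000),
            ]
        )
        ld = self._ld([("rs1", "rs2", 0.99)], ["rs1", "rs2"])
        assert set(clump(recs, ld)["snp"]) == {"rs1", "rs2"}

    def test_chained_triple_greedy_trace(self):
        """r2(1,2)=0.9, r2(1,3)=0.0005, r2(2,3)=0.9, p1<p2<p3: keep {1,3}."""
        recs = _records(
            [
                ("rs1", "1", 1_000_000, "A", "G", 0.3, 0.4, 0.05, 1e-12, 5000),
                ("rs2", "1", 1_010_000, "A", "G", 0.3, 0.3, 0.05, 1e-11, 5000),
                ("rs3", "1", 1_020_000, "A", "G", 0.3, 0.2, 0.05, 1e-10, 5000),
            ]
        )
        ld = self._ld(
            [("rs1", "rs2", 0.9), ("rs1", "rs3", 0.0005), ("rs2", "rs3", 0.9)],
            ["rs1", "rs2", "rs3"],
        )
        assert set(clump(recs, ld)["snp"]) == {"rs1", "rs3"}

    def test_input_order_invariance(self, rng):
        rows = [
            (f"rs{i}", "1", 1_000_000 + i * 50_000, "A", "G", 0.3,
             rng.normal(), 0.05, 10.0 ** -rng.integers(8, 15), 5000)
            for i in range(8)
        ]
        snps = [r[0] for r in rows]
        r2 = rng.uniform(0, 0.2, size=(8, 8))
        r2 = (r2 + r2.T) / 2
        np.fill_diagonal(r2, 1.0)
        ld = pd.DataFrame(r2, index=snps, columns=snps)
        a = clump(_records(rows), ld)
        shuffled = [rows[i] for i in rng.permutation(8)]
        b = clump(_records(shuffled), ld)
        assert a["snp"].tolist() == b["snp"].tolist()

    def test_missing_ld_entry_names_pair(self):
        recs = _records(
            [
                ("rs1", "1", 1_000_000, "A", "G", 0.3, 0.4, 0.05, 1e-10, 5000),
                ("rs2", "1", 1_050_000, "A", "G", 0.3, 0.3, 0.05, 1e-9, 5000),
            ]
        )
        ld = pd.DataFrame([[1.0]], index=["rs1"], columns=["rs1"])
        with pytest.raises(ValueError, match="rs2"):
            clump(recs, ld)


class TestHarmonize:
    EXP = pd.Series(
        dict(snp="rs1", chr="1", pos=1, a1="A", a2="G", freq=0.3, beta=0.4, se=0.05, p=1e-9, n=5000)
    )

    def _out(self, a1, a2, beta=0.02):
        return pd.Series(
            dict(snp="rs1", chr="1", pos=1, a1=a1, a2=a2, freq=0.3, beta=beta, se=0.005, p=1e-4, n=50000)
        )

    def test_matching_alleles_unchanged(self):
        inst, _ = harmonize_alleles(self.EXP, self._out("A", "G"))
        assert inst.outcome_beta == 0.02 and not inst.flipped

    def test_swapped_alleles_negate_outcome(self):
        inst, _ = harmonize_alleles(self.EXP, self._out("G", "A"))
        assert inst.outcome_beta == -0.02 and inst.flipped

    def test_strand_complement_resolved(self):
        inst, _ = harmonize_alleles(self.EXP, self._out("T", "C"))
        assert inst.outcome_beta == 0.02 and not inst.flipped

    def test_palindromic_ambiguous_dropped(self):
        exp = self.EXP.copy()
        exp["a1"], exp["a2"], exp["freq"] = "A", "T", 0.5
        inst, reason = harmonize_alleles(exp, self._out("A", "T"))
        assert inst is None and "palindromic" in reason

    def test_allele_mismatch_dropped(self):
        inst, reason = harmonize_alleles(self.EXP, self._out("C", "G"))
        assert inst is None and "mismatch" in reason


class TestWaldRatio:
    def test_unit_exposure_is_identity(self):
        beta, se, _ = wald_ratio(0.03, 0.01, 1.0)
        assert (beta, se) == (0.03, 0.01)

    def test_hand_arithmetic(self):
        beta, se, p = wald_ratio(0.02, 0.005, 0.4)
        assert beta == pytest.approx(0.05)
        assert se == pytest.approx(0.0125)
        assert beta / se == pytest.approx(4.0)

    def test_allele_flip_invariance(self):
        a = wald_ratio(0.02, 0.005, 0.4)
        b = wald_ratio(-0.02, 0.005, -0.4)
        assert a == pytest.approx(b)

    def test_zero_exposure_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(0.02, 0.005, 0.0)

    def test_second_order_se_larger(self):
        _, se1, _ = wald_ratio(0.02, 0.005, 0.4)
        _, se2, _ = wald_ratio(0.02, 0.005, 0.4, se_exposure=0.05, second_order=True)
        assert se2 > se1


CHAIN = {
    "snp_to_cpg": {("rs1", "cg90000000"): 0.4},
    "cpg_to_trait": {"cg90000000": 0.05},
    "maf": {"rs1": 0.3},
}


def _summary_tables(seed, n=5000, chain=CHAIN, n_snps=1):
    geno, meth, trait, truth = simulate_mqtl_study(n, n_snps, 1, chain, seed=seed)
    mqtl = association_records(
        geno, meth["cg90000000"], truth.snp_positions, cpg="cg90000000"
    )
    gwas = association_records(geno, trait, truth.snp_positions)
    return geno, meth, trait, truth, mqtl, gwas


class TestForwardMR:
    def test_recovers_planted_slope_within_two_se(self):
        """The ±2 se interval covers the planted slope at roughly its
        nominal 95% rate, and the estimator is unbiased on average."""
        hits, estimates, ses = 0, [], []
        for seed in range(20):
            *_, truth, mqtl, gwas = _summary_tables(seed)
            res, _ = forward_mr(
                ["cg90000000"], mqtl, gwas, cpg_positions=truth.cpg_positions
            )
            row = res.iloc[0]
            estimates.append(row["beta"])
            ses.append(row["se"])
            if abs(row["beta"] - 0.05) <= 2 * row["se"]:
                hits += 1
        assert hits >= 16  # binomial(20, 0.95) lower tail
        mc_se = np.mean(ses) / np.sqrt(len(estimates))
        assert abs(np.mean(estimates) - 0.05) < 2.5 * mc_se

    def test_matches_two_stage_least_squares_oracle(self):
        geno, meth, trait, truth, mqtl, gwas = _summary_tables(7)
        res, _ = forward_mr(["cg90000000"], mqtl, gwas, cpg_positions=truth.cpg_positions)
        g = geno["rs1"].to_numpy()
        x = meth["cg90000000"].to_numpy()
        y = trait.to_numpy()
        gc = g - g.mean()
        beta_2sls = (gc @ (y - y.mean())) / (gc @ (x - x.mean()))
        assert res.iloc[0]["beta"] == pytest.approx(beta_2sls, abs=1e-10)

    def test_allele_flip_leaves_results_unchanged(self):
        *_, truth, mqtl, gwas = _summary_tables(3)
        res_a, _ = forward_mr(["cg90000000"], mqtl, gwas, cpg_positions=truth.cpg_positions)
        flipped = gwas.copy()
        flipped["a1"], flipped["a2"] = gwas["a2"], gwas["a1"]
        flipped["beta"] = -gwas["beta"]
        flipped["freq"] = 1.0 - gwas["freq"]
        res_b, _ = forward_mr(["cg90000000"], mqtl, flipped, cpg_positions=truth.cpg_positions)
        assert res_a.iloc[0]["beta"] == pytest.approx(res_b.iloc[0]["beta"], abs=1e-12)
        assert res_a.iloc[0]["p"] == pytest.approx(res_b.iloc[0]["p"], abs=1e-12)

    def test_null_chain_not_significant(self):
        chain = dict(CHAIN, cpg_to_trait={"cg90000000": 0.0})
        fdr_hits = 0
        for seed in range(20):
            *_, truth, mqtl, gwas = _summary_tables(seed + 100, chain=chain)
            res, _ = forward_mr(["cg90000000"], mqtl, gwas, cpg_positions=truth.cpg_positions)
            if not res.empty and (res["q_fdr"] < 0.05).any():
                fdr_hits += 1
        assert fdr_hits <= 2

    def test_non_cis_stronger_snp_ignored(self):
        chain = {
            "snp_to_cpg": {("rs1", "cg90000000"): 0.4, ("rs2", "cg90000000"): 0.8},
            "cpg_to_trait": {"cg90000000": 0.05},
            "maf": {"rs1": 0.3, "rs2": 0.3},
            "snp_offsets": {"rs1": 100_000, "rs2": 1_500_000},
        }
        *_, truth, mqtl, gwas = _summary_tables(11, chain=chain, n_snps=2)
        res, _ = forward_mr(["cg90000000"], mqtl, gwas, cpg_positions=truth.cpg_positions)
        assert res.iloc[0]["snp"] == "rs1"

    def test_cpg_without_instrument_reported(self):
        *_, truth, mqtl, gwas = _summary_tables(5)
        res, untested = forward_mr(
            ["cg90000000", "cg_absent"], mqtl, gwas, cpg_positions=truth.cpg_positions
        )
        assert untested["cpg"].tolist() == ["cg_absent"]

    def test_empty_cpg_list_rejected(self):
        *_, truth, mqtl, gwas = _summary_tables(5)
        with pytest.raises(ValueError):
            forward_mr([], mqtl, gwas)


class TestReverseMR:
    def test_single_instrument_reduces_to_wald_ratio(self):
        *_, truth, mqtl, gwas = _summary_tables(9)
        ld = pd.DataFrame([[1.0]], index=["rs1"], columns=["rs1"])
        gwas = gwas.assign(p=1e-10)  # make the instrument genome-wide significant
        res = reverse_mr(gwas, ld, mqtl, ["cg90000000"])
        exp, out = gwas.iloc[0], mqtl.iloc[0]
        want_beta, want_se, _ = wald_ratio(out["beta"], out["se"], exp["beta"])
        assert res.iloc[0]["beta"] == pytest.approx(want_beta, abs=1e-12)
        assert res.iloc[0]["se"] == pytest.approx(want_se, abs=1e-12)

    def test_recovers_planted_reverse_slope(self):
        """Trait drives the CpG through 5 independent SNPs; pooled estimate
        brackets the planted 0.1."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 8000
            g = rng.binomial(2, 0.3, size=(n, 5)).astype(float)
            trait = g @ np.full(5, 0.3) + rng.normal(0, 1, n)
            cpg = 0.1 * trait + rng.normal(0, 0.5, n)
            geno = pd.DataFrame(g, columns=[f"rs{i+1}" for i in range(5)])
            pos = {f"rs{i+1}": 1_000_000 + i * 3_000_000 for i in range(5)}
            gwas = association_records(geno, trait, pos)
            mqtl = association_records(geno, cpg, pos, cpg="cgX")
            ld = ld_matrix(geno)
            res = reverse_mr(gwas, ld, mqtl, ["cgX"])
            row = res.iloc[0]
            assert row["n_instruments"] == 5
            if abs(row["beta"] - 0.1) <= 2 * row["se"]:
                hits += 1
        assert hits >= 8

    def test_no_instruments_after_clumping_rejected(self):
        *_, truth, mqtl, gwas = _summary_tables(9)
        gwas = gwas.assign(p=0.5)
        ld = pd.DataFrame([[1.0]], index=["rs1"], columns=["rs1"])
        with pytest.raises(ValueError, match="clump"):
            reverse_mr(gwas, ld, mqtl, ["cg90000000"])
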