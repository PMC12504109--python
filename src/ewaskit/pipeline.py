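"""End-to-end pipeline driver binding the stages in dependency order.

``run_pipeline`` executes ``simulate -> mwas -> meta`` and then the four
downstream stages (``dmr``, ``score``, ``het``, ``mr``) on the stage
outputs, writing every artifact as TSV/JSON plus a run manifest recording
the configuration, seed, package version and SHA-256 of each artifact —
enough to reproduce the run byte-for-byte.

The last simulated cohort is held out of the meta-analysis and used as the
independent evaluation sample for the methylation score; the proteomic
panel and the mQTL study are simulated from seeds derived from the master
seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dmr as dmr_mod
from . import heterogeneity as het_mod
from . import mr as mr_mod
from . import score as score_mod
from .containers import CohortDataset
from .meta import MetaConfig, two_stage_meta
from .mwas import genomic_inflation, run_probe_regression
from .synthetic import (
    SimulationConfig,
    association_records,
    ld_matrix,
    simulate_consortium,
    simulate_mqtl_study,
    simulate_protein_panel,
    write_cohort,
    write_ground_truth,
)

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "mwas", "meta", "dmr", "score", "het", "mr")

_STAGE_DEPS = {
    "mwas": "simulate",
    "meta": "mwas",
    "dmr": "meta",
    "score": "meta",
    "het": "mwas",
    "mr": "simulate",
}


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run."""

    out_dir: str = "ewaskit_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    simulation: SimulationConfig | None = None
    model: str = "ahrr"
    n_pcs: int = 10
    meta: MetaConfig = field(default_factory=MetaConfig)
    score_thresholds: tuple[float, ...] = score_mod.DEFAULT_THRESHOLDS
    n_proteins: int = 92
    lod_fail_fraction: float = 22 / 92
    mr_window: int = 1_000_000
    mr_p_max: float = 5e-8
    mr_r2_max: float = 0.001
    mr_n_samples: int = 50_000
    write_cohort_matrices: bool = False

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s) {sorted(unknown)}")
        for stage in self.stages:
            dep = _STAGE_DEPS.get(stage)
            if dep is not None and dep not in self.stages:
                raise ValueError(
                    f"stage '{stage}' requires upstream stage '{dep}'"
                )
        self.meta.validate()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages and return a summary dict.

    Every stage output is written under ``config.out_dir``; the run
    manifest (``run_manifest.json``) captures configuration, seed and
    artifact hashes.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    summary: dict = {"seed": config.seed}
    rng = np.random.SeedSequence(config.seed)
    child = {name: s for name, s in zip(("protein", "mqtl"), rng.spawn(2))}

    sim_config = config.simulation or SimulationConfig(seed=config.seed)
    cohorts: list[CohortDataset] = []
    truth = None
    if "simulate" in config.stages:
        logger.info("stage simulate: %d cohorts", len(sim_config.cohorts))
        cohorts, truth = simulate_consortium(sim_config)
        write_ground_truth(truth, out / "ground_truth.json")
        artifacts["ground_truth"] = out / "ground_truth.json"
        if config.write_cohort_matrices:
            for cohort in cohorts:
                write_cohort(cohort, out / "cohorts")
        summary["n_cohorts"] = len(cohorts)
        summary["n_samples_total"] = sum(c.n_samples for c in cohorts)

    stats_by_study = []
    eval_cohort = None
    if "mwas" in config.stages:
        train, eval_cohort = cohorts[:-1], cohorts[-1]
        logger.info("stage mwas: model=%s on %d cohorts", config.model, len(train))
        for cohort in train:
            stats = run_probe_regression(cohort, model=config.model, n_pcs=config.n_pcs)
            stats_by_study.append(stats)
            lam, n_used = genomic_inflation(stats["p"])
            logger.info("  %s: lambda=%.3f over %d probes", cohort.study_id, lam, n_used)
        joined = pd.concat(stats_by_study, ignore_index=True)
        path = out / "cohort_summary_stats.tsv"
        joined.to_csv(path, sep="\t", index=False, na_rep=".")
        artifacts["cohort_summary_stats"] = path
        summary["n_studies_analyzed"] = len(stats_by_study)

    meta_table = None
    manifest_all = None
    if "meta" in config.stages:
        logger.info("stage meta: pooling %d studies", len(stats_by_study))
        meta_table = two_stage_meta(stats_by_study, config.meta)
        path = out / "meta_results.tsv"
        meta_table.to_csv(path, sep="\t", index=False, na_rep=".")
        artifacts["meta_results"] = path
        threshold = config.meta.alpha / max(len(meta_table), 1)
        n_sig = int((meta_table["p"] < threshold).sum())
        summary["n_probes_meta"] = len(meta_table)
        summary["n_significant_probes"] = n_sig
        manifest_all = (
            pd.concat([c.manifest for c in cohorts])
            .drop_duplicates("probe")
            .reset_index(drop=True)
            if cohorts
            else None
        )

    if "dmr" in config.stages:
        corr_source = cohorts[-2].m_values if len(cohorts) >= 2 else None
        dmrs = dmr_mod.call_dmrs(meta_table, manifest_all, corr_source)
        path = out / "dmr_results.tsv"
        dmrs.to_csv(path, sep="\t", index=False, na_rep=".")
        dmr_mod.write_dmr_bed(dmrs[dmrs["n_probes"] >= 2], out / "dmr_regions.bed")
        artifacts["dmr_results"] = path
        artifacts["dmr_regions_bed"] = out / "dmr_regions.bed"
        summary["n_significant_dmrs"] = int(
            (dmrs["significant"] & (dmrs["n_probes"] >= 2)).sum()
        )

    if "score" in config.stages:
        logger.info("stage score: evaluating on held-out cohort %s", eval_cohort.study_id)
        weight_sets = score_mod.build_weights(meta_table, config.score_thresholds)
        score_rows = []
        last_scores = None
        for ws in weight_sets:
            scores = score_mod.compute_scores(eval_cohort.m_values, ws)
            covs = eval_cohort.covariates[["age", "sex", "smoking_proxy"]]
            result = score_mod.classify_case_control(
                scores, eval_cohort.phenotype, covs
            )
            score_rows.append({"threshold": ws.threshold, **result})
            last_scores = scores
        score_table = pd.DataFrame(score_rows)
        path = out / "score_classification.tsv"
        score_table.to_csv(path, sep="\t", index=False, na_rep=".")
        artifacts["score_classification"] = path
        strictest = score_table.iloc[-1]
        summary["score_auc"] = float(strictest["auc"])
        summary["score_p"] = float(strictest["p"])

        # proteomic arm: panel coupled to the strictest score
        prot_rng = np.random.default_rng(child["protein"])
        slopes = np.zeros(config.n_proteins)
        n_active = max(1, config.n_proteins // 18)
        slopes[prot_rng.choice(config.n_proteins, n_active, replace=False)] = (
            prot_rng.choice([-0.15, 0.12], size=n_active)
        )
        panel, prot_truth = simulate_protein_panel(
            eval_cohort.n_samples,
            config.n_proteins,
            last_scores.to_numpy(),
            slopes,
            config.lod_fail_fraction,
            seed=int(child["protein"].generate_state(1)[0] % (2**31)),
        )
        filtered, retention = score_mod.filter_proteins_by_detection(panel)
        resid_covs = eval_cohort.covariates[["age", "sex"]]
        resid_score = score_mod.residualize(
            last_scores.to_numpy(),
            eval_cohort.covariates[["age", "sex", "smoking_proxy"]],
        )
        pwas_table = score_mod.pwas(resid_score, filtered, resid_covs)
        path = out / "pwas_results.tsv"
        pwas_table.to_csv(path, sep="\t", index=False, na_rep=".")
        artifacts["pwas_results"] = path
        summary["n_proteins_retained"] = len(filtered.proteins)
        summary["n_pwas_fdr_hits"] = int((pwas_table["q_fdr"] < 0.05).sum())

    if "het" in config.stages:
        threshold = config.meta.alpha / max(len(meta_table), 1)
        top = meta_table[meta_table["p"] < threshold]["probe"].tolist()
        if not top:
            top = meta_table.nsmallest(5, "p")["probe"].tolist()
        loo = het_mod.leave_one_out_meta(stats_by_study, probes=top, config=config.meta)
        path = out / "leave_one_out.tsv"
        loo.to_csv(path, sep="\t", index=False, na_rep=".")
        artifacts["leave_one_out"] = path
        ref = max(stats_by_study, key=lambda s: s["n"].iloc[0])
        probe_list = het_mod.top_probes(ref, min(1000, len(ref)))
        corr, n_pairs, n_pos, pct = het_mod.pairwise_effect_correlation(
            stats_by_study, probe_list
        )
        corr.to_csv(out / "effect_correlations.tsv", sep="\t", na_rep=".")
        artifacts["effect_correlations"] = out / "effect_correlations.tsv"
        summary["n_study_pairs"] = n_pairs
        summary["percent_pairs_positive"] = pct

    if "mr" in config.stages:
        logger.info("stage mr: bidirectional Wald-ratio analysis")
        mqtl_seed = int(child["mqtl"].generate_state(1)[0] % (2**31))
        chain = {
            "snp_to_cpg": {("rs1", "cg90000000"): 0.4, ("rs2", "cg90000001"): 0.35},
            "cpg_to_trait": {"cg90000000": 0.05},
            "maf": {"rs1": 0.3, "rs2": 0.25},
        }
        geno, meth, trait, mr_truth = simulate_mqtl_study(
            config.mr_n_samples, 6, 2, chain, seed=mqtl_seed
        )
        mqtl_stats = pd.concat(
            [
                association_records(
                    geno, meth[cpg], mr_truth.snp_positions, cpg=cpg
                ).assign(cpg_pos=mr_truth.cpg_positions[cpg])
                for cpg in meth.columns
            ],
            ignore_index=True,
        )
        gwas_stats = association_records(geno, trait, mr_truth.snp_positions)
        forward, untested = mr_mod.forward_mr(
            list(meth.columns),
            mqtl_stats,
            gwas_stats,
            cpg_positions=mr_truth.cpg_positions,
            window=config.mr_window,
            p_max=config.mr_p_max,
        )
        ld = ld_matrix(geno)
        try:
            reverse = mr_mod.reverse_mr(
                gwas_stats, ld, mqtl_stats, list(meth.columns),
                p_max=config.mr_p_max, window=config.mr_window,
                r2_max=config.mr_r2_max,
            )
        except ValueError:
            reverse = pd.DataFrame()
        forward.to_csv(out / "mr_forward.tsv", sep="\t", index=False, na_rep=".")
        reverse.to_csv(out / "mr_reverse.tsv", sep="\t", index=False, na_rep=".")
        artifacts["mr_forward"] = out / "mr_forward.tsv"
        artifacts["mr_reverse"] = out / "mr_reverse.tsv"
        if not forward.empty:
            summary["mr_forward_beta"] = float(
                forward.set_index("cpg").loc["cg90000000", "beta"]
            )
        summary["mr_n_untested"] = len(untested)

    manifest = {
        "seed": config.seed,
        "stages": list(config.stages),
        "config": _jsonable(config),
        "artifacts": {name: _sha256(path) for name, path in artifacts.items()},
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    summary["artifact_dir"] = str(out)
    return summary


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj
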