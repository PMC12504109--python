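"""Synthetic multi-cohort methylation consortia with planted effects.

The generator emulates the structure of a large case-control DNA
methylation consortium for a binary psychiatric phenotype: many studies of
widely varying size and case prevalence, profiled on two array generations
(450K and EPIC, where the EPIC probe set is a strict superset of the 450K
set), with additive confounding from age, sex, batch, blood-cell
composition, smoking, BMI and alcohol.  Every planted quantity — the
case-control shift at causal probes, SNP->CpG->liability slopes for the
Mendelian-randomization chain, protein-on-score slopes for the proteomic
panel — is returned in a :class:`GroundTruth` object so downstream stages
have an exact acceptance surface.

M values are simulated directly as Gaussian, matching the scale on which
association models are fitted; :func:`ewaskit.mwas.m_to_beta` converts to
beta values for I/O realism when needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CohortDataset, ProteinPanel

__all__ = [
    "CohortSpec",
    "ConfounderConfig",
    "SimulationConfig",
    "GroundTruth",
    "default_consortium",
    "simulate_consortium",
    "simulate_mqtl_study",
    "simulate_protein_panel",
    "association_records",
    "ld_matrix",
    "write_cohort",
    "write_ground_truth",
]

#: Probe id reserved for the smoking-responsive AHRR CpG used as the
#: smoking covariate throughout the pipeline.
SMOKING_PROXY_PROBE = "cg05575921"

CELL_TYPES = ["cd8t", "cd4t", "nk", "bcell", "gran"]


class ConfigurationError(ValueError):
    """A simulation configuration field is outside its documented domain."""


@dataclass(frozen=True)
class CohortSpec:
    """Size, prevalence and array membership of one simulated study."""

    study_id: str
    n_samples: int
    case_prevalence: float
    array: str  # "A450" or "EPIC"
    mean_age: float = 45.0
    has_lifestyle: bool = True  # BMI and alcohol recorded


def default_consortium() -> tuple[CohortSpec, ...]:
    """Eighteen studies (24,754 samples, 5,443 cases) mirroring the mix of
    sizes, prevalences (6-86%), mean ages and array generations seen in
    large depression methylation consortia.  Three studies lack lifestyle
    covariates, so the fully adjusted model runs on a reduced consortium.
    """
    rows = [
        # study_id, n, prevalence, array, mean age, lifestyle
        ("cohort01", 657, 0.311, "A450", 29.4, False),
        ("cohort02", 305, 0.728, "EPIC", 37.5, True),
        ("cohort03", 561, 0.515, "EPIC", 51.6, True),
        ("cohort04", 186, 0.199, "A450", 38.0, True),
        ("cohort05", 1625, 0.198, "A450", 18.5, False),
        ("cohort06", 1181, 0.161, "A450", 56.3, True),
        ("cohort07", 985, 0.165, "A450", 23.8, True),
        ("cohort08", 366, 0.254, "EPIC", 25.4, True),
        ("cohort09", 667, 0.510, "EPIC", 35.3, True),
        ("cohort10", 9502, 0.172, "EPIC", 49.8, True),
        ("cohort11", 222, 0.860, "EPIC", 42.8, True),
        ("cohort12", 633, 0.602, "EPIC", 15.1, True),
        ("cohort13", 497, 0.626, "A450", 48.1, True),
        ("cohort14", 2701, 0.161, "A450", 36.5, True),
        ("cohort15", 492, 0.171, "EPIC", 51.1, True),
        ("cohort16", 692, 0.290, "A450", 59.0, True),
        ("cohort17", 1121, 0.064, "EPIC", 58.4, True),
        ("cohort18", 2361, 0.117, "EPIC", 51.1, False),
    ]
    return tuple(CohortSpec(*row) for row in rows)


@dataclass
class ConfounderConfig:
    """Additive confounder slopes on the M-value scale.

    Each confounder loads on a random ``affected_fraction`` of probes with
    the stated slope magnitude (random sign), so covariate adjustment in the
    association model is consequential.  ``smoking_case_shift`` couples the
    latent smoking liability to case status, which makes the smoking-proxy
    probe a genuine confounder rather than noise.
    """

    age_slope: float = 0.005  # per year
    sex_slope: float = 0.10
    batch_sd: float = 0.20
    cell_slope: float = 0.60
    smoking_slope: float = 0.20
    smoking_case_shift: float = 0.30
    bmi_slope: float = 0.01  # per kg/m^2
    alcohol_slope: float = 0.01  # per weekly unit
    affected_fraction: float = 0.10


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic consortium.

    Defaults reproduce the consortium structure of :func:`default_consortium`
    with a desk-scale methylome (the probe dimension is reduced; everything
    else keeps its realistic value).
    """

    cohorts: tuple[CohortSpec, ...] = field(default_factory=default_consortium)
    n_probes_shared: int = 4000
    n_probes_epic_only: int = 800
    n_causal_probes: int = 15
    effect_size_d: float = 0.2
    n_dmr_blocks: int = 0
    dmr_block_size: int = 3
    dmr_effect_d: float = 0.3
    dmr_correlation: float = 0.6
    confounders: ConfounderConfig = field(default_factory=ConfounderConfig)
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        for spec in self.cohorts:
            if not 0.0 < spec.case_prevalence < 1.0:
                raise ConfigurationError(
                    f"case_prevalence for {spec.study_id} must be in (0,1), "
                    f"got {spec.case_prevalence}"
                )
            if spec.array not in ("A450", "EPIC"):
                raise ConfigurationError(
                    f"array for {spec.study_id} must be 'A450' or 'EPIC', "
                    f"got {spec.array!r}"
                )
            n_case = round(spec.n_samples * spec.case_prevalence)
            if min(n_case, spec.n_samples - n_case) < 2:
                raise ConfigurationError(
                    f"n_samples for {spec.study_id} leaves fewer than 2 "
                    "samples in one phenotype group"
                )
        if self.n_probes_shared < 1:
            raise ConfigurationError("n_probes_shared must be >= 1")
        if self.n_probes_epic_only < 0:
            raise ConfigurationError("n_probes_epic_only must be >= 0")
        n_block_probes = self.n_dmr_blocks * self.dmr_block_size
        if self.n_causal_probes + n_block_probes + 1 > self.n_probes_shared:
            raise ConfigurationError(
                "n_causal_probes plus DMR block probes exceeds n_probes_shared"
            )
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if not 0.0 <= self.dmr_correlation < 1.0:
            raise ConfigurationError("dmr_correlation must be in [0,1)")


@dataclass
class GroundTruth:
    """Planted parameters of a simulated dataset, keyed by entity ids."""

    causal_probe_ids: set[str] = field(default_factory=set)
    true_effects: dict[str, float] = field(default_factory=dict)
    dmr_blocks: list[list[str]] = field(default_factory=list)
    smoking_proxy_probe: str = SMOKING_PROXY_PROBE
    mqtl_truth: dict[tuple[str, str], float] = field(default_factory=dict)
    noncis_snps: set[str] = field(default_factory=set)
    causal_cpg_to_trait: dict[str, float] = field(default_factory=dict)
    protein_truth: dict[str, float] = field(default_factory=dict)
    snp_positions: dict[str, int] = field(default_factory=dict)
    cpg_positions: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = asdict(self)
        payload["causal_probe_ids"] = sorted(self.causal_probe_ids)
        payload["noncis_snps"] = sorted(self.noncis_snps)
        payload["mqtl_truth"] = {
            f"{snp}|{cpg}": slope for (snp, cpg), slope in self.mqtl_truth.items()
        }
        return json.dumps(payload, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# probe universe


def _build_manifest(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Lay probes on chromosomes 1-22 with a gap mixture so that some runs
    of consecutive probes sit within a 500-bp window (DMR-able adjacency)."""
    n_total = config.n_probes_shared + config.n_probes_epic_only
    probe_ids = [f"cg{i:08d}" for i in range(1, n_total + 1)]
    # the smoking proxy probe is part of the shared set
    probe_ids[0] = SMOKING_PROXY_PROBE

    chroms = np.array([str(c) for c in rng.integers(1, 23, size=n_total)])
    positions = np.empty(n_total, dtype=np.int64)
    for chrom in np.unique(chroms):
        idx = np.where(chroms == chrom)[0]
        close = rng.random(len(idx)) < 0.3
        gaps = np.where(
            close,
            rng.integers(50, 450, size=len(idx)),
            rng.integers(2_000, 50_000, size=len(idx)),
        )
        positions[idx] = 10_000 + np.cumsum(gaps)

    islands = rng.choice(
        ["Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea"],
        p=[0.15, 0.08, 0.08, 0.04, 0.04, 0.61],
        size=n_total,
    )
    genes = np.where(
        rng.random(n_total) < 0.6,
        [f"GENE{i % 997:03d}" for i in range(n_total)],
        ".",
    )
    array = np.array(["Both"] * config.n_probes_shared + ["EPIC"] * config.n_probes_epic_only)
    manifest = pd.DataFrame(
        {
            "probe": probe_ids,
            "chr": chroms,
            "pos": positions,
            "gene": genes,
            "island_relation": islands,
            "array": array,
        }
    )
    return manifest


def _plant_dmr_blocks(
    config: SimulationConfig, manifest: pd.DataFrame, rng: np.random.Generator
) -> list[list[str]]:
    """Rewrite positions for a few runs of shared probes so each run forms a
    tight same-chromosome block with consecutive gaps under 250 bp."""
    blocks: list[list[str]] = []
    size = config.dmr_block_size
    start_idx = 1  # skip the smoking proxy probe
    for b in range(config.n_dmr_blocks):
        idx = slice(start_idx + b * size, start_idx + (b + 1) * size)
        members = manifest.iloc[idx]
        chrom = members.iloc[0]["chr"]
        base = 1_000_000 + b * 100_000
        gaps = rng.integers(60, 240, size=size - 1)
        pos = base + np.concatenate([[0], np.cumsum(gaps)])
        manifest.loc[members.index, "chr"] = chrom
        manifest.loc[members.index, "pos"] = pos
        blocks.append(list(members["probe"]))
    return blocks


# ---------------------------------------------------------------------------
# consortium


def simulate_consortium(
    config: SimulationConfig,
) -> tuple[list[CohortDataset], GroundTruth]:
    """Simulate one multi-study consortium and return its ground truth.

    A single master seed spawns one deterministic stream for the shared
    probe universe and loadings plus one per cohort, so any cohort is
    reproducible independent of cohort order.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    master_ss, *cohort_ss = ss.spawn(len(config.cohorts) + 1)
    master = np.random.default_rng(master_ss)

    manifest = _build_manifest(config, master)
    dmr_blocks = _plant_dmr_blocks(config, manifest, master)
    block_probes = [p for block in dmr_blocks for p in block]
    n_total = len(manifest)
    probe_ids = manifest["probe"].to_numpy()

    # causal probes live in the shared set so both arrays contribute
    candidates = [
        p
        for p in probe_ids[: config.n_probes_shared]
        if p != SMOKING_PROXY_PROBE and p not in block_probes
    ]
    causal = list(
        master.choice(candidates, size=config.n_causal_probes, replace=False)
    )

    d = np.zeros(n_total)
    probe_index = pd.Index(probe_ids)
    d[probe_index.get_indexer(causal)] = config.effect_size_d
    true_effects = {p: config.effect_size_d for p in causal}
    for block in dmr_blocks:
        d[probe_index.get_indexer(block)] = config.dmr_effect_d
        true_effects.update({p: config.dmr_effect_d for p in block})

    # shared structure across cohorts
    conf = config.confounders
    baseline = master.normal(0.0, 2.0, size=n_total)

    def loadings(slope: float) -> np.ndarray:
        mask = master.random(n_total) < conf.affected_fraction
        signs = master.choice([-1.0, 1.0], size=n_total)
        return slope * signs * mask

    age_load = loadings(conf.age_slope)
    sex_load = loadings(conf.sex_slope)
    smoke_load = loadings(conf.smoking_slope)
    bmi_load = loadings(conf.bmi_slope)
    alc_load = loadings(conf.alcohol_slope)
    cell_load = np.stack([loadings(conf.cell_slope) for _ in range(5)], axis=1)

    proxy_idx = int(probe_index.get_indexer([SMOKING_PROXY_PROBE])[0])

    truth = GroundTruth(
        causal_probe_ids=set(causal) | set(block_probes),
        true_effects=true_effects,
        dmr_blocks=dmr_blocks,
    )

    cohorts: list[CohortDataset] = []
    for spec, child in zip(config.cohorts, cohort_ss):
        rng = np.random.default_rng(child)
        n = spec.n_samples
        n_case = round(n * spec.case_prevalence)
        case = np.zeros(n)
        case[rng.choice(n, size=n_case, replace=False)] = 1.0

        age = np.clip(rng.normal(spec.mean_age, 8.0, size=n), 10.0, 95.0)
        sex = (rng.random(n) < 0.45).astype(float)
        n_batches = int(rng.integers(2, 5))
        batch = rng.integers(0, n_batches, size=n)
        cells = rng.dirichlet([12.0, 20.0, 4.0, 6.0, 58.0], size=n)
        bmi = np.clip(rng.normal(26.0, 4.0, size=n), 15.0, 55.0)
        alcohol = np.clip(rng.normal(8.0, 5.0, size=n), 0.0, None)
        smoking = rng.normal(0.0, 1.0, size=n) + conf.smoking_case_shift * case

        keep = manifest["array"].isin(["Both"] if spec.array == "A450" else ["Both", "EPIC"])
        keep_idx = np.where(keep.to_numpy())[0]
        sub = manifest.loc[keep.to_numpy()].reset_index(drop=True)

        # batch loadings are cohort-specific
        batch_mask = rng.random(n_total) < conf.affected_fraction
        batch_load = (
            rng.normal(0.0, conf.batch_sd, size=(n_total, n_batches))
            * batch_mask[:, None]
        )

        noise = rng.normal(0.0, config.noise_sd, size=(n_total, n))
        if config.dmr_correlation > 0 and dmr_blocks:
            rho = config.dmr_correlation
            for block in dmr_blocks:
                bi = probe_index.get_indexer(block)
                shared = rng.normal(0.0, config.noise_sd, size=n)
                noise[bi, :] = (
                    np.sqrt(rho) * shared[None, :]
                    + np.sqrt(1.0 - rho) * noise[bi, :]
                )

        m = (
            baseline[:, None]
            + config.noise_sd * d[:, None] * case[None, :]
            + age_load[:, None] * (age - spec.mean_age)[None, :]
            + sex_load[:, None] * sex[None, :]
            + batch_load[:, batch]
            + cell_load @ (cells - cells.mean(axis=0)).T
            + smoke_load[:, None] * smoking[None, :]
            + noise
        )
        if spec.has_lifestyle:
            m += bmi_load[:, None] * (bmi - 26.0)[None, :]
            m += alc_load[:, None] * (alcohol - 8.0)[None, :]
        # the smoking-proxy probe tracks the latent smoking liability
        m[proxy_idx, :] = (
            baseline[proxy_idx]
            - smoking
            + 0.1 * rng.normal(0.0, 1.0, size=n)
        )

        sample_ids = [f"{spec.study_id}_s{i:05d}" for i in range(n)]
        m_values = pd.DataFrame(
            m[keep_idx, :], index=probe_ids[keep_idx], columns=sample_ids
        )
        covariates = pd.DataFrame(
            {
                "age": age,
                "sex": sex,
                "batch": [f"b{b}" for b in batch],
                **{ct: cells[:, i] for i, ct in enumerate(CELL_TYPES)},
                "smoking_proxy": m[proxy_idx, :],
            },
            index=sample_ids,
        )
        if spec.has_lifestyle:
            covariates["bmi"] = bmi
            covariates["alcohol"] = alcohol
        phenotype = pd.Series(case.astype(int), index=sample_ids, name="md_status")

        cohorts.append(
            CohortDataset(
                m_values=m_values,
                phenotype=phenotype,
                covariates=covariates,
                manifest=sub,
                study_id=spec.study_id,
                array=spec.array,
            )
        )

    return cohorts, truth


# ---------------------------------------------------------------------------
# mQTL study


def simulate_mqtl_study(
    n_samples: int,
    n_snps: int,
    n_cpgs: int,
    chain_spec: dict,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, GroundTruth]:
    """Simulate a SNP -> CpG -> liability causal chain.

    ``chain_spec`` keys (all optional):

    ``snp_to_cpg``
        ``{(snp_id, cpg_id): slope}`` — M-value change per allele dosage.
    ``cpg_to_trait``
        ``{cpg_id: slope}`` — liability change per M-value unit.
    ``maf``
        ``{snp_id: minor allele frequency}``, default drawn U(0.1, 0.4).
    ``snp_offsets``
        ``{snp_id: bp}`` — distance from the SNP to its target CpG (for
        SNPs without a target, to the first CpG).  Offsets beyond 1 Mb put
        the SNP outside the cis window and it is flagged non-cis.
    ``cpg_noise_sd`` / ``trait_noise_sd``
        Residual scales, defaults 0.5 and 1.0.

    Genotypes are binomial(2, MAF) under Hardy-Weinberg.  CpGs sit 3 Mb
    apart on chromosome 1 so cis windows do not overlap.
    """
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10 for downstream regression")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    snp_ids = [f"rs{i + 1}" for i in range(n_snps)]
    cpg_ids = [f"cg{90_000_000 + i:08d}" for i in range(n_cpgs)]
    snp_to_cpg = dict(chain_spec.get("snp_to_cpg", {}))
    cpg_to_trait = dict(chain_spec.get("cpg_to_trait", {}))
    for (snp, cpg), slope in snp_to_cpg.items():
        if snp not in snp_ids or cpg not in cpg_ids:
            raise ValueError(f"chain_spec references unknown entity ({snp}, {cpg})")
        if not np.isfinite(slope):
            raise ValueError(f"slope for ({snp}, {cpg}) is not finite")
    for cpg, slope in cpg_to_trait.items():
        if cpg not in cpg_ids:
            raise ValueError(f"chain_spec references unknown CpG {cpg}")
        if not np.isfinite(slope):
            raise ValueError(f"trait slope for {cpg} is not finite")

    mafs = dict(chain_spec.get("maf", {}))
    for snp in snp_ids:
        mafs.setdefault(snp, float(rng.uniform(0.1, 0.4)))
    for snp, maf in mafs.items():
        if not 0.05 < maf < 0.5:
            raise ValueError(f"MAF for {snp} must be in (0.05, 0.5), got {maf}")

    cpg_positions = {cpg: 5_000_000 + i * 3_000_000 for i, cpg in enumerate(cpg_ids)}
    target = {snp: cpg for (snp, cpg) in snp_to_cpg}
    offsets = dict(chain_spec.get("snp_offsets", {}))
    for snp in snp_ids:
        offsets.setdefault(snp, int(rng.integers(-500_000, 500_000)))
    snp_positions = {
        snp: cpg_positions[target.get(snp, cpg_ids[0])] + int(offsets[snp])
        for snp in snp_ids
    }

    geno = np.column_stack(
        [rng.binomial(2, mafs[snp], size=n_samples) for snp in snp_ids]
    ).astype(float)
    genotypes = pd.DataFrame(geno, columns=snp_ids)

    cpg_noise = float(chain_spec.get("cpg_noise_sd", 0.5))
    trait_noise = float(chain_spec.get("trait_noise_sd", 1.0))
    meth = rng.normal(0.0, cpg_noise, size=(n_samples, n_cpgs))
    cpg_index = {cpg: j for j, cpg in enumerate(cpg_ids)}
    for (snp, cpg), slope in snp_to_cpg.items():
        meth[:, cpg_index[cpg]] += slope * genotypes[snp].to_numpy()
    methylation = pd.DataFrame(meth, columns=cpg_ids)

    trait = rng.normal(0.0, trait_noise, size=n_samples)
    for cpg, slope in cpg_to_trait.items():
        trait += slope * methylation[cpg].to_numpy()
    trait = pd.Series(trait, name="liability")

    noncis = {
        snp
        for snp in snp_ids
        if abs(snp_positions[snp] - cpg_positions[target.get(snp, cpg_ids[0])])
        > 1_000_000
    }
    truth = GroundTruth(
        mqtl_truth=snp_to_cpg,
        causal_cpg_to_trait=cpg_to_trait,
        noncis_snps=noncis,
        snp_positions=snp_positions,
        cpg_positions=cpg_positions,
    )
    return genotypes, methylation, trait, truth


# ---------------------------------------------------------------------------
# protein panel


def simulate_protein_panel(
    n_samples: int,
    n_proteins: int,
    score: np.ndarray,
    truth_slopes: np.ndarray,
    lod_fail_fraction: float,
    seed: int,
) -> tuple[ProteinPanel, GroundTruth]:
    """Simulate a multiplex inflammation panel coupled to a methylation score.

    A ``lod_fail_fraction`` of proteins is censored so that strictly more
    than 40% of their values fall below the assay's lower limit of
    detection; the detection filter downstream removes exactly those.
    Remaining proteins follow ``slope * standardized score + N(0, 1)``.
    """
    score = np.asarray(score, dtype=float)
    truth_slopes = np.asarray(truth_slopes, dtype=float)
    if len(score) != n_samples:
        raise ValueError(f"score length {len(score)} != n_samples {n_samples}")
    if len(truth_slopes) != n_proteins:
        raise ValueError(
            f"truth_slopes length {len(truth_slopes)} != n_proteins {n_proteins}"
        )
    if not 0.0 <= lod_fail_fraction <= 1.0:
        raise ValueError("lod_fail_fraction must be in [0, 1]")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    names = [f"prot{i + 1:03d}" for i in range(n_proteins)]
    z = (score - score.mean()) / score.std(ddof=0) if score.std(ddof=0) > 0 else score * 0.0
    abundance = truth_slopes[None, :] * z[:, None] + rng.normal(
        0.0, 1.0, size=(n_samples, n_proteins)
    )

    n_fail = round(lod_fail_fraction * n_proteins)
    failing = set(rng.choice(n_proteins, size=n_fail, replace=False).tolist())
    mask = np.zeros_like(abundance, dtype=bool)
    for j in range(n_proteins):
        q = rng.uniform(0.45, 0.70) if j in failing else 0.02
        llod = np.quantile(abundance[:, j], q)
        mask[:, j] = abundance[:, j] < llod

    panel = ProteinPanel(
        abundance=pd.DataFrame(abundance, columns=names),
        below_llod=pd.DataFrame(mask, columns=names),
        metadata={"assay": "synthetic 92-plex-style inflammation panel"},
    )
    truth = GroundTruth(
        protein_truth={names[j]: float(truth_slopes[j]) for j in range(n_proteins)}
    )
    return panel, truth


# ---------------------------------------------------------------------------
# per-SNP summary statistics and LD from simulated individual-level data


def association_records(
    genotypes: pd.DataFrame,
    outcome,
    snp_positions: dict[str, int],
    chrom: str = "1",
    cpg: str | None = None,
) -> pd.DataFrame:
    """Per-SNP simple-regression summary statistics for one outcome.

    Alleles are labelled A (effect, dosage-counted) / G; the effect-allele
    frequency is the mean dosage over 2.  Adding a ``cpg`` label yields
    mQTL-style records usable as Mendelian-randomization exposures.
    """
    y = np.asarray(outcome, dtype=float)
    rows = []
    for snp in genotypes.columns:
        g = genotypes[snp].to_numpy(dtype=float)
        n = len(g)
        gc = g - g.mean()
        yc = y - y.mean()
        sxx = float(gc @ gc)
        if sxx == 0:
            continue
        beta = float(gc @ yc / sxx)
        resid = yc - beta * gc
        sigma2 = float(resid @ resid) / (n - 2)
        se = float(np.sqrt(sigma2 / sxx))
        t = beta / se if se > 0 else 0.0
        p = float(max(2.0 * stats.t.sf(abs(t), n - 2), np.finfo(float).tiny))
        row = {
            "snp": snp,
            "chr": chrom,
            "pos": int(snp_positions[snp]),
            "a1": "A",
            "a2": "G",
            "freq": float(g.mean() / 2.0),
            "beta": beta,
            "se": se,
            "p": p,
            "n": n,
        }
        if cpg is not None:
            row["cpg"] = cpg
        rows.append(row)
    return pd.DataFrame(rows)


def ld_matrix(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Pairwise r^2 between SNP dosages, indexed by snp id."""
    r = np.corrcoef(genotypes.to_numpy(dtype=float).T)
    return pd.DataFrame(r**2, index=genotypes.columns, columns=genotypes.columns)


# ---------------------------------------------------------------------------
# writers


def write_cohort(dataset: CohortDataset, out_dir: str | Path) -> None:
    """Write one cohort as three TSVs: M-value matrix (probes as rows),
    phenotype/covariate table (one row per sample) and manifest slice."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    m = dataset.m_values.copy()
    m.insert(0, "probe", m.index)
    m.to_csv(out / f"{dataset.study_id}_mvalues.tsv", sep="\t", index=False)
    pheno = dataset.covariates.copy()
    pheno.insert(0, "md_status", dataset.phenotype)
    pheno.insert(0, "sample", pheno.index)
    pheno.to_csv(out / f"{dataset.study_id}_samples.tsv", sep="\t", index=False, na_rep=".")
    dataset.manifest.to_csv(
        out / f"{dataset.study_id}_manifest.tsv", sep="\t", index=False, na_rep="."
    )


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(truth.to_json())
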