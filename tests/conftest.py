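"""Shared fixtures: small synthetic consortia reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import ewaskit as ek
from ewaskit.synthetic import CohortSpec, ConfounderConfig, SimulationConfig, simulate_consortium


def no_confounders() -> ConfounderConfig:
    return ConfounderConfig(
        age_slope=0.0, sex_slope=0.0, batch_sd=0.0, cell_slope=0.0,
        smoking_slope=0.0, smoking_case_shift=0.0, bmi_slope=0.0,
        alcohol_slope=0.0,
    )


def small_config(seed: int = 11, **overrides) -> SimulationConfig:
    defaults = dict(
        cohorts=tuple(
            CohortSpec(f"c{i}", 400, 0.3, "A450" if i % 2 else "EPIC")
            for i in range(5)
        ),
        n_probes_shared=500,
        n_probes_epic_only=100,
        n_causal_probes=5,
        effect_size_d=0.5,
        n_dmr_blocks=2,
        dmr_effect_d=0.4,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_consortium():
    """Five cohorts, 600 probes, 5 causal probes (d=0.5) and 2 DMR blocks."""
    config = small_config()
    cohorts, truth = simulate_consortium(config)
    return cohorts, truth, config


@pytest.fixture(scope="session")
def cohort_stats(small_consortium):
    """Smoking-adjusted per-cohort summary statistics for the first four
    cohorts (the fifth is held out for score evaluation).

    All confounders in the generator are measured covariates, so the fits
    use n_pcs=0: at a toy probe dimension the principal components would
    absorb the planted correlated blocks themselves.
    """
    cohorts, _, _ = small_consortium
    return [
        ek.run_probe_regression(c, model="ahrr", n_pcs=0) for c in cohorts[:-1]
    ]


@pytest.fixture(scope="session")
def meta_table(cohort_stats):
    return ek.two_stage_meta(cohort_stats)


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_901)
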