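"""In-memory containers shared across pipeline stages.

Tables (summary statistics, meta-analysis results, manifests) are plain
:class:`pandas.DataFrame` objects with documented column contracts — see
:mod:`ewaskit.io` for the on-disk layout.  The classes here bundle the
pieces that travel together: one cohort's methylation data and a protein
panel with its detection mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Column contract for per-study and meta-analysed summary statistics.
SUMMARY_STAT_COLUMNS = [
    "probe", "chr", "pos", "beta", "se", "p",
    "n", "n_case", "n_control", "study_id", "array", "model",
]

#: Column contract for probe manifests.
MANIFEST_COLUMNS = ["probe", "chr", "pos", "gene", "island_relation", "array"]


@dataclass
class CohortDataset:
    """One study's methylation matrix with phenotype, covariates and manifest.

    Parameters
    ----------
    m_values
        Probes x samples matrix of M values (log2 methylated/unmethylated
        ratios).  Index = probe ids, columns = sample ids.
    phenotype
        Binary case status per sample (1 = case), indexed like the matrix
        columns.
    covariates
        One row per sample: ``age``, ``sex``, ``batch``, cell proportions
        (``cd8t``, ``cd4t``, ``nk``, ``bcell``, ``gran``), ``smoking_proxy``
        (M value of the smoking-responsive probe) and optionally ``bmi``
        and ``alcohol``.
    manifest
        Probe annotation slice covering every matrix row.
    study_id
        Cohort label.
    array
        ``"A450"`` or ``"EPIC"``.
    """

    m_values: pd.DataFrame
    phenotype: pd.Series
    covariates: pd.DataFrame
    manifest: pd.DataFrame
    study_id: str
    array: str

    def __post_init__(self) -> None:
        if self.phenotype.isna().any():
            raise ValueError(f"{self.study_id}: phenotype contains missing values")
        values = set(np.unique(self.phenotype))
        if not values <= {0, 1}:
            raise ValueError(f"{self.study_id}: phenotype must be binary 0/1")
        n_case = int(self.phenotype.sum())
        if n_case == 0 or n_case == len(self.phenotype):
            raise ValueError(f"{self.study_id}: need at least one case and one control")
        if self.m_values.index.duplicated().any():
            dupes = self.m_values.index[self.m_values.index.duplicated()].tolist()
            raise ValueError(f"{self.study_id}: duplicate probe ids {dupes[:5]}")
        missing = set(self.m_values.index) - set(self.manifest["probe"])
        if missing:
            raise ValueError(
                f"{self.study_id}: manifest does not cover probes "
                f"{sorted(missing)[:5]}"
            )

    @property
    def n_samples(self) -> int:
        return self.m_values.shape[1]

    @property
    def n_case(self) -> int:
        return int(self.phenotype.sum())

    @property
    def n_control(self) -> int:
        return len(self.phenotype) - self.n_case


@dataclass
class ProteinPanel:
    """Relative protein abundances with a below-detection mask.

    ``abundance`` is samples x proteins; ``below_llod`` is a boolean frame of
    the same shape flagging values under the assay's lower limit of
    detection.
    """

    abundance: pd.DataFrame
    below_llod: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.abundance.shape != self.below_llod.shape:
            raise ValueError(
                "below-LLOD mask shape "
                f"{self.below_llod.shape} does not match abundance "
                f"{self.abundance.shape}"
            )

    @property
    def proteins(self) -> list[str]:
        return list(self.abundance.columns)

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[0]
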