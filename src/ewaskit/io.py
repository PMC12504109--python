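"""TSV readers and writers with explicit column contracts.

Dialect: tab-separated, UTF-8, ``.`` for missing values, header row
mandatory and order-insensitive.  Genomic positions are 1-based inclusive
internally; BED exports (see :func:`ewaskit.dmr.write_dmr_bed`) convert to
0-based half-open.  Chromosome labels are normalized by stripping any
``chr`` prefix.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MANIFEST_COLUMNS, SUMMARY_STAT_COLUMNS

__all__ = [
    "read_summary_stats",
    "write_summary_stats",
    "read_manifest",
    "write_manifest",
    "normalize_chromosome",
]

logger = logging.getLogger(__name__)

_NUMERIC_STAT_COLUMNS = {"beta": float, "se": float, "p": float, "pos": int,
                         "n": int, "n_case": int, "n_control": int}


def normalize_chromosome(label) -> str:
    """Map 'chr3' and '3' to the one internal convention ('3')."""
    text = str(label)
    return text[3:] if text.lower().startswith("chr") else text


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["."], keep_default_na=True)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing mandatory column(s) {missing}")
    if df.empty:
        logger.warning("%s: valid header but no data rows", path.name)
    return df


def _coerce_numeric(df: pd.DataFrame, path: Path, columns: dict) -> pd.DataFrame:
    for col, kind in columns.items():
        if col not in df.columns:
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            lines = (df.index[bad] + 2).tolist()  # +2: header + 1-based
            raise ValueError(
                f"{path.name}: non-numeric '{col}' at line(s) {lines[:5]}"
            )
        df[col] = converted.astype(float if kind is float else "Int64")
    return df


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    """Read a per-study or meta-analysis summary-statistics TSV.

    Mandatory columns: probe, chr, pos, beta, se, p, n, n_case, n_control,
    study_id, array, model.  Unparseable numeric cells are rejected with
    their line numbers.
    """
    path = Path(path)
    df = _read_tsv(path, SUMMARY_STAT_COLUMNS)
    df = _coerce_numeric(df, path, _NUMERIC_STAT_COLUMNS)
    df["chr"] = df["chr"].map(normalize_chromosome)
    for col in ("n", "n_case", "n_control", "pos"):
        df[col] = df[col].astype(int)
    return df[SUMMARY_STAT_COLUMNS]


def write_summary_stats(stats: pd.DataFrame, path: str | Path) -> None:
    stats[SUMMARY_STAT_COLUMNS].to_csv(path, sep="\t", index=False, na_rep=".")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a probe manifest TSV (probe, chr, pos, gene, island_relation,
    array).  Positions are parsed as 1-based integers; duplicate probe ids
    are rejected."""
    path = Path(path)
    df = _read_tsv(path, MANIFEST_COLUMNS)
    df = _coerce_numeric(df, path, {"pos": int})
    df["pos"] = df["pos"].astype(int)
    df["chr"] = df["chr"].map(normalize_chromosome)
    dupes = df.loc[df["probe"].duplicated(), "probe"].tolist()
    if dupes:
        raise ValueError(f"{path.name}: duplicate probe id(s) {sorted(set(dupes))[:10]}")
    return df[MANIFEST_COLUMNS]


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest[MANIFEST_COLUMNS].to_csv(path, sep="\t", index=False, na_rep=".")
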