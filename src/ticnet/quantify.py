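"""Peptide -> protein TIC rollup, detection filtering and replicate QC.

A protein's total ion count (TIC) in a sample is the sum of the summed
fragment intensities of its member peptides in that sample. A protein
enters a two-state comparison only if it was detected in both biological
replicates of both states; everything else is reported as ND downstream.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import Comparison, TicTable
from .errors import InsufficientDataError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

PEPTIDE_COLUMNS = ["peptide_id", "protein_id", "sample_id", "intensity"]


def rollup_tic(peptides: pd.DataFrame, design: dict | None = None) -> TicTable:
    """Sum peptide intensities per (protein, sample) into a TIC table.

    Parameters
    ----------
    peptides
        DataFrame with columns ``peptide_id, protein_id, sample_id,
        intensity``. Duplicate (peptide, sample) rows are aggregated with a
        logged warning; negative intensities are rejected.
    design
        Optional sample design; parsed from ``<state>_rep<k>`` sample ids
        when omitted.

    Proteins with no peptides in a sample come out as ND (NaN) there.
    """
    if peptides.empty:
        raise ValidationError("empty peptide table")
    missing = [c for c in PEPTIDE_COLUMNS if c not in peptides.columns]
    if missing:
        raise SchemaError(f"peptide table missing columns: {missing}")
    if (peptides["intensity"] < 0).any():
        bad = peptides.loc[peptides["intensity"] < 0, "peptide_id"].iloc[0]
        raise ValidationError(f"negative intensity for peptide {bad!r}")

    dup = peptides.duplicated(subset=["peptide_id", "sample_id"])
    if dup.any():
        logger.warning(
            "aggregating %d duplicate (peptide, sample) rows", int(dup.sum())
        )

    tic = (
        peptides.groupby(["protein_id", "sample_id"], sort=True)["intensity"]
        .sum()
        .unstack("sample_id")
    )
    tic.index.name = "protein_id"
    # a zero sum can only arise from explicit zero-intensity rows: treat as ND
    tic = tic.where(tic > 0)
    return TicTable(tic, design=design or {})


def filter_detected(table: TicTable, comparison: Comparison) -> TicTable:
    """Keep proteins observed (non-ND) in all four samples of a comparison.

    The returned table is restricted to the comparison's four sample
    columns. The operation is idempotent.
    """
    cols = table.comparison_samples(comparison)
    sub = table.values[cols]
    kept = sub.dropna()
    logger.info(
        "detection filter %s: %d of %d proteins observed in all 4 samples",
        comparison.label, len(kept), len(sub),
    )
    return TicTable(kept, design={c: table.design[c] for c in cols})


def nd_proteins(table: TicTable, comparison: Comparison) -> pd.Index:
    """Proteins excluded from a comparison by the detection rule."""
    cols = table.comparison_samples(comparison)
    mask = table.values[cols].isna().any(axis=1)
    return table.values.index[mask]


def detected_per_state(table: TicTable, state: str) -> int:
    """Number of proteins observed in both replicates of ``state``.

    This is the per-condition identified-protein count logged by the
    pipeline (analysis step 1).
    """
    cols = table.samples_for(state)
    return int(table.values[cols].notna().all(axis=1).sum())


def replicate_correlation(table: TicTable, state: str) -> float:
    """Pearson correlation of log2 TIC between the two replicates of a state.

    Computed over proteins detected in both replicates; at least three
    co-detected proteins are required.
    """
    cols = table.samples_for(state)
    if len(cols) != 2:
        raise SchemaError(f"state {state!r} must have exactly 2 replicates")
    pair = table.values[cols].dropna()
    if len(pair) < 3:
        raise InsufficientDataError(
            f"state {state!r}: only {len(pair)} proteins detected in both "
            "replicates (need >= 3)"
        )
    x, y = np.log2(pair[cols[0]]), np.log2(pair[cols[1]])
    r = stats.pearsonr(x, y).statistic
    return float(r)
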