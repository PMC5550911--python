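"""Protein-level matrix assembly.

Rolls normalized peptide areas up to proteins, applies the missingness
filter (a protein may lack at most one measurement per condition), and
log10-transforms the retained intensities for testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AssembleError",
    "QuantMatrix",
    "rollup_proteins",
    "filter_missingness",
    "log10_transform",
    "read_matrix_tsv",
    "write_matrix_tsv",
]

log = logging.getLogger(__name__)

CONDITION_CONTROL = "control_18C"
CONDITION_ELEVATED = "elevated_22C"


class AssembleError(ValueError):
    pass


@dataclass
class QuantMatrix:
    """Protein x sample table of (normalized) areas with condition labels.

    ``data`` holds proteins as rows and samples as columns; missing
    measurements are NaN. ``conditions`` maps each sample id to its
    condition label. ``log10`` records whether values are log10-transformed.
    """

    data: pd.DataFrame
    conditions: pd.Series
    log10: bool = False

    def __post_init__(self) -> None:
        self.conditions = pd.Series(self.conditions)
        missing = [c for c in self.data.columns if c not in self.conditions.index]
        if missing:
            raise AssembleError(f"samples without condition labels: {missing}")
        self.conditions = self.conditions.loc[list(self.data.columns)]
        counts = self.conditions.value_counts()
        if (counts < 2).any():
            raise AssembleError(f"need >= 2 samples per condition, got {counts.to_dict()}")

    @property
    def proteins(self) -> list[str]:
        return list(self.data.index)

    @property
    def condition_labels(self) -> list[str]:
        # stable order of first appearance
        return list(dict.fromkeys(self.conditions))

    def samples_for(self, condition: str) -> list[str]:
        return list(self.conditions.index[self.conditions == condition])

    def values_for(self, protein: str, condition: str, dropna: bool = True) -> np.ndarray:
        v = self.data.loc[protein, self.samples_for(condition)].to_numpy(dtype=float)
        return v[~np.isnan(v)] if dropna else v

    def copy(self) -> "QuantMatrix":
        return QuantMatrix(self.data.copy(), self.conditions.copy(), self.log10)


def rollup_proteins(
    peptide_table: pd.DataFrame,
    peptide_map: pd.DataFrame | None = None,
    conditions: pd.Series | dict | None = None,
    agg: str = "sum",
    area_col: str = "normalized_area",
) -> QuantMatrix:
    """Aggregate peptide areas to protein areas per replicate.

    ``peptide_table`` needs ``peptide``, ``replicate`` and ``area_col``
    columns plus either a ``protein`` column or a two-column
    ``peptide_map`` (peptide, protein). Peptides mapping to more than one
    protein (shared/degenerate peptides) are dropped with a log message;
    peptides with no mapping are an error listing the offenders. A protein
    is missing in a replicate when none of its peptides was quantified
    there; a replicate where only some peptides are present is aggregated
    from the available ones.
    """
    table = peptide_table.copy()
    if "protein" not in table.columns:
        if peptide_map is None:
            raise AssembleError("peptide_table lacks a 'protein' column and no peptide_map given")
        pm = peptide_map[["peptide", "protein"]].drop_duplicates()
        shared = pm["peptide"][pm["peptide"].duplicated(keep=False)].unique()
        if len(shared):
            log.info("dropping %d shared peptide(s) from rollup", len(shared))
            pm = pm[~pm["peptide"].isin(shared)]
            table = table[~table["peptide"].isin(shared)]
        table = table.merge(pm, on="peptide", how="left")
    unmapped = sorted(table.loc[table["protein"].isna(), "peptide"].unique())
    if unmapped:
        raise AssembleError(f"peptides with no protein mapping: {unmapped}")
    if agg not in ("sum", "mean"):
        raise AssembleError(f"unknown rollup aggregation {agg!r}")
    # min_count=1 keeps a replicate NaN (missing) when every peptide is NaN
    pivot = table.pivot_table(
        index="protein",
        columns="replicate",
        values=area_col,
        aggfunc="sum" if agg == "sum" else "mean",
        dropna=False,
    )
    present = table.pivot_table(
        index="protein", columns="replicate", values=area_col, aggfunc="count", dropna=False
    )
    pivot = pivot.where(present.fillna(0) > 0)
    pivot.index.name = "protein"
    pivot.columns.name = None
    if conditions is None:
        conditions = pd.Series({c: CONDITION_CONTROL for c in pivot.columns})
        log.warning("no condition labels supplied; labeling all replicates %s", CONDITION_CONTROL)
    return QuantMatrix(pivot, pd.Series(conditions))


def filter_missingness(
    matrix: QuantMatrix, max_missing_per_condition: int = 1
) -> tuple[QuantMatrix, list[str]]:
    """Drop proteins missing more than ``max_missing_per_condition``
    measurements in any condition; returns the filtered matrix and the list
    of removed proteins."""
    keep = pd.Series(True, index=matrix.data.index)
    for cond in matrix.condition_labels:
        cols = matrix.samples_for(cond)
        n_missing = matrix.data[cols].isna().sum(axis=1)
        keep &= n_missing <= max_missing_per_condition
    removed = list(matrix.data.index[~keep])
    out = QuantMatrix(matrix.data.loc[keep].copy(), matrix.conditions.copy(), matrix.log10)
    return out, removed


def log10_transform(matrix: QuantMatrix) -> QuantMatrix:
    """Cell-wise log10; missing values stay missing.

    Non-missing values must be positive — guaranteed upstream by the noise
    floor, enforced here as a domain guard.
    """
    if matrix.log10:
        raise AssembleError("matrix is already log10-transformed")
    vals = matrix.data.to_numpy(dtype=float)
    bad = (vals <= 0) & ~np.isnan(vals)
    if bad.any():
        rows = sorted(matrix.data.index[bad.any(axis=1)])
        raise AssembleError(f"non-positive intensities cannot be log10-transformed: {rows}")
    return QuantMatrix(np.log10(matrix.data), matrix.conditions.copy(), log10=True)


# ---------------------------------------------------------------------------
# TSV dialect (matrix + two-column condition sidecar)
# ---------------------------------------------------------------------------


def write_matrix_tsv(matrix: QuantMatrix, matrix_path, conditions_path) -> None:
    matrix.data.to_csv(matrix_path, sep="\t", index_label="protein", na_rep="NA")
    matrix.conditions.rename("condition").to_csv(conditions_path, sep="\t", index_label="sample")


def read_matrix_tsv(matrix_path, conditions_path, log10: bool = False) -> QuantMatrix:
    data = pd.read_csv(matrix_path, sep="\t", index_col="protein", na_values=["NA"])
    cond = pd.read_csv(conditions_path, sep="\t", index_col="sample")["condition"]
    return QuantMatrix(data, cond, log10=log10)
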