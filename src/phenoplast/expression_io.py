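"""Reading and preprocessing of protein expression tables.

Densitometry-normalized western-blot panels arrive as CSV tables with one row
per (case x region x replicate run) and one column per protein.  This module
reads and validates those tables, averages replicate runs, optionally fills
missing cells by nearest-neighbor imputation, and centers the protein matrix
for the downstream PCA (columns are centered but never scaled, so abundant
proteins keep their variance).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("phenoplast")

#: Cell contents treated as missing, compared case-insensitively after strip.
MISSING_TOKENS = frozenset({"", "na", "nan"})

#: Metadata fields that, when present, form the unique row key.
KEY_FIELDS = ("case_id", "region", "run")


class PhenoplastError(Exception):
    """User-facing error (bad input, violated precondition)."""


@dataclass
class ExpressionTable:
    """A protein expression panel: metadata columns plus a protein matrix.

    ``data`` holds metadata columns as strings (preserved verbatim) and
    protein columns as floats with NaN for missing cells.
    """

    data: pd.DataFrame
    protein_names: list[str]
    metadata_fields: list[str]

    def __post_init__(self) -> None:
        if len(set(self.protein_names)) != len(self.protein_names):
            raise PhenoplastError("duplicate protein names in panel")
        values = self.data[self.protein_names].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any(values < 0):
                raise PhenoplastError("protein values must be nonnegative")
        key = [f for f in KEY_FIELDS if f in self.metadata_fields]
        if key and self.data.duplicated(subset=key).any():
            dup = self.data.loc[self.data.duplicated(subset=key), key].iloc[0]
            raise PhenoplastError(
                f"duplicate {tuple(key)} combination: {tuple(dup)}"
            )

    @property
    def n_rows(self) -> int:
        return len(self.data)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_names)

    def protein_matrix(self) -> np.ndarray:
        return self.data[self.protein_names].to_numpy(dtype=float)

    def accounting(self) -> dict:
        """Row/cell bookkeeping in the style of a design-size table."""
        values = self.protein_matrix()
        return {
            "rows": int(values.shape[0]),
            "proteins": int(values.shape[1]),
            "cells": int(values.size),
            "observed_cells": int(np.isfinite(values).sum()),
            "missing_cells": int(np.isnan(values).sum()),
        }

    def log_accounting(self, label: str = "table") -> dict:
        acct = self.accounting()
        logger.info("%s accounting: %s", label, json.dumps(acct))
        return acct


@dataclass
class CenteredMatrix:
    """Column-centered (never scaled) protein matrix ready for PCA."""

    values: np.ndarray
    column_means: np.ndarray
    protein_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = max(1, self.values.shape[0])
        if np.abs(self.values.sum(axis=0)).max() > 1e-9 * n:
            raise PhenoplastError("matrix is not column-centered")
        if np.isnan(self.values).any():
            raise PhenoplastError("centered matrix contains missing values")


def _parse_protein_cell(cell: object) -> float:
    if cell is None:
        return np.nan
    text = str(cell).strip()
    if text.lower() in MISSING_TOKENS:
        return np.nan
    try:
        value = float(text)
    except ValueError:
        return np.nan
    return value


def read_expression_table(
    path,
    protein_columns: list[str],
    metadata_columns: list[str],
) -> ExpressionTable:
    """Read a CSV panel, parsing protein cells as floats and keeping metadata verbatim.

    Non-parsable protein cells (empty, "NA", "NaN", stray text) become missing.
    Raises :class:`PhenoplastError` for absent files, absent declared columns,
    or duplicate (case_id, region, run) keys.
    """
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise PhenoplastError(f"input file not found: {path}") from None
    for col in list(metadata_columns) + list(protein_columns):
        if col not in raw.columns:
            raise PhenoplastError(f"declared column absent from {path}: {col!r}")
    data = raw[list(metadata_columns)].copy()
    for col in protein_columns:
        data[col] = raw[col].map(_parse_protein_cell)
    table = ExpressionTable(
        data=data.reset_index(drop=True),
        protein_names=list(protein_columns),
        metadata_fields=list(metadata_columns),
    )
    table.log_accounting(label=str(path))
    return table


def average_runs(table: ExpressionTable, run_field: str = "run") -> ExpressionTable:
    """Collapse replicate runs to their per-cell arithmetic mean.

    A cell is averaged over the runs where it was observed and stays missing
    only when missing in every run.  The run column is dropped; remaining
    metadata is taken from the first run of each (case, region) group.  With
    no run field the table is returned unchanged.
    """
    if run_field not in table.metadata_fields:
        return table
    group_fields = [f for f in table.metadata_fields if f != run_field]
    if not group_fields:
        raise PhenoplastError("cannot average runs without grouping metadata")
    grouped = table.data.groupby(group_fields, sort=False, as_index=False)
    data = grouped[table.protein_names].mean()  # NaN-skipping mean
    out = ExpressionTable(
        data=data,
        protein_names=list(table.protein_names),
        metadata_fields=group_fields,
    )
    out.log_accounting(label="run-averaged")
    return out


def impute_missing(table: ExpressionTable, k: int = 10, seed: int = 0) -> ExpressionTable:
    """Fill missing cells with the mean over the k nearest rows.

    Distances are Euclidean over the proteins observed in both rows, computed
    on column-standardized values (standardization is for the distance only;
    imputed values are on the original scale).  Neighbors must observe the
    target protein; distance ties break by row order.  ``k`` is capped at the
    number of complete rows minus one.  ``seed`` is accepted for interface
    uniformity; the procedure is deterministic.
    """
    del seed
    values = table.protein_matrix()
    observed = np.isfinite(values)
    if not observed.any(axis=1).all():
        bad = np.where(~observed.any(axis=1))[0]
        keys = table.data.iloc[bad].to_dict("records")
        raise PhenoplastError(f"rows with all proteins missing: {keys}")
    for j, name in enumerate(table.protein_names):
        if not observed[:, j].any():
            raise PhenoplastError(f"protein never observed: {name}")
    if not observed.all():
        complete = int(observed.all(axis=1).sum())
        if complete < 1:
            raise PhenoplastError("k-NN imputation requires at least one complete row")
        k = max(1, min(int(k), complete - 1 if complete > 1 else 1))
        col_mean = np.nanmean(values, axis=0)
        col_sd = np.nanstd(values, axis=0, ddof=1)
        col_sd[~np.isfinite(col_sd) | (col_sd == 0)] = 1.0
        z = (values - col_mean) / col_sd
        filled = values.copy()
        for i in np.where(~observed.all(axis=1))[0]:
            for j in np.where(~observed[i])[0]:
                candidates = np.where(observed[:, j] & (np.arange(len(values)) != i))[0]
                dists = []
                for c in candidates:
                    shared = observed[i] & observed[c]
                    if not shared.any():
                        dists.append(np.inf)
                        continue
                    diff = z[i, shared] - z[c, shared]
                    dists.append(float(np.sqrt(np.sum(diff**2))))
                order = np.argsort(np.asarray(dists), kind="stable")[:k]
                neighbors = candidates[order]
                filled[i, j] = float(np.mean(values[neighbors, j]))
        values = filled
    data = table.data.copy()
    data[table.protein_names] = values
    out = ExpressionTable(
        data=data,
        protein_names=list(table.protein_names),
        metadata_fields=list(table.metadata_fields),
    )
    out.log_accounting(label="imputed")
    return out


def center(table: ExpressionTable) -> CenteredMatrix:
    """Subtract column means; never divide by the standard deviation."""
    values = table.protein_matrix()
    if np.isnan(values).any():
        raise PhenoplastError(
            "missing cells present: run average_runs and/or impute_missing first"
        )
    means = values.mean(axis=0)
    return CenteredMatrix(
        values=values - means,
        column_means=means,
        protein_names=list(table.protein_names),
    )


def write_expression_table(table: ExpressionTable, path) -> None:
    table.data.to_csv(path, index=False)


def write_accounting(table: ExpressionTable, path) -> None:
    with open(path, "w") as fh:
        json.dump(table.accounting(), fh, indent=2)
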