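"""Readers and writers for the tabular peak-table convention.

Three inputs: a data matrix (features x samples intensities), a variable
metadata table (feature id, m/z, RT, arbitrary extra columns) and a square
pairwise similarity matrix, all tab- or comma-delimited with one header row
and the feature identifier in the first column.  An optional fourth input is
a two-column (label, delta) list of reference mass differences; the token
``"default"`` selects the builtin list.

Outputs: the variable metadata table with five appended result columns, and
a Cytoscape SIF network file of the above-threshold correlated pairs.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable, Sequence

import pandas as pd

from .deltas import BUILTIN_TOKEN, default_delta_list
from .tables import DeltaEntry, DeltaList, FeatureTable, IntensityMatrix, SimilarityMatrix

__all__ = [
    "read_data_matrix",
    "read_variable_metadata",
    "read_similarity_matrix",
    "read_delta_list",
    "write_sif",
    "write_annotated_metadata",
    "RESULT_COLUMN_ORDER",
]

logger = logging.getLogger(__name__)

#: order of the appended result columns; the representative column name is
#: method-dependent (``representative_<method>``) and fills the placeholder.
RESULT_COLUMN_ORDER = (
    "ACorF_groups",
    "isotopes_adducts_fragments",
    "ACorF_filter",
    "representative_{method}",
    "annotation_relative_to_representative",
)

_DEFAULT_SENTINEL = object()


def _detect_delimiter(path: str) -> str:
    """Pick tab vs comma from the header line (tab wins when both appear)."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    if "\t" in header:
        sep = "\t"
    elif "," in header:
        sep = ","
    else:
        sep = "\t"
    logger.debug("detected %r delimiter in %s", sep, path)
    return sep


def _check_nonempty(path: str) -> None:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if os.path.getsize(path) == 0:
        raise ValueError(f"empty file: {path}")


def read_data_matrix(path: str, features_in_rows: bool = True) -> IntensityMatrix:
    """Read the intensity matrix; non-numeric cells become missing.

    Parameters
    ----------
    path
        Tab- or comma-delimited table, one header row, feature (or sample)
        identifiers in the first column.
    features_in_rows
        When ``False`` the table is transposed after reading so that rows
        are features.
    """
    _check_nonempty(path)
    sep = _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if not features_in_rows:
        df = df.T
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate feature identifiers in data matrix: {dup}")
    values = df.apply(pd.to_numeric, errors="coerce")
    logger.info("data matrix: %d features x %d samples", *values.shape)
    return IntensityMatrix(values)


def _resolve_column(df: pd.DataFrame, requested, what: str) -> str | None:
    """Case-insensitive column lookup.

    An explicitly requested name that is absent is a hard error; the
    default name ('mz'/'rt') is allowed to be absent and returns None.
    """
    explicit = requested is not _DEFAULT_SENTINEL
    name = {"m/z": "mz", "retention time": "rt"}[what] if not explicit else requested
    lowered = {c.lower(): c for c in df.columns}
    hit = lowered.get(str(name).lower())
    if hit is None and explicit:
        raise ValueError(
            f"requested {what} column {name!r} not found; available columns: {list(df.columns)}"
        )
    return hit


def read_variable_metadata(
    path: str,
    mz_column=_DEFAULT_SENTINEL,
    rt_column=_DEFAULT_SENTINEL,
) -> FeatureTable:
    """Read per-feature metadata, binding m/z and RT columns by name.

    Column matching is case-insensitive; the defaults are ``mz`` and ``rt``.
    All cells are kept as strings so the original columns survive a
    read -> write round trip unchanged.
    """
    _check_nonempty(path)
    sep = _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[1] < 1:
        raise ValueError(f"no columns found in {path}")
    id_column = df.columns[0]
    mz_col = _resolve_column(df, mz_column, "m/z")
    rt_col = _resolve_column(df, rt_column, "retention time")
    table = FeatureTable(df, id_column=id_column, mz_column=mz_col, rt_column=rt_col)
    logger.info(
        "variable metadata: %d features, mz=%r rt=%r", len(df), mz_col, rt_col
    )
    return table


def read_similarity_matrix(path: str) -> SimilarityMatrix:
    """Read the square pairwise similarity table (CSV or TSV).

    The first row and first column carry feature identifiers.  Asymmetry
    beyond 1e-6 or a non-square shape is a hard error.
    """
    _check_nonempty(path)
    sep = _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.shape[0] != df.shape[1]:
        raise ValueError(
            f"similarity matrix is non-square: {df.shape[0]} rows x {df.shape[1]} columns"
        )
    if list(df.index) != list(df.columns):
        # accept identical sets in different order by aligning columns to rows
        if set(df.index) == set(df.columns):
            df = df.loc[:, df.index]
        else:
            raise ValueError("similarity matrix row and column identifiers differ")
    df = df.apply(pd.to_numeric, errors="coerce")
    logger.info("similarity matrix: %d features", df.shape[0])
    return SimilarityMatrix(df)


def read_delta_list(source: str) -> DeltaList:
    """Read a two-column (label, delta) list, or the builtin default.

    Passing the token ``"default"`` returns the shipped reference list.
    Non-positive or non-numeric deltas are hard errors reported with their
    line number.
    """
    if source == BUILTIN_TOKEN:
        return default_delta_list()
    _check_nonempty(source)
    sep = _detect_delimiter(source)
    entries: list[DeltaEntry] = []
    with open(source, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            parts = line.split(sep)
            if len(parts) < 2:
                raise ValueError(f"{source}:{lineno}: expected two columns (label, delta)")
            label = parts[0].strip()
            # tolerate a header row
            if lineno == 1 and label.lower() in {"label", "name", "annotation"}:
                continue
            try:
                delta = float(parts[1])
            except ValueError:
                raise ValueError(
                    f"{source}:{lineno}: non-numeric delta {parts[1]!r}"
                ) from None
            if delta <= 0:
                raise ValueError(f"{source}:{lineno}: delta must be > 0, got {delta}")
            entries.append(DeltaEntry(label, delta))
    dl = DeltaList(entries)
    logger.info("delta list: %d entries from %s", len(dl), source)
    return dl


def write_sif(pairs: Iterable, path: str) -> None:
    """Write the above-threshold pairs as a Cytoscape SIF network file.

    One line per unordered pair, three tab-separated tokens: the first
    feature id, the similarity rendered to 4 decimal places as the
    interaction label, the second feature id.
    """
    seen: set[frozenset[str]] = set()
    with open(path, "w", encoding="utf-8") as fh:
        for p in pairs:
            key = frozenset((p.id_a, p.id_b))
            if key in seen:
                continue
            seen.add(key)
            fh.write(f"{p.id_a}\t{p.similarity:.4f}\t{p.id_b}\n")
    logger.info("wrote %d pairs to %s", len(seen), path)


def write_annotated_metadata(table: pd.DataFrame, path: str, sep: str = "\t") -> None:
    """Write the annotated variable metadata table (original columns first)."""
    table.to_csv(path, sep=sep, index=False)
    logger.info("wrote annotated metadata (%d rows) to %s", len(table), path)


def write_data_matrix(matrix: IntensityMatrix, path: str, sep: str = "\t") -> None:
    """Write an intensity matrix with features in rows."""
    matrix.values.to_csv(path, sep=sep, index_label="feature")
    logger.info("wrote data matrix %dx%d to %s", *matrix.values.shape, path)


def write_similarity_matrix(sim: SimilarityMatrix, path: str, sep: str = "\t") -> None:
    """Write a similarity matrix in the square layout the reader accepts."""
    sim.values.to_csv(path, sep=sep, index_label="feature")
    logger.info("wrote similarity matrix (%d features) to %s", sim.values.shape[0], path)
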