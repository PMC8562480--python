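"""Readers and writers for the pipeline's plain-text formats.

Tables are tab-separated UTF-8 with a ``#SampleID``-style id column (the
QIIME-era convention); trees are newick.  The internal orientation for OTU
tables is samples-as-rows; ``read_otu_table`` normalizes either file
orientation to it.
"""
from __future__ import annotations

from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .containers import (
    DistanceMatrix,
    FormatError,
    OtuTable,
    PhyloTree,
    SampleMetadata,
)

__all__ = [
    "read_otu_table", "write_otu_table",
    "read_tree", "write_tree",
    "read_metadata", "write_metadata",
    "read_distance_matrix", "write_distance_matrix",
    "to_relative",
]

Orientation = Literal["samples-as-rows", "samples-as-columns"]

_ID_HEADER = "#SampleID"


def _read_tsv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0,
                         encoding="utf-8", comment=None)
    except pd.errors.ParserError as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_otu_table(path, orientation: Orientation = "samples-as-rows") -> OtuTable:
    """Read a tab-separated OTU table.

    Parameters
    ----------
    path
        TSV file with one id header row and one id column, numeric body.
    orientation
        Whether samples are file rows or file columns; the result is always
        samples-as-rows.
    """
    if orientation not in ("samples-as-rows", "samples-as-columns"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_tsv(path)
    if orientation == "samples-as-columns":
        df = df.T
    bad = df.columns[[not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]]
    if len(bad):
        raise FormatError(f"non-numeric OTU table columns: {list(bad)}")
    return OtuTable(df, is_relative=False)


def write_otu_table(table: OtuTable, path) -> None:
    df = table.data.copy()
    df.index.name = _ID_HEADER
    df.to_csv(path, sep="\t", encoding="utf-8")


def read_tree(path) -> PhyloTree:
    """Read a rooted newick tree; missing branch lengths are rejected."""
    return PhyloTree.from_path(path)


def write_tree(tree: PhyloTree, path) -> None:
    Path(path).write_text(tree.to_newick(), encoding="utf-8")


def read_metadata(path, env_vars: tuple[str, ...] | None = None) -> SampleMetadata:
    df = _read_tsv(path)
    return SampleMetadata(df, env_vars=env_vars)


def write_metadata(metadata: SampleMetadata, path) -> None:
    df = metadata.data.copy()
    df.index.name = _ID_HEADER
    df.to_csv(path, sep="\t", encoding="utf-8")


def read_distance_matrix(path) -> DistanceMatrix:
    df = _read_tsv(path)
    return DistanceMatrix.from_dataframe(df)


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    df = dm.to_dataframe()
    df.index.name = _ID_HEADER
    df.to_csv(path, sep="\t", encoding="utf-8")


def to_relative(table: OtuTable) -> OtuTable:
    """Convert counts to per-sample proportions.

    Thin functional alias for :meth:`OtuTable.to_relative`; errors on
    zero-total samples, listing their ids.
    """
    return table.to_relative()
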