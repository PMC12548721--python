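"""Delimited-table readers and fingerprint-matrix serialisation.

Datasets are plain delimited text with a header row; the delimiter is
auto-detected between comma and tab (anything else needs an explicit
``sep``).  Malformed rows are routed to a reject list with a reason,
never silently dropped.  Fingerprint matrices round-trip losslessly as
dense delimited text or as sparse (row, col, value) triplets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError

logger = logging.getLogger(__name__)


@dataclass
class RejectEntry:
    row_index: int
    reason: str
    content: str


def detect_delimiter(path: str | Path) -> str:
    """Pick comma or tab from the header line; tabs win if present."""
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_dataset_table(
    path: str | Path,
    smiles_column: str,
    label_column: str | None = None,
    sep: str | None = None,
) -> tuple[pd.DataFrame, list[RejectEntry]]:
    """Read a dataset table, validating the named columns.

    Returns the well-formed rows and a reject list for rows with missing
    values in the required columns.  A missing column raises
    :class:`SchemaError` naming the columns that are available.
    """
    sep = sep or detect_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in filter(None, [smiles_column, label_column]):
        if col not in df.columns:
            raise SchemaError(
                f"column {col!r} not found; available: {list(df.columns)}"
            )
    required = [smiles_column] + ([label_column] if label_column else [])
    rejects = []
    bad = df[required].isna().any(axis=1)
    for idx in df.index[bad]:
        rejects.append(
            RejectEntry(int(idx), "missing required value", str(df.loc[idx].to_dict()))
        )
    if rejects:
        logger.warning("%d malformed row(s) rejected from %s", len(rejects), path)
    return df[~bad].reset_index(drop=True), rejects


def write_rejects(rejects: list[RejectEntry], path: str | Path) -> None:
    pd.DataFrame(
        [{"row": r.row_index, "reason": r.reason, "content": r.content} for r in rejects]
    ).to_csv(path, index=False)


def write_fingerprint_matrix(
    fps, path: str | Path, sparse: bool = False, sep: str = "\t"
) -> None:
    """Write fingerprints as dense rows or sparse (row, col, value) triplets.

    Counts are written as integers, never binarized; a round-trip read
    recovers the identical matrix.
    """
    X = np.asarray(fps)
    if X.ndim != 2:
        raise ValueError("fingerprint matrix must be 2-D with uniform widths")
    if sparse:
        rows, cols = np.nonzero(X)
        df = pd.DataFrame(
            {"row": rows, "col": cols, "value": X[rows, cols]}
        )
        with open(path, "w") as fh:
            fh.write(f"# sparse {X.shape[0]} {X.shape[1]}\n")
            df.to_csv(fh, sep=sep, index=False)
    else:
        pd.DataFrame(X).to_csv(path, sep=sep, index=False)


def read_fingerprint_matrix(path: str | Path, sep: str = "\t") -> np.ndarray:
    """Read a matrix written by :func:`write_fingerprint_matrix`."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# sparse"):
        _, _, n_rows, n_cols = first.split()
        df = pd.read_csv(path, sep=sep, skiprows=1)
        X = np.zeros((int(n_rows), int(n_cols)), dtype=np.int64)
        X[df["row"], df["col"]] = df["value"]
        return X
    return pd.read_csv(path, sep=sep).to_numpy(dtype=np.int64)
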