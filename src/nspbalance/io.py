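"""Delimited-text matrix I/O and JSON result records.

Matrices travel as plain CSV/TSV so that any spreadsheet or ``numpy.loadtxt``
call can produce or consume them.  Results are JSON records carrying the
measure name, its value (scalar or vector) and provenance metadata.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("nspbalance")

__all__ = [
    "MatrixParseError",
    "ResultRecord",
    "read_matrix",
    "write_matrix",
    "write_results",
    "read_results",
    "matrix_sha256",
]


class MatrixParseError(ValueError):
    """A delimited matrix file could not be parsed as a finite numeric table."""


def _infer_delimiter(path: str | os.PathLike) -> str:
    suffix = os.path.splitext(os.fspath(path))[1].lower()
    return "\t" if suffix in (".tsv", ".tab") else ","


def read_matrix(
    path: str | os.PathLike,
    delimiter: str | None = None,
    has_header: bool = False,
) -> np.ndarray:
    """Read a dense numeric matrix from a delimited text file.

    Parameters
    ----------
    path
        File to read.  An empty file is an error.
    delimiter
        Cell separator; inferred from the file suffix when omitted
        (``.tsv``/``.tab`` -> tab, otherwise comma).
    has_header
        Skip the first row if it holds column names.

    Returns
    -------
    numpy.ndarray
        2-D float array.  Non-numeric or non-finite cells raise
        :class:`MatrixParseError` naming the offending 1-based row/column.
    """
    path = os.fspath(path)
    if delimiter is None:
        delimiter = _infer_delimiter(path)
    try:
        df = pd.read_csv(
            path,
            sep=delimiter,
            header=0 if has_header else None,
            comment="#",
            dtype=str,
            skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError as exc:
        raise MatrixParseError(f"{path}: file is empty") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise MatrixParseError(f"{path}: file holds no matrix rows")

    raw = df.to_numpy()
    offset = 2 if has_header else 1  # user-facing row numbers are 1-based
    values = np.empty(raw.shape, dtype=float)
    for (r, c), cell in np.ndenumerate(raw):
        try:
            values[r, c] = float(cell)
        except (TypeError, ValueError):
            raise MatrixParseError(
                f"{path}: non-numeric cell {cell!r} at row {r + offset}, "
                f"column {c + 1}"
            ) from None
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        r, c = bad[0]
        raise MatrixParseError(
            f"{path}: non-finite value at row {r + offset}, column {c + 1}"
        )
    logger.info("read matrix %s shape=%s", path, values.shape)
    return values


def write_matrix(
    values: np.ndarray,
    path: str | os.PathLike,
    delimiter: str = ",",
    fmt: str = "%.12g",
) -> None:
    """Write a dense matrix as delimited text (12 significant digits)."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if not np.all(np.isfinite(values)):
        raise ValueError("refusing to write non-finite matrix entries")
    np.savetxt(path, values, delimiter=delimiter, fmt=fmt)


@dataclass
class ResultRecord:
    """A named measure plus provenance, serializable to JSON without loss."""

    name: str
    value: float | Sequence[float]
    metadata: dict[str, Any] = field(default_factory=dict)

    def to_json_obj(self) -> dict[str, Any]:
        value = self.value
        if isinstance(value, np.ndarray):
            value = value.tolist()
        elif isinstance(value, (np.floating, np.integer)):
            value = value.item()
        elif isinstance(value, (list, tuple)):
            value = [float(v) for v in value]
        return {"name": self.name, "value": value, "metadata": self.metadata}


def write_results(records: Sequence[ResultRecord], path: str | os.PathLike) -> None:
    """Serialize result records to a JSON file.

    Floats survive a write/read round trip exactly (``repr``-precision JSON).
    An empty record list is rejected: silently writing nothing has hidden
    upstream failures before.
    """
    records = list(records)
    if not records:
        raise ValueError("no result records to write")
    payload = [r.to_json_obj() for r in records]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=False)
        fh.write("\n")
    logger.info("wrote %d result records to %s", len(records), os.fspath(path))


def read_results(path: str | os.PathLike) -> list[ResultRecord]:
    with open(path) as fh:
        payload = json.load(fh)
    return [ResultRecord(p["name"], p["value"], p.get("metadata", {})) for p in payload]


def matrix_sha256(values: np.ndarray) -> str:
    """Provenance hash of a matrix (shape + little-endian float64 bytes)."""
    values = np.ascontiguousarray(values, dtype="<f8")
    h = hashlib.sha256()
    h.update(str(values.shape).encode())
    h.update(values.tobytes())
    return h.hexdigest()
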