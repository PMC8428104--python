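"""Validated readers and writers for the pipeline's plain-text tables.

All tables are UTF-8 with a header row; matrices and event tables are
tab-separated, sample sheets and cardiac traces comma-separated.  Writers
prepend ``#`` comment lines carrying the tool version, the run seed and a
hash of the stage parameters, so every output records how it was produced;
readers skip such lines.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .cardiac import CardiacTrace

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "params_hash",
    "read_counts",
    "read_events",
    "read_samples",
    "read_trace",
    "write_table",
]

SAMPLE_COLUMNS = ("sample", "population", "condition", "replicate")


class ValidationError(ValueError):
    """An input file violates the format contract (message names the spot)."""


def params_hash(params: Mapping[str, Any] | None) -> str:
    """Stable short hash of a parameter mapping."""
    blob = json.dumps(dict(params or {}), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    params: Mapping[str, Any] | None = None,
    index: bool = True,
    sep: str = "\t",
) -> Path:
    """Write a table with a provenance comment header."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# heterosiskit {__version__}\n")
        fh.write(f"# seed: {seed}\n")
        fh.write(f"# params_hash: {params_hash(params)}\n")
        df.to_csv(fh, sep=sep, index=index)
    return path


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples count matrix (TSV, gene ids in column 1).

    Rejects duplicate gene or sample ids and negative or non-integer
    counts, naming the offending row.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicate gene id {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValidationError(f"{path}: duplicate sample id {dup!r}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValidationError(f"{path}: non-numeric values in the count matrix")
    neg = np.argwhere(arr < 0)
    if len(neg):
        r, c = neg[0]
        raise ValidationError(
            f"{path}: negative count {arr[r, c]} at row {r + 1} "
            f"(gene {df.index[r]!r}, sample {df.columns[c]!r})"
        )
    if not np.allclose(arr, np.round(arr)):
        r, c = np.argwhere(arr != np.round(arr))[0]
        raise ValidationError(
            f"{path}: non-integer count {arr[r, c]} at row {r + 1} (gene {df.index[r]!r})"
        )
    out = df.astype(np.int64)
    logger.info(
        "%s: %d genes x %d samples; column totals %s..%s, grand total %d",
        path, out.shape[0], out.shape[1],
        int(out.sum().min()), int(out.sum().max()), int(out.to_numpy().sum()),
    )
    return out


def read_samples(path: str | Path, counts: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read a sample sheet (CSV) and optionally check it against a matrix."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise ValidationError(f"{path}: duplicate sample id {dup!r}")
    if counts is not None:
        sheet, cols = set(df["sample"]), set(counts.columns)
        if sheet != cols:
            raise ValidationError(
                f"{path}: sample sheet does not match matrix columns; "
                f"only in sheet: {sorted(sheet - cols)}, "
                f"only in matrix: {sorted(cols - sheet)}"
            )
    return df


def read_trace(path: str | Path) -> CardiacTrace:
    """Read a cardiac trace CSV with columns ``temp_c`` and ``bpm``."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    for col in ("temp_c", "bpm"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    try:
        return CardiacTrace(
            temperature_c=df["temp_c"].to_numpy(float),
            rate_bpm=df["bpm"].to_numpy(float),
        )
    except ValueError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def read_events(path: str | Path) -> pd.DataFrame:
    """Read a wide splice-event table (TSV)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("event_id", "gene_id", "event_type", "li", "ls"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    if df["event_id"].duplicated().any():
        dup = df.loc[df["event_id"].duplicated(), "event_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate event id {dup!r}")
    count_cols = [c for c in df.columns if c.startswith(("I_", "S_"))]
    if not count_cols:
        raise ValidationError(f"{path}: no junction-count columns (I_*/S_*)")
    arr = df[count_cols].to_numpy()
    if (arr < 0).any():
        r = int(np.argwhere(arr < 0)[0][0])
        raise ValidationError(
            f"{path}: negative junction count at row {r + 1} (event {df['event_id'].iloc[r]!r})"
        )
    return df
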