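"""File readers and writers: matrices, labels, results.

Wide matrices are TSV/CSV with the first row and column holding object
ids; long matrices are (source_id, target_id, value) triples where every
unlisted ordered pair is missing — which doubles as a network edge-list
reader (an absent edge is missing, not zero).  Spreadsheet (``.xlsx``)
input is accepted for both matrix formats and for feature tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import DissimilarityMatrix, InputError, Partition
from .stat import NmaResult

__all__ = [
    "read_matrix",
    "read_labels",
    "read_feature_table",
    "write_result",
    "read_result",
]

_NA = {"", "na", "nan", "null"}


def _read_table(path, header, index_col) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"file not found: {path}")
    try:
        if path.suffix.lower() in (".xlsx", ".xls"):
            return pd.read_excel(path, header=header, index_col=index_col)
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        return pd.read_csv(
            path,
            sep=sep,
            header=header,
            index_col=index_col,
            na_values=list(_NA),
            keep_default_na=True,
            skip_blank_lines=True,
        )
    except InputError:
        raise
    except Exception as exc:  # ragged rows, encoding, ...
        raise InputError(f"cannot parse {path}: {exc}") from exc


def read_matrix(path, format: str = "wide") -> DissimilarityMatrix:
    """Read a dissimilarity matrix from ``path``.

    ``format="wide"``: square table, ids in the header row and first
    column, empty cells or ``NA`` meaning missing.  ``format="long"``:
    (source_id, target_id, value) triples; unlisted ordered pairs become
    missing entries; duplicate pairs are an error.
    """
    if format == "wide":
        frame = _read_table(path, header=0, index_col=0)
        ids = [str(i) for i in frame.index]
        col_ids = [str(c) for c in frame.columns]
        if ids != col_ids:
            if sorted(ids) != sorted(col_ids):
                raise InputError(
                    "wide matrix row and column ids do not match"
                )
            frame = frame[list(frame.index)]
        try:
            vals = frame.astype(float).to_numpy()
        except (TypeError, ValueError) as exc:
            raise InputError(f"non-numeric value cell: {exc}") from exc
        return DissimilarityMatrix(vals, ids=ids)
    if format == "long":
        frame = _read_table(path, header=None, index_col=None)
        if frame.shape[1] != 3:
            raise InputError(
                f"long format needs 3 columns (source, target, value), "
                f"got {frame.shape[1]}"
            )
        frame.columns = ["source", "target", "value"]
        # tolerate a header line
        first = str(frame.iloc[0, 2]).strip().lower()
        try:
            float(frame.iloc[0, 2])
        except (TypeError, ValueError):
            if first not in _NA:
                frame = frame.iloc[1:]
        if frame.empty:
            raise InputError("empty long matrix file")
        src = frame["source"].astype(str).tolist()
        tgt = frame["target"].astype(str).tolist()
        try:
            val = frame["value"].astype(float).to_numpy()
        except (TypeError, ValueError) as exc:
            raise InputError(f"non-numeric value cell: {exc}") from exc
        ids = list(dict.fromkeys(src + tgt))
        pos = {o: i for i, o in enumerate(ids)}
        vals = np.full((len(ids), len(ids)), np.nan)
        seen = set()
        for s, t, v in zip(src, tgt, val):
            if (s, t) in seen:
                raise InputError(f"duplicate pair: ({s!r}, {t!r})")
            seen.add((s, t))
            vals[pos[s], pos[t]] = v
        return DissimilarityMatrix(vals, ids=ids)
    raise InputError("format must be 'wide' or 'long'")


def read_labels(path) -> Partition:
    """Read a two-column (object_id, group_label) file into a Partition."""
    frame = _read_table(path, header=None, index_col=None)
    if frame.shape[1] != 2:
        raise InputError(
            f"labels file needs 2 columns (object_id, group_label), "
            f"got {frame.shape[1]}"
        )
    ids = frame.iloc[:, 0].astype(str).tolist()
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise InputError(f"duplicate id in labels file: {dup!r}")
    labels = frame.iloc[:, 1].astype(str).tolist()
    return Partition(labels, ids=ids)


def read_feature_table(path) -> pd.DataFrame:
    """Objects-in-rows feature table (header row, ids in first column)."""
    frame = _read_table(path, header=0, index_col=0)
    try:
        return frame.astype(float)
    except (TypeError, ValueError) as exc:
        raise InputError(f"non-numeric value cell: {exc}") from exc


def write_result(result: NmaResult, path, format: str = "json") -> None:
    """Serialize an :class:`NmaResult` as JSON (all fields) or TSV
    (replicate, F, p)."""
    path = Path(path)
    if format == "json":
        path.write_text(result.to_json(indent=2) + "\n")
    elif format == "tsv":
        pd.DataFrame(
            {
                "replicate": np.arange(1, result.n_samplings + 1),
                "F": result.f_values,
                "p": result.p_values,
            }
        ).to_csv(path, sep="\t", index=False)
    else:
        raise InputError("format must be 'json' or 'tsv'")


def read_result(path) -> NmaResult:
    """Round-trip reader for JSON results written by :func:`write_result`."""
    return NmaResult.from_dict(json.loads(Path(path).read_text()))
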