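"""Reading and writing count matrices, designs and result tables."""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .detest import DEResult, GroupDesign
from .matrix import CountMatrix

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "read_design",
    "write_result",
    "write_truth",
]


def _sniff_sep(path: Path) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(65536)
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,").delimiter
    except csv.Error:
        return "\t"


def read_count_matrix(path, dialect: str | None = None) -> CountMatrix:
    """Read a transcripts x samples count table (TSV or CSV, auto-detected).

    The first column holds transcript ids and the header row sample ids.
    Negative, missing or non-integer entries are rejected with their
    coordinates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = {"tsv": "\t", "csv": ","}.get(dialect, None) or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns found (separator {sep!r}?)")
    if df.isna().any().any():
        r, c = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: missing value at transcript {df.index[r]!r}, "
            f"sample {df.columns[c]!r}"
        )
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        raise ValueError(f"{path}: non-numeric entries in count matrix")
    return CountMatrix(vals, list(df.index.astype(str)), list(df.columns.astype(str)))


def write_count_matrix(counts: CountMatrix, path, sep: str = "\t") -> None:
    counts.to_frame().to_csv(path, sep=sep, index_label="transcript_id")


def read_design(path) -> GroupDesign:
    """Read a two-column (sample_id, group) table; header optional."""
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: design needs two columns (sample_id, group)")
    first = df.iloc[0]
    if first.iloc[0].lower() in {"sample", "sample_id"}:
        df = df.iloc[1:]
    mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    if len(mapping) != len(df):
        raise ValueError(f"{path}: duplicate sample ids in design")
    return GroupDesign.from_mapping(mapping)


def write_result(result: DEResult, path, sep: str = "\t") -> None:
    result.to_frame().to_csv(path, sep=sep, index=False)


def write_truth(transcript_ids, is_de, direction, path, sep: str = "\t") -> None:
    pd.DataFrame(
        {
            "transcript_id": transcript_ids,
            "is_de": np.asarray(is_de, dtype=bool),
            "direction": np.asarray(direction, dtype=int),
        }
    ).to_csv(path, sep=sep, index=False)
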