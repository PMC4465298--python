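"""Count-matrix containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CountMatrix", "NormalizedMatrix"]


def _check_ids(ids, what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate {what}: {dupes[:5]}")
    return ids


@dataclass
class CountMatrix:
    """Transcripts x samples matrix of nonnegative integer read counts."""

    values: np.ndarray
    transcript_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (transcripts x samples)")
        if np.any(self.values < 0):
            r, c = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative count at transcript {self.transcript_ids[r]!r}, "
                f"sample {self.sample_ids[c]!r}"
            )
        if not np.issubdtype(self.values.dtype, np.integer):
            if np.any(self.values != np.floor(self.values)):
                r, c = np.argwhere(self.values != np.floor(self.values))[0]
                raise ValueError(
                    f"non-integer count at transcript {self.transcript_ids[r]!r}, "
                    f"sample {self.sample_ids[c]!r}"
                )
            self.values = self.values.astype(np.int64)
        self.transcript_ids = _check_ids(self.transcript_ids, "transcript ids")
        self.sample_ids = _check_ids(self.sample_ids, "sample ids")
        if len(self.transcript_ids) != self.values.shape[0]:
            raise ValueError("transcript_ids length does not match row count")
        if len(self.sample_ids) != self.values.shape[1]:
            raise ValueError("sample_ids length does not match column count")

    @property
    def n_transcripts(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def column(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.sample_ids.index(sample_id)]

    def subset_samples(self, sample_ids) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(
            self.values[:, idx].copy(), list(self.transcript_ids), [self.sample_ids[i] for i in idx]
        )

    def subset_transcripts(self, keep_mask: np.ndarray) -> "CountMatrix":
        keep_mask = np.asarray(keep_mask, dtype=bool)
        ids = [t for t, k in zip(self.transcript_ids, keep_mask) if k]
        return CountMatrix(self.values[keep_mask].copy(), ids, list(self.sample_ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.transcript_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(df.to_numpy(), list(df.index), list(df.columns))


@dataclass
class NormalizedMatrix:
    """Real-valued matrix produced by a named normalization method."""

    values: np.ndarray
    transcript_ids: list[str]
    sample_ids: list[str]
    method: str
    per_sample_factors: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.transcript_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match identifiers")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.transcript_ids, columns=self.sample_ids)
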