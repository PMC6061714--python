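"""In-memory containers shared across the analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["RetentionMatrix", "as_frame"]


@dataclass
class RetentionMatrix:
    """Runs x compounds matrix of retention times, in minutes.

    Columns are ordered by mean elution time; ``compound_mz`` optionally
    carries one m/z per compound for the peak-list stages.
    """

    values: pd.DataFrame
    compound_mz: pd.Series | None = None

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("retention matrix contains non-finite values")
        if self.compound_mz is not None:
            self.compound_mz = self.compound_mz.reindex(self.values.columns)

    @property
    def run_labels(self) -> list[str]:
        return list(self.values.index)

    @property
    def compound_labels(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_csv(self, path: str | Path) -> None:
        self.values.to_csv(path, index_label="run")

    @classmethod
    def from_csv(
        cls, path: str | Path, compound_mz: pd.Series | None = None
    ) -> "RetentionMatrix":
        df = pd.read_csv(path, index_col=0)
        try:
            values = df.astype(float)
        except ValueError as exc:
            bad = [
                c
                for c in df.columns
                if pd.to_numeric(df[c], errors="coerce").isna().any()
            ]
            raise ValueError(
                f"non-numeric retention values in column(s) {bad}"
            ) from exc
        return cls(values=values, compound_mz=compound_mz)


def as_frame(X) -> pd.DataFrame:
    """Coerce a RetentionMatrix or DataFrame to a float DataFrame."""
    if isinstance(X, RetentionMatrix):
        return X.values
    if isinstance(X, pd.DataFrame):
        return X
    raise TypeError(f"expected RetentionMatrix or DataFrame, got {type(X).__name__}")
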