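"""In-memory container and TSV interchange for probe-level expression data."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = ["ExpressionMatrix"]


@dataclass
class ExpressionMatrix:
    """N x T matrix of log2 probe intensities for one chromosome x strand.

    Rows are arrays, columns are probes ordered by genomic position.
    """

    values: np.ndarray
    array_ids: Optional[list[str]] = None
    probe_ids: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("expression matrix must be 2-D (arrays x probes)")
        if not np.all(np.isfinite(self.values)):
            raise DataError("expression matrix contains non-finite values")
        if self.array_ids is None:
            self.array_ids = [f"array_{i}" for i in range(self.n_arrays)]
        if self.probe_ids is None:
            self.probe_ids = [f"probe_{t}" for t in range(self.n_probes)]
        if len(self.array_ids) != self.n_arrays or len(self.probe_ids) != self.n_probes:
            raise DataError("array/probe id counts do not match the matrix shape")

    @property
    def n_arrays(self) -> int:
        return self.values.shape[0]

    @property
    def n_probes(self) -> int:
        return self.values.shape[1]

    def to_tsv(self, path) -> None:
        """Write a probes x arrays TSV with a leading ``probe_id`` column."""
        df = pd.DataFrame(self.values.T, columns=self.array_ids)
        df.insert(0, "probe_id", self.probe_ids)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t")
        if "probe_id" not in df.columns:
            raise DataError(f"{path}: expected a 'probe_id' column")
        probe_ids = df["probe_id"].astype(str).tolist()
        arrays = [c for c in df.columns if c != "probe_id"]
        if not arrays:
            raise DataError(f"{path}: no array columns found")
        return cls(values=df[arrays].to_numpy(dtype=float).T, array_ids=arrays, probe_ids=probe_ids)
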