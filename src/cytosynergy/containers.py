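"""Shared in-memory containers for the factorial stimulation pipeline."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

#: Canonical condition labels for the 2x2 factorial design:
#: untreated control, cytokine A alone (IL-17), cytokine B alone (TNF-alpha),
#: and the A+B combination.
CONDITIONS: tuple[str, ...] = ("control", "A", "B", "AB")


@dataclass
class CountMatrix:
    """Gene x sample integer count matrix with per-sample condition labels.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id with one column per sample; entries are
        non-negative integers.
    conditions
        Series mapping each sample id (index) to its condition label. Must
        cover exactly the columns of ``counts``.
    """

    counts: pd.DataFrame
    conditions: pd.Series

    def __post_init__(self) -> None:
        if self.counts.shape[0] == 0 or self.counts.shape[1] == 0:
            raise ValueError("count matrix must have at least one gene and one sample")
        if self.counts.isna().any().any():
            raise ValueError("count matrix contains missing entries")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("count matrix contains non-integer entries")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("count matrix contains negative entries")
        if self.counts.index.duplicated().any():
            dups = sorted(set(self.counts.index[self.counts.index.duplicated()]))
            raise ValueError(f"duplicate gene ids: {dups}")
        self.conditions = self.conditions.reindex(self.counts.columns)
        if self.conditions.isna().any():
            missing = list(self.conditions.index[self.conditions.isna()])
            raise ValueError(f"samples without a condition label: {missing}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def condition_labels(self) -> list[str]:
        """Distinct condition labels in order of first appearance."""
        return list(dict.fromkeys(self.conditions))

    def samples_for(self, condition: str) -> list[str]:
        """Sample ids belonging to ``condition`` (error if the label is absent)."""
        samples = [s for s, c in self.conditions.items() if c == condition]
        if not samples:
            raise KeyError(f"unknown condition label: {condition!r}")
        return samples

    def require_conditions(self, labels: Sequence[str]) -> None:
        present = set(self.conditions)
        missing = [c for c in labels if c not in present]
        if missing:
            raise ValueError(f"missing conditions: {missing}")
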