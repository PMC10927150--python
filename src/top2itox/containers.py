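"""Shared in-memory containers for the expression stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SAMPLE_SHEET_COLUMNS = ("individual", "treatment", "time")


@dataclass
class CountExperiment:
    """Gene-by-sample integer counts plus the design metadata.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, genes in rows, samples in
        columns.
    samples
        Sample sheet indexed by sample id with columns ``individual``,
        ``treatment`` and ``time``. The index must match the count
        columns one-to-one.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts, samples = self.counts, self.samples
        if counts.index.duplicated().any():
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups[:5]}")
        if samples.index.duplicated().any():
            raise ValueError("duplicate sample ids in sample sheet")
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in samples.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        orphans = set(counts.columns).symmetric_difference(samples.index)
        if orphans:
            raise ValueError(
                f"sample sheet and count columns disagree: {sorted(orphans)}"
            )
        vals = counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("negative counts")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("non-integer counts")
        if (vals.sum(axis=0) <= 0).any():
            empty = counts.columns[vals.sum(axis=0) <= 0].tolist()
            raise ValueError(f"samples with zero total counts: {empty}")
        # keep sample sheet in column order
        self.samples = samples.loc[counts.columns]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def lib_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids) -> "CountExperiment":
        ids = list(sample_ids)
        return CountExperiment(self.counts[ids], self.samples.loc[ids].copy())

    def group_samples(self, treatment: str, time: str) -> list[str]:
        s = self.samples
        mask = (s["treatment"] == treatment) & (s["time"] == time)
        return s.index[mask].tolist()
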