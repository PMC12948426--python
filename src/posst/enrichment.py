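"""Ro/e tissue-preference enrichment.

Ro/e is the ratio of observed to expected spot numbers of a niche (or cell
state) in a tissue region.  Expected counts come from the independence
model underlying the χ² test: E[i, j] = row_i total × column_j total / N.
Ro/e > 1 marks a niche as enriched in that region.  Only the expected
counts are borrowed from the χ² machinery — no test statistic, p-value or
continuity correction is involved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats.contingency import expected_freq

__all__ = ["RoeTable", "compute_roe", "region_counts"]


@dataclass
class RoeTable:
    """Observed, expected and Ro/e matrices over niches × regions."""

    observed: pd.DataFrame
    expected: pd.DataFrame
    roe: pd.DataFrame

    @property
    def enriched(self) -> pd.DataFrame:
        """Boolean mask of (niche, region) cells with Ro/e > 1."""
        return self.roe > 1


def region_counts(niches: pd.Series, regions: pd.Series) -> pd.DataFrame:
    """Niche × region contingency table from per-spot labels."""
    return pd.crosstab(niches.rename("niche"), regions.rename("region"))


def compute_roe(counts: pd.DataFrame) -> RoeTable:
    """Compute Ro/e = O/E from a niche × region count table.

    All-zero rows or columns are reported and dropped (they admit no
    expected count).  Cells with O = 0 get Ro/e = 0, a plain ratio, not a
    missing value.
    """
    obs = counts.astype(float)
    if (obs.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    if obs.to_numpy().sum() == 0:
        raise ValueError("all-zero contingency table")
    zero_rows = obs.index[obs.sum(axis=1) == 0].tolist()
    zero_cols = obs.columns[obs.sum(axis=0) == 0].tolist()
    if zero_rows or zero_cols:
        warnings.warn(
            f"dropping all-zero rows {zero_rows} and columns {zero_cols}",
            stacklevel=2,
        )
        obs = obs.drop(index=zero_rows, columns=zero_cols)

    exp = pd.DataFrame(
        expected_freq(obs.to_numpy()), index=obs.index, columns=obs.columns
    )
    roe = obs / exp
    return RoeTable(observed=obs, expected=exp, roe=roe)
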