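"""Observed heterozygosity and its relationship with genomic inbreeding.

Ho for an individual is the heterozygous fraction of its non-missing calls
(equivalently: non-missing minus homozygous, over non-missing).  Because
every base of autozygous genome is homozygous, Ho and F_ROH are mechanically
coupled — E[Ho] = (1 - F_ROH) * h0 for background heterozygosity h0 — and
their Pearson correlation across a cohort is strongly negative.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .datamodel import MISSING, GenotypeMatrix


def observed_het(calls_1d: np.ndarray) -> float | None:
    """Heterozygous fraction of the non-missing calls (None if all missing)."""
    calls = np.asarray(calls_1d)
    nonmiss = int((calls != MISSING).sum())
    if nonmiss == 0:
        return None
    return float((calls == 1).sum() / nonmiss)


def diversity_table(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-sample Ho with the breed label attached."""
    nonmiss = (g.calls != MISSING).sum(axis=1)
    het = (g.calls == 1).sum(axis=1)
    with np.errstate(invalid="ignore"):
        ho = np.where(nonmiss > 0, het / np.maximum(nonmiss, 1), np.nan)
    return pd.DataFrame(
        {
            "sample_id": g.samples["sample_id"],
            "population": g.samples["population"],
            "ho": ho,
        }
    )


def breed_mean_ho(div: pd.DataFrame) -> pd.DataFrame:
    return (
        div.groupby("population", as_index=False)["ho"].mean().rename(columns={"ho": "mean_ho"})
    )


def ho_froh_correlation(div: pd.DataFrame, froh_table: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between Ho and F_ROH over the
    samples present in both tables."""
    merged = div.merge(froh_table[["sample_id", "froh_all"]], on="sample_id").dropna(
        subset=["ho", "froh_all"]
    )
    if len(merged) < 3:
        raise ValueError("need >= 3 paired samples for a correlation")
    x = merged["ho"].to_numpy()
    y = merged["froh_all"].to_numpy()
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("zero variance in Ho or F_ROH")
    r, p = pearsonr(x, y)
    return float(r), float(p)
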