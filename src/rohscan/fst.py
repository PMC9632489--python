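"""Per-SNP Weir & Cockerham (1984) FST, genome-wide weighted means, empirical
z-score p-values and top-0.1% outlier calls.

The estimator decomposes allele-frequency variance into components *a*
(among populations), *b* (among individuals within populations) and *c*
(within individuals); theta-hat = a / (a + b + c) per SNP, and the
genome-wide mean is the ratio of sums sum(a) / sum(a+b+c) (the weighted,
PLINK-style mean).  Empirical p-values come from the normal approximation to
the distribution of per-SNP estimates: z = (fst - mean)/sd, p = Phi(z).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import norm

from .datamodel import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

TRACK_COLUMNS = ["marker_id", "chromosome", "position_bp", "a", "den", "fst", "p_empirical"]


def _wc_components(n_i: np.ndarray, p_i: np.ndarray, h_i: np.ndarray):
    """Variance components from per-population sample sizes (diploid counts),
    allele frequencies and observed heterozygote frequencies.

    Arrays are (r_pops, m_snps); populations absent at a SNP carry n_i = 0.
    Returns (a, b, c, valid) where valid marks SNPs with >= 2 populations.
    """
    n_i = np.asarray(n_i, dtype=np.float64)
    p_i = np.where(n_i > 0, p_i, 0.0)
    h_i = np.where(n_i > 0, h_i, 0.0)
    r = (n_i > 0).sum(axis=0)
    valid = r >= 2
    r_safe = np.maximum(r, 2)
    nsum = n_i.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = nsum / r_safe
        nc = (nsum - (n_i**2).sum(axis=0) / nsum) / (r_safe - 1)
        pbar = (n_i * p_i).sum(axis=0) / nsum
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r_safe - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / nsum
        inner = pbar * (1 - pbar) - (r_safe - 1) / r_safe * s2 - hbar / 4.0
        a = nbar / nc * (s2 - inner / (nbar - 1))
        b = nbar / (nbar - 1) * (
            pbar * (1 - pbar) - (r_safe - 1) / r_safe * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
    # single-member populations make nbar-1 or nc degenerate; mark invalid
    valid &= np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    return a, b, c, valid


def wc_fst_snp(counts_per_pop) -> tuple[float, float, float, float]:
    """Weir-Cockerham components for one SNP.

    ``counts_per_pop``: iterable of (n_hom_a, n_het, n_hom_b) per population.
    Returns (a, b, c, fst); fst is NaN when a+b+c == 0 (monomorphic).
    """
    counts = np.asarray(list(counts_per_pop), dtype=np.float64)
    if counts.ndim != 2 or counts.shape[1] != 3:
        raise ValueError("expected (n_hom_a, n_het, n_hom_b) per population")
    n_i = counts.sum(axis=1, keepdims=True)
    if (n_i > 0).sum() < 2:
        raise ValueError("need >= 2 populations with >= 1 non-missing call")
    with np.errstate(invalid="ignore", divide="ignore"):
        p_i = (2 * counts[:, 2:3] + counts[:, 1:2]) / (2 * n_i)
        h_i = counts[:, 1:2] / n_i
    a, b, c, valid = _wc_components(n_i, p_i, h_i)
    a, b, c = float(a[0]), float(b[0]), float(c[0])
    den = a + b + c
    return a, b, c, (a / den if den != 0 else float("nan"))


def fst_track(g: GenotypeMatrix, populations=None) -> pd.DataFrame:
    """Per-SNP Weir-Cockerham FST across the populations of ``g``.

    ``populations`` restricts/orders the populations compared (default: all
    labels present).  Monomorphic SNPs (a+b+c = 0) and SNPs informative in
    fewer than two populations are skipped.
    """
    labels = g.populations.to_numpy()
    pops = sorted(set(labels)) if populations is None else list(populations)
    if len(pops) < 2:
        raise ValueError("need >= 2 populations for FST")
    m = g.n_markers
    n_i = np.zeros((len(pops), m))
    p_i = np.zeros((len(pops), m))
    h_i = np.zeros((len(pops), m))
    for k, pop in enumerate(pops):
        sub = g.calls[labels == pop]
        nonmiss = sub != MISSING
        n = nonmiss.sum(axis=0)
        n_i[k] = n
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[k] = np.where(n > 0, np.where(nonmiss, sub, 0).sum(axis=0) / (2 * np.maximum(n, 1)), 0.0)
            h_i[k] = np.where(n > 0, (sub == 1).sum(axis=0) / np.maximum(n, 1), 0.0)
    a, b, c, valid = _wc_components(n_i, p_i, h_i)
    den = a + b + c
    keep = valid & (den != 0) & np.isfinite(den)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(keep, a / np.where(den == 0, 1.0, den), np.nan)
    track = pd.DataFrame(
        {
            "marker_id": g.markers["marker_id"],
            "chromosome": g.markers["chromosome"],
            "position_bp": g.markers["position_bp"],
            "a": a,
            "den": den,
            "fst": fst,
        }
    ).loc[keep]
    vals = track["fst"].to_numpy()
    sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
    if sd > 0:
        track["p_empirical"] = norm.cdf((vals - vals.mean()) / sd)
    else:
        track["p_empirical"] = 0.5
    return track.reset_index(drop=True)


def fst_mean(track: pd.DataFrame) -> float:
    """Weighted (ratio-of-sums) genome-wide mean FST."""
    if len(track) == 0:
        raise ValueError("empty FST track")
    return float(track["a"].sum() / track["den"].sum())


def fst_outliers(track: pd.DataFrame, top_fraction: float = 0.001) -> pd.DataFrame:
    """Top-fraction selection-signature calls.

    Ranks SNPs by FST (ties broken by genome order), takes the
    ceil(top_fraction * n) highest and keeps those with empirical
    p > 1 - top_fraction.  A flat track (sd = 0) yields no outliers.
    """
    n = len(track)
    if n == 0:
        return track.iloc[0:0].copy()
    vals = track["fst"].to_numpy()
    if np.all(vals == vals[0]):
        logger.warning("all FST values equal; no outliers callable")
        return track.iloc[0:0].copy()
    k = int(np.ceil(top_fraction * n))
    order = np.argsort(-vals, kind="stable")[:k]
    top = track.iloc[np.sort(order)]
    return top[top["p_empirical"] > 1.0 - top_fraction].copy()


def pairwise_comparisons(g: GenotypeMatrix) -> list[tuple[str, ...]]:
    """The multi-way comparison followed by every population pair."""
    pops = sorted(set(g.populations))
    comps: list[tuple[str, ...]] = []
    if len(pops) > 2:
        comps.append(tuple(pops))
    comps.extend(
        (pops[i], pops[j]) for i in range(len(pops)) for j in range(i + 1, len(pops))
    )
    return comps
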