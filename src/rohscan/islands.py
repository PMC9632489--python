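"""ROH incidence tracks and ROH-island calling.

For one breed, the *incidence* of a SNP is the percentage of individuals
whose ROH cover it.  Standard-normal z-scores over the breed's incidence
distribution give each SNP a p-value Phi(z); a SNP belongs to an island when
p exceeds 0.999 (the top-0.1% rule) *and* its incidence reaches the 30%
population floor.  When no SNP clears the primary rule (a very inbred breed
shifts the whole distribution upward), an optional fallback threshold of
p >= 0.998 is applied and flagged in the output.  Adjacent member SNPs are
merged into island intervals with a 1 Mb gap tolerance.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import norm

from .datamodel import GenotypeMatrix

logger = logging.getLogger(__name__)

TRACK_COLUMNS = [
    "marker_id",
    "chromosome",
    "position_bp",
    "n_covered",
    "incidence_pct",
    "z",
    "p",
]

ISLAND_COLUMNS = [
    "chromosome",
    "start_bp",
    "end_bp",
    "n_snps",
    "peak_snp_id",
    "peak_incidence_pct",
    "threshold_rule",
]


def incidence(
    segments: pd.DataFrame,
    g: GenotypeMatrix,
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-SNP ROH incidence for one breed.

    A SNP counts as covered for an individual iff its position lies within
    [start_bp, end_bp] of any of that individual's segments.  ``g`` supplies
    the marker map the segments were called on; ``sample_ids`` the breed
    membership (defaults to all samples of ``g``).
    """
    ids = list(sample_ids) if sample_ids is not None else g.sample_ids
    if not ids:
        raise ValueError("empty breed: no samples to compute incidence over")
    markers = g.markers
    counts = np.zeros(len(markers), dtype=np.int64)
    pos_by_chrom = {
        chrom: (g.chromosome_slice(chrom), markers["position_bp"].to_numpy()[g.chromosome_slice(chrom)])
        for chrom in g.chromosomes()
    }
    member = segments[segments["sample_id"].isin(ids)]
    for (sid, chrom), seg in member.groupby(["sample_id", "chromosome"], sort=False):
        idx, pos = pos_by_chrom[str(chrom)]
        covered = np.zeros(len(idx), dtype=bool)
        for start, end in zip(seg["start_bp"], seg["end_bp"]):
            a = np.searchsorted(pos, start, side="left")
            b = np.searchsorted(pos, end, side="right")
            covered[a:b] = True
        counts[idx] += covered
    pct = 100.0 * counts / len(ids)
    sd = pct.std(ddof=1) if len(pct) > 1 else 0.0
    if sd > 0:
        z = (pct - pct.mean()) / sd
        p = norm.cdf(z)
    else:
        z = np.zeros_like(pct)
        p = np.full_like(pct, 0.5)
    return pd.DataFrame(
        {
            "marker_id": markers["marker_id"],
            "chromosome": markers["chromosome"],
            "position_bp": markers["position_bp"],
            "n_covered": counts,
            "incidence_pct": pct,
            "z": z,
            "p": p,
        }
    )


def zscore_track(track: pd.DataFrame) -> pd.DataFrame:
    """Recompute the z and p columns from ``incidence_pct`` (e.g. after
    subsetting or rescaling a track)."""
    out = track.copy()
    pct = out["incidence_pct"].to_numpy(dtype=float)
    sd = pct.std(ddof=1) if len(pct) > 1 else 0.0
    if sd > 0:
        out["z"] = (pct - pct.mean()) / sd
        out["p"] = norm.cdf(out["z"].to_numpy())
    else:
        out["z"] = 0.0
        out["p"] = 0.5
    return out


def _merge_members(track: pd.DataFrame, member: np.ndarray, merge_gap_bp: int, rule: str):
    islands = []
    sub = track.loc[member].sort_values(["chromosome", "position_bp"])
    for chrom, grp in sub.groupby("chromosome", sort=False):
        pos = grp["position_bp"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > merge_gap_bp)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [len(pos) - 1]))
        for a, b in zip(starts, ends):
            block = grp.iloc[a : b + 1]
            peak_inc = block["incidence_pct"].max()
            peaks = block[block["incidence_pct"] == peak_inc]
            peak = peaks.iloc[(len(peaks) - 1) // 2]  # plateau centre
            islands.append(
                {
                    "chromosome": chrom,
                    "start_bp": int(pos[a]),
                    "end_bp": int(pos[b]),
                    "n_snps": int(b - a + 1),
                    "peak_snp_id": peak["marker_id"],
                    "peak_incidence_pct": float(peak_inc),
                    "threshold_rule": rule,
                }
            )
    return islands


def call_islands(
    track: pd.DataFrame,
    p_min: float = 0.999,
    incidence_floor_pct: float = 30.0,
    merge_gap_bp: int = 1_000_000,
    fallback_p_min: float | None = 0.998,
):
    """Call ROH islands from an incidence track.

    Returns ``(islands, members)``: island intervals (ISLAND_COLUMNS) and the
    per-SNP member rows that support them.  Membership requires p > ``p_min``
    and incidence >= ``incidence_floor_pct``; if nothing passes and
    ``fallback_p_min`` is set, the relaxed rule p >= ``fallback_p_min`` is
    applied instead and islands are flagged ``fallback``.  A flat track
    (sd = 0) yields no islands.
    """
    if track["incidence_pct"].nunique() < 2:
        logger.warning("incidence track has zero variance; no islands callable")
        return (
            pd.DataFrame(columns=ISLAND_COLUMNS),
            track.iloc[0:0].copy(),
        )
    member = (track["p"].to_numpy() > p_min) & (
        track["incidence_pct"].to_numpy() >= incidence_floor_pct
    )
    rule = "primary"
    if not member.any() and fallback_p_min is not None:
        member = (track["p"].to_numpy() >= fallback_p_min) & (
            track["incidence_pct"].to_numpy() >= incidence_floor_pct
        )
        rule = "fallback"
        if member.any():
            logger.info("island fallback threshold p>=%.3f engaged", fallback_p_min)
    islands = pd.DataFrame(
        _merge_members(track, member, merge_gap_bp, rule), columns=ISLAND_COLUMNS
    )
    members = track.loc[member].copy()
    members["threshold_rule"] = rule
    return islands, members
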