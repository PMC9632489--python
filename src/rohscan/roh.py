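"""Sliding-window detection of runs of homozygosity (ROH) and genomic
inbreeding (F_ROH).

The caller follows the standard SNP-chip recipe: the window length L is set
so that, genome- and cohort-wide, a window of L consecutive homozygous SNPs
is unlikely (< alpha) to arise by chance,

    L = ceil( ln(alpha / (n_snps * n_samples)) / ln(1 - mean_het) ),

with a floor of 20 SNPs.  A window is *homozygous* iff it contains no
heterozygous call and at most one missing call; a SNP enters a run when at
least 5% of the windows covering it are homozygous.  Candidate runs are then
split at inter-SNP gaps above 1 Mb and kept only if they contain at least L
SNPs at an average density of one SNP per 150 kb or better.

F_ROH is the summed ROH length divided by the SNP-covered autosomal genome
length (sum over chromosomes of last minus first SNP position), overall and
per length class (1-2, 2-4, 4-8, 8-16, >16 Mb).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import LENGTH_CLASSES, MISSING, GenotypeMatrix, length_class

logger = logging.getLogger(__name__)

SEGMENT_COLUMNS = [
    "sample_id",
    "chromosome",
    "start_bp",
    "end_bp",
    "n_snps",
    "length_bp",
    "length_class",
]


@dataclass(frozen=True)
class RohParams:
    alpha: float = 0.05
    window_overlap_min: float = 0.05
    max_missing_per_window: int = 1
    max_het_per_window: int = 0
    min_density_bp_per_snp: int = 150_000
    max_gap_bp: int = 1_000_000
    min_snps_floor: int = 20
    window_snps: int | None = None  # computed from the data when None
    min_snps_per_run: int | None = None  # defaults to the window length

    def __post_init__(self):
        if self.max_het_per_window != 0:
            raise ValueError("heterozygous calls are not allowed inside a window")
        if not 0.0 < self.window_overlap_min <= 1.0:
            raise ValueError("window_overlap_min must lie in (0, 1]")


def compute_L(
    n_snps: int,
    n_samples: int,
    mean_het: float,
    alpha: float = 0.05,
    floor: int = 20,
) -> int:
    """Minimum window length so chance homozygous stretches are unlikely
    across ``n_snps * n_samples`` tests."""
    if n_snps < 1 or n_samples < 1:
        raise ValueError("n_snps and n_samples must be >= 1")
    if not 0.0 < mean_het < 1.0:
        raise ValueError("mean_het must lie strictly between 0 and 1")
    L = math.ceil(math.log(alpha / (n_snps * n_samples)) / math.log(1.0 - mean_het))
    return max(L, floor)


def mean_observed_het(g: GenotypeMatrix) -> float:
    """Cohort mean of the per-individual heterozygous-call fraction."""
    nonmiss = (g.calls != MISSING).sum(axis=1)
    het = (g.calls == 1).sum(axis=1)
    with np.errstate(invalid="ignore"):
        rates = np.where(nonmiss > 0, het / nonmiss, np.nan)
    return float(np.nanmean(rates))


def resolve_window(g: GenotypeMatrix, params: RohParams) -> int:
    """Window length: explicit override or the L formula on this cohort."""
    if params.window_snps is not None:
        return params.window_snps
    return compute_L(
        g.n_markers,
        g.n_samples,
        mean_observed_het(g),
        alpha=params.alpha,
        floor=params.min_snps_floor,
    )


def window_flags(calls: np.ndarray, L: int, params: RohParams) -> np.ndarray:
    """Per-SNP in-run flags for a (n_samples, m) call block of one chromosome.

    Every length-L window is homozygous iff its heterozygote count is zero
    and its missing count is at most ``max_missing_per_window``; a SNP is
    flagged iff the homozygous fraction of the windows covering it reaches
    ``window_overlap_min``.
    """
    calls = np.atleast_2d(calls)
    n, m = calls.shape
    if m < L:
        return np.zeros((n, m), dtype=bool)
    het = (calls == 1).astype(np.int32)
    mis = (calls == MISSING).astype(np.int32)
    cs_het = np.zeros((n, m + 1), dtype=np.int32)
    cs_mis = np.zeros((n, m + 1), dtype=np.int32)
    np.cumsum(het, axis=1, out=cs_het[:, 1:])
    np.cumsum(mis, axis=1, out=cs_mis[:, 1:])
    het_win = cs_het[:, L:] - cs_het[:, :-L]
    mis_win = cs_mis[:, L:] - cs_mis[:, :-L]
    ok = (het_win <= params.max_het_per_window) & (
        mis_win <= params.max_missing_per_window
    )
    n_win = m - L + 1
    cs_ok = np.zeros((n, n_win + 1), dtype=np.int32)
    np.cumsum(ok, axis=1, out=cs_ok[:, 1:])
    j = np.arange(m)
    lo = np.maximum(0, j - L + 1)
    hi = np.minimum(j, n_win - 1)
    covering = hi - lo + 1
    ok_count = cs_ok[:, hi + 1] - cs_ok[:, lo]
    return ok_count / covering >= params.window_overlap_min


def window_scan(calls_1d: np.ndarray, L: int, params: RohParams) -> np.ndarray:
    """Single-sample convenience wrapper around :func:`window_flags`."""
    return window_flags(np.asarray(calls_1d)[None, :], L, params)[0]


def assemble_segments(
    flags: np.ndarray,
    positions: np.ndarray,
    params: RohParams,
    min_snps: int,
) -> list[tuple[int, int]]:
    """Turn per-SNP flags into runs: maximal flagged stretches, split at
    gaps above ``max_gap_bp``, kept if they hold >= ``min_snps`` SNPs at
    average density <= ``min_density_bp_per_snp`` bp/SNP.

    Returns (start_index, end_index) pairs, inclusive.
    """
    flags = np.asarray(flags, dtype=bool)
    positions = np.asarray(positions)
    out: list[tuple[int, int]] = []
    m = len(flags)
    i = 0
    while i < m:
        if not flags[i]:
            i += 1
            continue
        j = i
        while j + 1 < m and flags[j + 1]:
            j += 1
        # split the run at oversized gaps
        piece_start = i
        for k in range(i, j + 1):
            boundary = k == j or positions[k + 1] - positions[k] > params.max_gap_bp
            if boundary:
                n_snps = k - piece_start + 1
                length = int(positions[k] - positions[piece_start])
                if n_snps >= min_snps and (
                    n_snps > 0 and length / n_snps <= params.min_density_bp_per_snp
                ):
                    out.append((piece_start, k))
                piece_start = k + 1
        i = j + 1
    return out


def call_roh(
    g: GenotypeMatrix,
    params: RohParams | None = None,
    window_snps: int | None = None,
) -> pd.DataFrame:
    """Call ROH for every individual in a cohort.

    The window length is computed once from the whole cohort (``resolve_window``)
    unless overridden.  Returns one row per segment with the columns of
    ``SEGMENT_COLUMNS``.
    """
    params = params or RohParams()
    L = window_snps if window_snps is not None else resolve_window(g, params)
    min_snps = params.min_snps_per_run if params.min_snps_per_run is not None else L
    rows = []
    sample_ids = g.sample_ids
    pos_all = g.markers["position_bp"].to_numpy()
    for chrom in g.chromosomes():
        idx = g.chromosome_slice(chrom)
        pos = pos_all[idx]
        flags = window_flags(g.calls[:, idx], L, params)
        for s in range(g.n_samples):
            for a, b in assemble_segments(flags[s], pos, params, min_snps):
                length = int(pos[b] - pos[a])
                rows.append(
                    (
                        sample_ids[s],
                        chrom,
                        int(pos[a]),
                        int(pos[b]),
                        b - a + 1,
                        length,
                        length_class(length),
                    )
                )
    df = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    logger.info("called %d ROH segments (window L=%d)", len(df), L)
    return df


def froh(
    segments: pd.DataFrame,
    coverage_bp: int,
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Genomic inbreeding per individual: total and per length class.

    ``coverage_bp`` is the SNP-covered autosomal genome length of the map
    the segments were called on (``GenotypeMatrix.coverage_bp``).  Samples
    named in ``sample_ids`` but owning no segment get F_ROH = 0.
    """
    if coverage_bp <= 0:
        raise ValueError("coverage_bp must be positive")
    class_names = [name for name, _, _ in LENGTH_CLASSES]
    ids = list(sample_ids) if sample_ids is not None else sorted(
        segments["sample_id"].unique()
    )
    rows = []
    grouped = dict(tuple(segments.groupby("sample_id"))) if len(segments) else {}
    for sid in ids:
        seg = grouped.get(sid)
        row = {"sample_id": sid}
        if seg is None or seg.empty:
            row.update({"froh_all": 0.0, "sum_roh_kb": 0.0, "n_roh": 0})
            row.update({f"froh_{c}": 0.0 for c in class_names})
        else:
            total = float(seg["length_bp"].sum())
            row["froh_all"] = total / coverage_bp
            row["sum_roh_kb"] = total / 1e3
            row["n_roh"] = int(len(seg))
            by_class = seg.groupby("length_class")["length_bp"].sum()
            for c in class_names:
                row[f"froh_{c}"] = float(by_class.get(c, 0.0)) / coverage_bp
        rows.append(row)
    cols = ["sample_id", "froh_all"] + [f"froh_{c}" for c in class_names] + [
        "sum_roh_kb",
        "n_roh",
    ]
    return pd.DataFrame(rows, columns=cols)
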