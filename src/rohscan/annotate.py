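"""Candidate-gene lookup: map significant SNPs to genes within a flanking
distance (default +/- 100 kb), and build the report tables that pair
selection-signature SNPs with their candidate genes."""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_FLANK_BP = 100_000

FST_TABLE_COLUMNS = [
    "comparison",
    "chromosome",
    "marker_id",
    "position_bp",
    "fst",
    "shared",
    "genes",
]
ISLAND_TABLE_COLUMNS = [
    "population",
    "chromosome",
    "marker_id",
    "position_bp",
    "incidence_pct",
    "genes",
]


def flank_genes(
    chromosome: str,
    position_bp: int,
    genes: pd.DataFrame,
    flank_bp: int = DEFAULT_FLANK_BP,
) -> list[str]:
    """Genes whose [start, end] interval intersects
    [position - flank, position + flank] (closed on both ends), ordered by
    distance (0 for genes containing the SNP), ties by genome order."""
    if genes.empty:
        return []
    sub = genes[genes["chromosome"].astype(str) == str(chromosome)]
    if sub.empty:
        return []
    start = sub["start_bp"].to_numpy()
    end = sub["end_bp"].to_numpy()
    dist = np.where(
        position_bp < start,
        start - position_bp,
        np.where(position_bp > end, position_bp - end, 0),
    )
    hit = dist <= flank_bp
    order = np.lexsort((start[hit], dist[hit]))
    return sub.loc[hit].iloc[order]["name"].tolist()


def _shared_labels(tables: dict[str, pd.DataFrame]) -> dict[str, str]:
    """Assign a letter to every SNP significant in >= 2 pairwise comparisons,
    in order of first appearance."""
    seen: dict[str, int] = {}
    for comp in sorted(tables):
        for snp in tables[comp]["marker_id"]:
            seen[snp] = seen.get(snp, 0) + 1
    letters = {}
    next_ord = ord("a")
    for comp in sorted(tables):
        for snp in tables[comp]["marker_id"]:
            if seen[snp] > 1 and snp not in letters:
                letters[snp] = chr(next_ord)
                next_ord += 1
    return letters


def annotate_fst_outliers(
    outliers_by_comparison: dict[str, pd.DataFrame],
    genes: pd.DataFrame,
    flank_bp: int = DEFAULT_FLANK_BP,
) -> pd.DataFrame:
    """Gene-annotated significant-SNP table across FST comparisons.

    SNPs shared between comparisons carry a common superscript letter; SNPs
    with no gene within the flank are dropped from this table (they remain
    in the raw outlier output).
    """
    pairwise = {c: t for c, t in outliers_by_comparison.items() if len(c.split("~")) == 2}
    shared = _shared_labels(pairwise if pairwise else outliers_by_comparison)
    rows = []
    for comp in sorted(outliers_by_comparison):
        tab = outliers_by_comparison[comp]
        tab = tab.sort_values("fst", ascending=False)
        for _, row in tab.iterrows():
            names = flank_genes(row["chromosome"], int(row["position_bp"]), genes, flank_bp)
            if not names:
                continue
            rows.append(
                {
                    "comparison": comp,
                    "chromosome": row["chromosome"],
                    "marker_id": row["marker_id"],
                    "position_bp": int(row["position_bp"]),
                    "fst": float(row["fst"]),
                    "shared": shared.get(row["marker_id"], ""),
                    "genes": ",".join(names),
                }
            )
    return pd.DataFrame(rows, columns=FST_TABLE_COLUMNS)


def annotate_island_members(
    members_by_population: dict[str, pd.DataFrame],
    genes: pd.DataFrame,
    flank_bp: int = DEFAULT_FLANK_BP,
) -> pd.DataFrame:
    """Gene-annotated ROH-island SNP table (one row per member SNP with at
    least one candidate gene, sorted by incidence within breed)."""
    rows = []
    for pop in sorted(members_by_population):
        tab = members_by_population[pop].sort_values("incidence_pct", ascending=False)
        for _, row in tab.iterrows():
            names = flank_genes(row["chromosome"], int(row["position_bp"]), genes, flank_bp)
            if not names:
                continue
            rows.append(
                {
                    "population": pop,
                    "chromosome": row["chromosome"],
                    "marker_id": row["marker_id"],
                    "position_bp": int(row["position_bp"]),
                    "incidence_pct": float(row["incidence_pct"]),
                    "genes": ",".join(names),
                }
            )
    return pd.DataFrame(rows, columns=ISLAND_TABLE_COLUMNS)
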