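"""Core in-memory containers for SNP-array genotype data.

Genotype calls are held as an ``int8`` matrix of allele-B dosages
(0 = homozygous allele A, 1 = heterozygous, 2 = homozygous allele B) with
:data:`MISSING` (-1) marking no-calls.  Sample and marker registries are
pandas DataFrames so that downstream stages can join, group and export them
without conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call.
MISSING: int = -1

#: ROH length classes in Mb, half-open [lower, upper).  Runs shorter than
#: 1 Mb can occur on dense maps and get their own bucket so that per-class
#: inbreeding always sums to the total.
LENGTH_CLASSES: tuple[tuple[str, float, float], ...] = (
    ("<1", 0.0, 1e6),
    ("1-2", 1e6, 2e6),
    ("2-4", 2e6, 4e6),
    ("4-8", 4e6, 8e6),
    ("8-16", 8e6, 16e6),
    (">16", 16e6, float("inf")),
)

MARKER_COLUMNS = ["marker_id", "chromosome", "position_bp", "allele_a", "allele_b"]
SAMPLE_COLUMNS = ["sample_id", "population"]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


class IntegrityError(ValueError):
    """Raised when registries and payload dimensions disagree."""


def chromosome_sort_key(label: str):
    """Sort chromosome labels numerically where possible ("2" < "10")."""
    s = str(label)
    return (0, int(s), "") if s.isdigit() else (1, 0, s)


def length_class(length_bp: float) -> str:
    for name, lo, hi in LENGTH_CLASSES:
        if lo <= length_bp < hi:
            return name
    return LENGTH_CLASSES[-1][0]


@dataclass
class GeneRecord:
    """A gene interval, 1-based inclusive on both ends."""

    name: str
    chromosome: str
    start_bp: int
    end_bp: int

    def __post_init__(self):
        if self.start_bp > self.end_bp:
            raise ValueError(
                f"gene {self.name}: start {self.start_bp} > end {self.end_bp}"
            )


class GenotypeMatrix:
    """Samples x markers genotype calls plus their registries.

    Parameters
    ----------
    calls:
        ``(n_samples, n_markers)`` int array of allele-B dosages with
        ``MISSING`` for no-calls.
    samples:
        DataFrame with at least ``sample_id`` and ``population`` columns.
    markers:
        DataFrame with ``marker_id, chromosome, position_bp, allele_a,
        allele_b`` columns.  Markers are re-sorted by (chromosome, position)
        on construction and the column permutation is applied to ``calls``.
    """

    def __init__(self, calls: np.ndarray, samples: pd.DataFrame, markers: pd.DataFrame):
        calls = np.asarray(calls, dtype=np.int8)
        samples = samples.reset_index(drop=True).copy()
        markers = markers.reset_index(drop=True).copy()
        if calls.ndim != 2 or calls.shape != (len(samples), len(markers)):
            raise IntegrityError(
                f"calls shape {calls.shape} inconsistent with registries "
                f"({len(samples)} samples, {len(markers)} markers)"
            )
        bad = ~np.isin(calls, (MISSING, 0, 1, 2))
        if bad.any():
            raise IntegrityError("genotype calls outside {missing, 0, 1, 2}")
        if samples["sample_id"].duplicated().any():
            raise IntegrityError("duplicate sample ids")
        if markers["marker_id"].duplicated().any():
            raise IntegrityError("duplicate marker ids")
        if (markers["position_bp"] < 1).any():
            raise IntegrityError("marker positions must be >= 1")

        markers["chromosome"] = markers["chromosome"].astype(str)
        markers["position_bp"] = markers["position_bp"].astype(np.int64)
        order = sorted(
            range(len(markers)),
            key=lambda i: (
                chromosome_sort_key(markers["chromosome"].iat[i]),
                int(markers["position_bp"].iat[i]),
            ),
        )
        if order != list(range(len(markers))):
            markers = markers.iloc[order].reset_index(drop=True)
            calls = np.ascontiguousarray(calls[:, order])
        if markers.duplicated(["chromosome", "position_bp"]).any():
            raise IntegrityError("duplicate (chromosome, position) pairs")

        self.calls = calls
        self.samples = samples
        self.markers = markers

    # -- basic geometry ------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def sample_ids(self) -> list[str]:
        return self.samples["sample_id"].tolist()

    @property
    def populations(self) -> pd.Series:
        return self.samples["population"]

    def chromosomes(self) -> list[str]:
        seen = self.markers["chromosome"].unique().tolist()
        return sorted(seen, key=chromosome_sort_key)

    def chromosome_slice(self, chrom: str) -> np.ndarray:
        """Marker indices (sorted) of one chromosome."""
        return np.flatnonzero(self.markers["chromosome"].to_numpy() == str(chrom))

    # -- subsetting ----------------------------------------------------

    def subset(self, sample_idx=None, marker_idx=None) -> "GenotypeMatrix":
        calls = self.calls
        samples = self.samples
        markers = self.markers
        if sample_idx is not None:
            sample_idx = np.asarray(sample_idx)
            calls = calls[sample_idx]
            samples = samples.iloc[sample_idx]
        if marker_idx is not None:
            marker_idx = np.asarray(marker_idx)
            calls = calls[:, marker_idx]
            markers = markers.iloc[marker_idx]
        return GenotypeMatrix(calls.copy(), samples, markers)

    def by_population(self):
        """Yield (population label, sub-matrix) in sorted label order."""
        for pop in sorted(self.populations.unique()):
            idx = np.flatnonzero((self.populations == pop).to_numpy())
            yield pop, self.subset(sample_idx=idx)

    # -- summary statistics --------------------------------------------

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def sample_call_rate(self) -> np.ndarray:
        if self.n_markers == 0:
            return np.ones(self.n_samples)
        return 1.0 - self.missing_mask().mean(axis=1)

    def marker_call_rate(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.ones(self.n_markers)
        return 1.0 - self.missing_mask().mean(axis=0)

    def allele_b_frequency(self) -> np.ndarray:
        """Frequency of allele B per marker over non-missing calls (NaN if none)."""
        nonmiss = self.calls != MISSING
        n = nonmiss.sum(axis=0)
        dose = np.where(nonmiss, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, dose / (2.0 * n), np.nan)

    def maf(self) -> np.ndarray:
        p = self.allele_b_frequency()
        return np.minimum(p, 1.0 - p)

    def genotype_counts(self) -> pd.DataFrame:
        """Per-marker counts of hom-A, het, hom-B and missing calls."""
        return pd.DataFrame(
            {
                "n_hom_a": (self.calls == 0).sum(axis=0),
                "n_het": (self.calls == 1).sum(axis=0),
                "n_hom_b": (self.calls == 2).sum(axis=0),
                "n_missing": (self.calls == MISSING).sum(axis=0),
            }
        )

    def coverage_bp(self) -> int:
        """Length of the genome covered by the map: sum over chromosomes of
        (last SNP position - first SNP position)."""
        total = 0
        pos = self.markers["position_bp"].to_numpy()
        for chrom in self.chromosomes():
            idx = self.chromosome_slice(chrom)
            if len(idx) >= 2:
                total += int(pos[idx[-1]] - pos[idx[0]])
        return total

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"GenotypeMatrix({self.n_samples} samples x {self.n_markers} markers, "
            f"{len(self.populations.unique())} populations)"
        )


@dataclass
class QcStage:
    """Outcome of one QC filter: what went in, what was removed."""

    name: str
    n_samples_before: int
    n_markers_before: int
    removed_samples: list = field(default_factory=list)
    removed_markers: list = field(default_factory=list)

    @property
    def n_samples_after(self) -> int:
        return self.n_samples_before - len(self.removed_samples)

    @property
    def n_markers_after(self) -> int:
        return self.n_markers_before - len(self.removed_markers)


@dataclass
class QcReport:
    stages: list = field(default_factory=list)

    def add(self, stage: QcStage) -> None:
        self.stages.append(stage)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "stage": s.name,
                "samples_before": s.n_samples_before,
                "samples_removed": len(s.removed_samples),
                "samples_after": s.n_samples_after,
                "markers_before": s.n_markers_before,
                "markers_removed": len(s.removed_markers),
                "markers_after": s.n_markers_after,
                "removed_sample_ids": ",".join(map(str, s.removed_samples)),
                "removed_marker_ids": ",".join(map(str, s.removed_markers)),
            }
            for s in self.stages
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "stage",
                "samples_before",
                "samples_removed",
                "samples_after",
                "markers_before",
                "markers_removed",
                "markers_after",
                "removed_sample_ids",
                "removed_marker_ids",
            ],
        )
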