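"""Synthetic multi-breed SNP-array cohorts with known truth.

The generator emulates a small-livestock conservation cohort genotyped on a
medium-density chip: 18 autosomes, ~30k jitter-spaced SNPs, two or three
breeds of 20-30 individuals.  Three planted signals provide ground truth for
every downstream stage:

* **Breed divergence** — per-breed allele frequencies drawn from the
  Balding-Nichols model, Beta(p(1-F)/F, (1-p)(1-F)/F) around an ancestral
  frequency p, so the expected pairwise Weir-Cockerham FST between breeds i
  and j is (F_i + F_j)/2.
* **Individual autozygosity** — per-individual tracts in which both
  chromosomes carry one doubled haplotype sampled from the breed's
  frequencies (zero heterozygotes inside), planted to a target F_ROH.
* **Shared autozygosity (ROH islands)** — a core interval forced autozygous
  in a chosen fraction of a breed.  Each carrier is homozygous for one
  breed-shared haplotype across the core and for a private haplotype over
  Exponential-length flanking extensions, mirroring IBD sharing: a short
  common core inside longer individual ROH.  The extensions are what make a
  2 Mb core callable at all — at chip density a bare 2 Mb run holds fewer
  SNPs than the minimum run length L.
* **Divergent selection loci** — near-fixed frequency contrasts (favoured
  allele ~U[0.80, 0.98] in one breed group vs ~U[0.02, 0.20] in the other),
  the frequency configuration that detected selection signatures actually
  show; an unconstrained Balding-Nichols draw at high F models drift, which
  as often as not leaves both breeds on the same boundary.

Everything is deterministic under ``SimConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeMatrix

__all__ = [
    "SimConfig",
    "Truth",
    "plan_tracts",
    "simulate_frequencies",
    "simulate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class PlantedIsland:
    population: str
    chromosome: str
    start_bp: int
    end_bp: int
    carrier_fraction: float

    def __post_init__(self):
        if not 0.0 <= self.carrier_fraction <= 1.0:
            raise ValueError("carrier_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of a synthetic cohort.

    Defaults mirror a three-breed Mangalitsa-like cohort: pairwise
    divergence ~0.03 between the two close breeds and ~0.09-0.10 against the
    third, per-breed F_ROH targets of 0.24/0.16/0.21, and a chip of ~30.6k
    SNPs over 18 autosomes of 100 Mb (~60 kb mean spacing).
    """

    seed: int = 0
    pop_labels: tuple[str, ...] = ("BM", "RM", "SM")
    n_per_pop: tuple[int, ...] = (23, 24, 30)
    n_chrom: int = 18
    chrom_length_bp: int = 100_000_000
    snps_per_chrom: int = 1_700
    maf_range: tuple[float, float] = (0.05, 0.5)
    divergence_F: tuple[float, ...] = (0.03, 0.03, 0.16)
    froh_target: tuple[float, ...] = (0.24, 0.16, 0.21)
    froh_spread: float = 0.08  # per-individual spread around the breed target
    tract_length_range_mb: tuple[float, float] = (4.0, 16.0)
    islands: tuple[PlantedIsland, ...] = ()
    island_extension_mean_bp: float = 3_000_000.0
    n_divergent_loci: int = 0
    divergent_hi_range: tuple[float, float] = (0.80, 0.98)
    divergent_lo_range: tuple[float, float] = (0.02, 0.20)
    missing_rate: float = 0.01
    genotype_error_rate: float = 0.0
    position_jitter: float = 0.3

    def __post_init__(self):
        if not (len(self.pop_labels) == len(self.n_per_pop) == len(self.divergence_F) == len(self.froh_target)):
            raise ValueError("per-population tuples must have equal length")
        for F in self.divergence_F:
            if not 0.0 <= F < 1.0:
                raise ValueError("divergence_F must lie in [0, 1)")
        for isl in self.islands:
            if isl.end_bp > self.chrom_length_bp or isl.start_bp < 1:
                raise ValueError("island outside chromosome bounds")

    @property
    def n_pops(self) -> int:
        return len(self.pop_labels)

    @property
    def n_snps(self) -> int:
        return self.n_chrom * self.snps_per_chrom

    @property
    def genome_bp(self) -> int:
        return self.n_chrom * self.chrom_length_bp


@dataclass
class Truth:
    """Planted parameters, recoverable deterministically from the config+seed."""

    froh: pd.DataFrame  # sample_id, population, froh_true
    pairwise_F: pd.DataFrame  # pop_a, pop_b, F_true
    islands: pd.DataFrame  # population, chromosome, start_bp, end_bp, carrier_fraction, n_carriers
    divergent_loci: pd.DataFrame  # marker_id, chromosome, position_bp


def _merge_intervals(intervals):
    """Merge overlapping (start, end) pairs; inputs need not be sorted."""
    if not intervals:
        return []
    merged = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def plan_tracts(
    rng: np.random.Generator,
    froh_target: float,
    n_chrom: int,
    chrom_length_bp: int,
    length_range_mb: tuple[float, float] = (4.0, 16.0),
) -> list[tuple[int, int, int]]:
    """Plan non-overlapping autozygous tracts totalling ``froh_target`` of the
    genome: lengths uniform in ``length_range_mb``, chromosomes and start
    positions uniform, the final tract truncated to land on the target."""
    if froh_target <= 0:
        return []
    target_bp = froh_target * n_chrom * chrom_length_bp
    placed: dict[int, list[tuple[int, int]]] = {c: [] for c in range(n_chrom)}
    total = 0.0
    out = []
    attempts = 0
    while total < target_bp and attempts < 10_000:
        attempts += 1
        length = int(rng.uniform(*length_range_mb) * 1e6)
        length = int(min(length, target_bp - total + 1e5))
        length = max(length, int(1e6))
        chrom = int(rng.integers(n_chrom))
        start = int(rng.integers(1, chrom_length_bp - length))
        end = start + length
        if any(s < end and start < e for s, e in placed[chrom]):
            continue
        placed[chrom].append((start, end))
        out.append((chrom, start, end))
        total += length
    return out


def simulate_frequencies(
    rng: np.random.Generator, p_anc: np.ndarray, divergence_F
) -> np.ndarray:
    """Balding-Nichols per-population frequencies, (n_pops, m).  F = 0 gives
    the ancestral frequencies exactly; F = 1 is rejected."""
    p_anc = np.asarray(p_anc, dtype=np.float64)
    freqs = np.empty((len(divergence_F), p_anc.size))
    for k, F in enumerate(divergence_F):
        if F >= 1.0:
            raise ValueError("divergence_F must be < 1")
        if F == 0.0:
            freqs[k] = p_anc
        else:
            ratio = (1.0 - F) / F
            freqs[k] = rng.beta(p_anc * ratio, (1.0 - p_anc) * ratio)
    return freqs


def _marker_map(rng: np.random.Generator, cfg: SimConfig) -> pd.DataFrame:
    rows = []
    spacing = cfg.chrom_length_bp / cfg.snps_per_chrom
    for c in range(cfg.n_chrom):
        jitter = rng.uniform(-cfg.position_jitter, cfg.position_jitter, cfg.snps_per_chrom)
        pos = np.round((np.arange(cfg.snps_per_chrom) + 0.5 + jitter) * spacing).astype(np.int64)
        pos = np.maximum.accumulate(pos) + np.arange(cfg.snps_per_chrom)  # strictly increasing
        pos = np.clip(pos, 1, cfg.chrom_length_bp - cfg.snps_per_chrom) + np.arange(cfg.snps_per_chrom)
        chrom = str(c + 1)
        rows.append(
            pd.DataFrame(
                {
                    "marker_id": [f"SNP{chrom}_{i:05d}" for i in range(cfg.snps_per_chrom)],
                    "chromosome": chrom,
                    "position_bp": pos,
                    "allele_a": "A",
                    "allele_b": "B",
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def simulate_cohort(cfg: SimConfig) -> tuple[GenotypeMatrix, Truth]:
    """Generate the cohort and its truth tables.  Fully seed-deterministic."""
    rng = np.random.default_rng(cfg.seed)
    markers = _marker_map(rng, cfg)
    m = len(markers)
    pos = markers["position_bp"].to_numpy()
    chrom_arr = markers["chromosome"].to_numpy()
    chrom_index = {str(c + 1): np.flatnonzero(chrom_arr == str(c + 1)) for c in range(cfg.n_chrom)}

    p_anc = rng.uniform(*cfg.maf_range, m)
    freqs = simulate_frequencies(rng, p_anc, cfg.divergence_F)

    # divergent selection loci: random markers, breeds split into hi/lo groups
    div_rows = []
    if cfg.n_divergent_loci:
        loci = np.sort(rng.choice(m, cfg.n_divergent_loci, replace=False))
        for j in loci:
            while True:  # need both groups non-empty
                hi = rng.random(cfg.n_pops) < 0.5
                if hi.any() and not hi.all():
                    break
            p_hi = rng.uniform(*cfg.divergent_hi_range)
            p_lo = rng.uniform(*cfg.divergent_lo_range)
            freqs[:, j] = np.where(hi, p_hi, p_lo)
            div_rows.append(
                {
                    "marker_id": markers["marker_id"].iat[j],
                    "chromosome": chrom_arr[j],
                    "position_bp": int(pos[j]),
                }
            )

    sample_rows = []
    calls_blocks = []
    truth_rows = []
    island_rows = []
    for k, pop in enumerate(cfg.pop_labels):
        n = cfg.n_per_pop[k]
        pk = freqs[k]
        calls = rng.binomial(2, pk, (n, m)).astype(np.int8)
        autozygous: list[list[tuple[str, int, int]]] = [[] for _ in range(n)]

        # per-individual tracts toward the breed's F_ROH target, with
        # individual spread (real cohorts show wide per-animal variation)
        for i in range(n):
            t_i = cfg.froh_target[k]
            if t_i > 0 and cfg.froh_spread > 0:
                t_i = max(0.0, rng.uniform(t_i - cfg.froh_spread, t_i + cfg.froh_spread))
            for chrom0, s, e in plan_tracts(
                rng, t_i, cfg.n_chrom, cfg.chrom_length_bp,
                cfg.tract_length_range_mb,
            ):
                chrom = str(chrom0 + 1)
                idx = chrom_index[chrom]
                inside = idx[(pos[idx] >= s) & (pos[idx] <= e)]
                hap = rng.binomial(1, pk[inside]).astype(np.int8)
                calls[i, inside] = 2 * hap
                autozygous[i].append((chrom, s, e))

        # shared-locus autozygosity (islands) for this breed
        for isl in cfg.islands:
            if isl.population != pop:
                continue
            n_carriers = math.ceil(isl.carrier_fraction * n)
            carriers = rng.choice(n, n_carriers, replace=False)
            idx = chrom_index[str(isl.chromosome)]
            core = idx[(pos[idx] >= isl.start_bp) & (pos[idx] <= isl.end_bp)]
            core_hap = rng.binomial(1, pk[core]).astype(np.int8)
            for i in sorted(carriers):
                ext_l = rng.exponential(cfg.island_extension_mean_bp)
                ext_r = rng.exponential(cfg.island_extension_mean_bp)
                s = max(1, int(isl.start_bp - ext_l))
                e = min(cfg.chrom_length_bp, int(isl.end_bp + ext_r))
                region = idx[(pos[idx] >= s) & (pos[idx] <= e)]
                own_hap = rng.binomial(1, pk[region]).astype(np.int8)
                calls[i, region] = 2 * own_hap
                calls[i, core] = 2 * core_hap  # shared core overrides
                autozygous[i].append((str(isl.chromosome), s, e))
            island_rows.append(
                {
                    "population": pop,
                    "chromosome": str(isl.chromosome),
                    "start_bp": isl.start_bp,
                    "end_bp": isl.end_bp,
                    "carrier_fraction": isl.carrier_fraction,
                    "n_carriers": n_carriers,
                }
            )

        for i in range(n):
            sid = f"{pop}_{i + 1:03d}"
            sample_rows.append({"sample_id": sid, "population": pop})
            per_chrom: dict[str, list[tuple[int, int]]] = {}
            for chrom, s, e in autozygous[i]:
                per_chrom.setdefault(chrom, []).append((s, e))
            planted = sum(
                e - s for iv in per_chrom.values() for s, e in _merge_intervals(iv)
            )
            truth_rows.append(
                {
                    "sample_id": sid,
                    "population": pop,
                    "froh_true": planted / cfg.genome_bp,
                }
            )
        calls_blocks.append(calls)

    calls = np.vstack(calls_blocks) if calls_blocks else np.empty((0, m), np.int8)

    # genotype errors, then missingness
    if cfg.genotype_error_rate > 0:
        err = rng.random(calls.shape) < cfg.genotype_error_rate
        shift = rng.integers(1, 3, size=calls.shape)
        calls = np.where(err, (calls + shift) % 3, calls).astype(np.int8)
    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls = np.where(mask, MISSING, calls).astype(np.int8)

    samples = pd.DataFrame(sample_rows, columns=["sample_id", "population"])
    g = GenotypeMatrix(calls, samples, markers)

    pairs = [
        {
            "pop_a": cfg.pop_labels[i],
            "pop_b": cfg.pop_labels[j],
            "F_true": (cfg.divergence_F[i] + cfg.divergence_F[j]) / 2.0,
        }
        for i in range(cfg.n_pops)
        for j in range(i + 1, cfg.n_pops)
    ]
    truth = Truth(
        froh=pd.DataFrame(truth_rows, columns=["sample_id", "population", "froh_true"]),
        pairwise_F=pd.DataFrame(pairs, columns=["pop_a", "pop_b", "F_true"]),
        islands=pd.DataFrame(
            island_rows,
            columns=[
                "population",
                "chromosome",
                "start_bp",
                "end_bp",
                "carrier_fraction",
                "n_carriers",
            ],
        ),
        divergent_loci=pd.DataFrame(
            div_rows, columns=["marker_id", "chromosome", "position_bp"]
        ),
    )
    return g, truth


def demo_config(seed: int = 0) -> SimConfig:
    """A paper-like three-breed cohort with one planted island per breed and
    a handful of divergent loci — the pipeline's smoke-test conditions."""
    islands = (
        PlantedIsland("BM", "16", 20_000_000, 23_000_000, 0.65),
        PlantedIsland("RM", "15", 60_000_000, 63_000_000, 0.55),
        PlantedIsland("SM", "17", 17_000_000, 26_000_000, 0.80),
    )
    return SimConfig(seed=seed, islands=islands, n_divergent_loci=10)


def synthetic_gene_bed(
    cfg: SimConfig,
    truth: Truth,
    rng: np.random.Generator,
    n_background: int = 200,
) -> pd.DataFrame:
    """Synthetic gene intervals (BED-style, returned 1-based): one gene over
    each planted island core and divergent locus, plus random background
    genes.  Purely synthetic stand-ins for an annotation resource."""
    rows = []
    for t, isl in truth.islands.iterrows():
        mid = (isl["start_bp"] + isl["end_bp"]) // 2
        rows.append(("ISLGENE%d" % (t + 1), str(isl["chromosome"]), int(mid - 50_000), int(mid + 50_000)))
    for t, loc in truth.divergent_loci.iterrows():
        p = int(loc["position_bp"])
        rows.append(("DIVGENE%d" % (t + 1), str(loc["chromosome"]), max(1, p - 20_000), p + 20_000))
    for t in range(n_background):
        chrom = str(int(rng.integers(cfg.n_chrom)) + 1)
        s = int(rng.integers(1, cfg.chrom_length_bp - 100_000))
        rows.append(("BGGENE%d" % (t + 1), chrom, s, s + int(rng.integers(5_000, 100_000))))
    return pd.DataFrame(rows, columns=["name", "chromosome", "start_bp", "end_bp"])


def write_cohort(cfg: SimConfig, outdir) -> tuple[GenotypeMatrix, Truth]:
    """Simulate and write a cohort as PLINK text+binary files, a population
    file, a synthetic gene BED and truth TSVs.  Returns the cohort too."""
    from pathlib import Path

    from .plink import write_plink_binary, write_plink_text

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    g, truth = simulate_cohort(cfg)
    write_plink_binary(g, outdir / "cohort.bed", outdir / "cohort.bim", outdir / "cohort.fam")
    write_plink_text(g, outdir / "cohort.ped", outdir / "cohort.map")
    g.samples[["sample_id", "population"]].to_csv(
        outdir / "populations.tsv", sep="\t", header=False, index=False
    )
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 917]))
    genes = synthetic_gene_bed(cfg, truth, rng)
    bed = genes.copy()
    bed["start0"] = bed["start_bp"] - 1
    bed[["chromosome", "start0", "end_bp", "name"]].to_csv(
        outdir / "genes.bed", sep="\t", header=False, index=False
    )
    truth.froh.to_csv(outdir / "truth_froh.tsv", sep="\t", index=False)
    truth.pairwise_F.to_csv(outdir / "truth_fst.tsv", sep="\t", index=False)
    truth.islands.to_csv(outdir / "truth_islands.tsv", sep="\t", index=False)
    truth.divergent_loci.to_csv(outdir / "truth_divergent_loci.tsv", sep="\t", index=False)
    return g, truth
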