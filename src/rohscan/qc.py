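"""SNP-array quality control: call rate, MAF, Hardy-Weinberg exact test,
genomic-relationship-based sample removal and LD pruning.

Three named profiles mirror the branch-specific QC a selection-signature
workflow needs:

``structure``
    90% sample/marker call rate, MAF >= 0.05, HWE p >= 1e-6, relatedness
    <= 0.95, LD pruning (50-SNP window, 25-SNP step, r^2 <= 0.5).
``roh``
    95% marker call rate, no MAF or HWE pruning (both would delete exactly
    the homozygous stretches ROH detection is after), applied per breed.
``fst``
    90% call rate and HWE, but no MAF filter (rare alleles carry the
    differentiation signal).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeMatrix, QcReport, QcStage

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LdPruneParams:
    window_snps: int = 50
    step_snps: int = 25
    r2_max: float = 0.5

    def __post_init__(self):
        if not (self.window_snps > self.step_snps > 0):
            raise ValueError("need window_snps > step_snps > 0")


@dataclass(frozen=True)
class QcConfig:
    sample_call_rate_min: float = 0.90
    marker_call_rate_min: float = 0.90
    maf_min: float | None = 0.05
    hwe_p_min: float | None = 1e-6
    relatedness_max: float | None = 0.95
    ld_prune: LdPruneParams | None = None
    markers_first: bool = True  # call-rate order; samples-first also supported

    def __post_init__(self):
        for f in (self.sample_call_rate_min, self.marker_call_rate_min):
            if not 0.0 <= f <= 1.0:
                raise ValueError("call-rate thresholds must lie in [0, 1]")
        if self.maf_min is not None and not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must lie in [0, 0.5]")


_PROFILES = {
    "structure": QcConfig(ld_prune=LdPruneParams()),
    "roh": QcConfig(marker_call_rate_min=0.95, maf_min=None, hwe_p_min=None),
    "fst": QcConfig(maf_min=None),
}


def qc_profile(name: str, **overrides) -> QcConfig:
    """Return a named QC profile ('structure', 'roh' or 'fst')."""
    try:
        cfg = _PROFILES[name]
    except KeyError:
        raise ValueError(f"unknown QC profile {name!r}; choose from {sorted(_PROFILES)}")
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# call rate

def filter_call_rate(g: GenotypeMatrix, cfg: QcConfig):
    """Remove markers then samples (or vice versa) below the call-rate
    thresholds.  Returns (filtered matrix, list of QcStage)."""
    stages = []

    def _markers(gm):
        keep = gm.marker_call_rate() >= cfg.marker_call_rate_min
        st = QcStage(
            "marker_call_rate",
            gm.n_samples,
            gm.n_markers,
            removed_markers=gm.markers.loc[~keep, "marker_id"].tolist(),
        )
        return gm.subset(marker_idx=np.flatnonzero(keep)), st

    def _samples(gm):
        keep = gm.sample_call_rate() >= cfg.sample_call_rate_min
        st = QcStage(
            "sample_call_rate",
            gm.n_samples,
            gm.n_markers,
            removed_samples=gm.samples.loc[~keep, "sample_id"].tolist(),
        )
        return gm.subset(sample_idx=np.flatnonzero(keep)), st

    order = (_markers, _samples) if cfg.markers_first else (_samples, _markers)
    for step in order:
        g, st = step(g)
        stages.append(st)
    if g.n_samples == 0 or g.n_markers == 0:
        logger.warning("matrix empty after call-rate filtering")
    return g, stages


# ---------------------------------------------------------------------------
# allele frequency / MAF

def allele_frequency(g: GenotypeMatrix) -> np.ndarray:
    """Allele-B frequency per marker over non-missing calls."""
    return g.allele_b_frequency()


def filter_maf(g: GenotypeMatrix, maf_min: float | None):
    """Drop markers with minor allele frequency below ``maf_min`` (None = off).
    Monomorphic markers have MAF 0 and are dropped whenever maf_min > 0."""
    if maf_min is None:
        return g, QcStage("maf", g.n_samples, g.n_markers)
    maf = np.nan_to_num(g.maf(), nan=0.0)
    keep = maf >= maf_min
    st = QcStage(
        "maf",
        g.n_samples,
        g.n_markers,
        removed_markers=g.markers.loc[~keep, "marker_id"].tolist(),
    )
    return g.subset(marker_idx=np.flatnonzero(keep)), st


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test

def hwe_exact_p(n_hom_a: int, n_het: int, n_hom_b: int) -> float | None:
    """Two-sided exact Hardy-Weinberg test (Wigginton-style).

    Sums the probabilities of all heterozygote counts no more likely than
    the observed one under the exact conditional distribution of genotype
    counts given the allele counts.  Returns None for an empty marker.
    """
    n = n_hom_a + n_het + n_hom_b
    if n == 0:
        return None
    if min(n_hom_a, n_het, n_hom_b) < 0:
        raise ValueError("negative genotype count")
    rare = min(2 * n_hom_a + n_het, 2 * n_hom_b + n_het)
    if rare == 0:
        return 1.0  # monomorphic: single attainable configuration
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    # log P(h) up to a constant: multinomial coefficient x 2^h
    from scipy.special import gammaln

    logw = (
        hets * math.log(2.0)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
    )
    logw -= logw.max()
    probs = np.exp(logw)
    probs /= probs.sum()
    obs = probs[np.flatnonzero(hets == n_het)[0]]
    return min(1.0, float(probs[probs <= obs * (1.0 + 1e-10)].sum()))


def filter_hwe(g: GenotypeMatrix, hwe_p_min: float | None):
    """Drop markers whose exact HWE p-value is below ``hwe_p_min`` (None = off).
    All-missing markers are skipped (retained)."""
    if hwe_p_min is None:
        return g, QcStage("hwe", g.n_samples, g.n_markers)
    counts = g.genotype_counts()
    keep = np.ones(g.n_markers, dtype=bool)
    for j, (na, nh, nb) in enumerate(
        zip(counts["n_hom_a"], counts["n_het"], counts["n_hom_b"])
    ):
        p = hwe_exact_p(int(na), int(nh), int(nb))
        if p is not None and p < hwe_p_min:
            keep[j] = False
    st = QcStage(
        "hwe",
        g.n_samples,
        g.n_markers,
        removed_markers=g.markers.loc[~keep, "marker_id"].tolist(),
    )
    return g.subset(marker_idx=np.flatnonzero(keep)), st


# ---------------------------------------------------------------------------
# genomic relationship

def relatedness_matrix(g: GenotypeMatrix) -> np.ndarray:
    """VanRaden method-1 genomic relationship matrix.

    G_ij = sum_k z_ik z_jk / (2 sum_k p_k q_k) with z = dosage - 2p, the sums
    running over markers non-missing for *both* members of the pair.
    """
    p = g.allele_b_frequency()
    informative = ~np.isnan(p)
    calls = g.calls[:, informative].astype(np.float64)
    p = p[informative]
    miss = calls == MISSING
    z = np.where(miss, 0.0, calls - 2.0 * p)
    w = (~miss).astype(np.float64)
    num = z @ z.T
    pq = p * (1.0 - p)
    den = 2.0 * (w * pq) @ w.T
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, 0.0)


def drop_related(g: GenotypeMatrix, max_coef: float | None):
    """Greedily break sample pairs with relationship coefficient above
    ``max_coef``, removing the lower-call-rate member of each pair
    (tie -> the later sample)."""
    if max_coef is None or g.n_samples < 2:
        return g, QcStage("relatedness", g.n_samples, g.n_markers)
    G = relatedness_matrix(g)
    call_rate = g.sample_call_rate()
    iu, ju = np.triu_indices(g.n_samples, k=1)
    coefs = G[iu, ju]
    order = np.argsort(-coefs, kind="stable")
    dropped: set[int] = set()
    for k in order:
        if coefs[k] <= max_coef:
            break
        i, j = int(iu[k]), int(ju[k])
        if i in dropped or j in dropped:
            continue
        victim = j if call_rate[j] <= call_rate[i] else i
        dropped.add(victim)
    keep = np.array([i for i in range(g.n_samples) if i not in dropped])
    st = QcStage(
        "relatedness",
        g.n_samples,
        g.n_markers,
        removed_samples=g.samples.iloc[sorted(dropped)]["sample_id"].tolist(),
    )
    return g.subset(sample_idx=keep), st


# ---------------------------------------------------------------------------
# LD pruning

def ld_r2(g: GenotypeMatrix, i: int, j: int) -> float:
    """Squared Pearson correlation of 0/1/2 dosages over pairwise-complete
    samples; 0.0 when either marker has no variance."""
    x = g.calls[:, i].astype(float)
    y = g.calls[:, j].astype(float)
    ok = (x != MISSING) & (y != MISSING)
    x, y = x[ok], y[ok]
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _window_r2(calls: np.ndarray) -> np.ndarray:
    """Pairwise-complete r^2 among the columns of a dosage block."""
    x = calls.astype(float)
    x[x == MISSING] = np.nan
    r = pd.DataFrame(x).corr(min_periods=2).to_numpy()
    return np.nan_to_num(r * r, nan=0.0)


def prune_ld(g: GenotypeMatrix, params: LdPruneParams | None = None):
    """Sliding-window LD pruning (PLINK --indep-pairwise semantics).

    Within each ``window_snps`` window on a chromosome, pairs with
    r^2 > ``r2_max`` are broken by removing the lower-MAF member (tie -> the
    later position), repeating to a fixpoint, then the window advances by
    ``step_snps``.
    """
    params = params or LdPruneParams()
    maf = np.nan_to_num(g.maf(), nan=0.0)
    active = np.ones(g.n_markers, dtype=bool)
    for chrom in g.chromosomes():
        idx = g.chromosome_slice(chrom)
        start = 0
        while start < len(idx):
            win = idx[start : start + params.window_snps]
            changed = True
            while changed:
                changed = False
                live = win[active[win]]
                if len(live) < 2:
                    break
                r2 = _window_r2(g.calls[:, live])
                for a in range(len(live)):
                    for b in range(a + 1, len(live)):
                        if r2[a, b] > params.r2_max:
                            ia, ib = live[a], live[b]
                            victim = ib if maf[ib] <= maf[ia] else ia
                            active[victim] = False
                            changed = True
                            break
                    if changed:
                        break
            if start + params.window_snps >= len(idx):
                break
            start += params.step_snps
    st = QcStage(
        "ld_prune",
        g.n_samples,
        g.n_markers,
        removed_markers=g.markers.loc[~active, "marker_id"].tolist(),
    )
    return g.subset(marker_idx=np.flatnonzero(active)), st


# ---------------------------------------------------------------------------
# full cascade

def apply_qc(g: GenotypeMatrix, cfg: QcConfig):
    """Run the QC cascade (call rate -> MAF -> HWE -> relatedness -> LD)
    and return (filtered matrix, QcReport)."""
    report = QcReport()
    g, stages = filter_call_rate(g, cfg)
    for st in stages:
        report.add(st)
    g, st = filter_maf(g, cfg.maf_min)
    report.add(st)
    g, st = filter_hwe(g, cfg.hwe_p_min)
    report.add(st)
    g, st = drop_related(g, cfg.relatedness_max)
    report.add(st)
    if cfg.ld_prune is not None:
        g, st = prune_ld(g, cfg.ld_prune)
        report.add(st)
    for st in report.stages:
        logger.info(
            "QC %s: samples %d->%d, markers %d->%d",
            st.name,
            st.n_samples_before,
            st.n_samples_after,
            st.n_markers_before,
            st.n_markers_after,
        )
    return g, report
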