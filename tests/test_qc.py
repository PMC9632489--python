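"""Quality control: call rate, MAF, exact HWE, relatedness, LD pruning."""

import math
from fractions import Fraction

import numpy as np
import pytest

from rohscan.datamodel import MISSING
from rohscan.qc import (
    LdPruneParams,
    QcConfig,
    drop_related,
    filter_call_rate,
    filter_hwe,
    filter_maf,
    hwe_exact_p,
    ld_r2,
    prune_ld,
    qc_profile,
    relatedness_matrix,
)

from conftest import make_matrix


# ---------------------------------------------------------------------------
# call rate


def test_marker_below_call_rate_removed():
    calls = np.zeros((10, 10), dtype=np.int8)
    calls[:2, 0] = MISSING  # SNP 0 call rate 0.8 < 0.9
    g, stages = filter_call_rate(make_matrix(calls), QcConfig())
    assert stages[0].removed_markers == ["snp0"]
    assert g.n_markers == 9


def test_sample_below_call_rate_removed():
    calls = np.zeros((20, 10), dtype=np.int8)
    calls[1, :5] = MISSING  # sample 1 call rate 0.5; markers stay at 19/20
    g, stages = filter_call_rate(make_matrix(calls), QcConfig())
    assert not stages[0].removed_markers
    assert stages[1].removed_samples == ["s1"]
    assert g.n_samples == 19


def test_complete_matrix_is_identity():
    calls = np.ones((5, 8), dtype=np.int8)
    g, stages = filter_call_rate(make_matrix(calls), QcConfig())
    assert g.n_samples == 5 and g.n_markers == 8
    assert all(not s.removed_samples and not s.removed_markers for s in stages)


def test_samples_first_order_supported():
    calls = np.zeros((10, 10), dtype=np.int8)
    calls[0, :] = MISSING  # sample 0 entirely missing drags down every marker
    cfg = QcConfig(markers_first=False)
    g, stages = filter_call_rate(make_matrix(calls), cfg)
    assert stages[0].name == "sample_call_rate"
    assert g.n_samples == 9 and g.n_markers == 10  # markers recover once s0 is gone


# ---------------------------------------------------------------------------
# MAF


def test_maf_from_genotype_counts():
    # counts hom_a=5, het=5 -> p_b = 5/20 = 0.25
    calls = np.array([[0] * 5 + [1] * 5]).T.astype(np.int8).reshape(10, 1)
    g = make_matrix(calls)
    assert g.maf()[0] == pytest.approx(0.25)


def test_monomorphic_marker_removed_and_none_disables():
    calls = np.zeros((6, 2), dtype=np.int8)
    calls[:3, 1] = 1
    g, st = filter_maf(make_matrix(calls), 0.05)
    assert st.removed_markers == ["snp0"]
    g2, st2 = filter_maf(make_matrix(calls), None)
    assert g2.n_markers == 2 and not st2.removed_markers


# ---------------------------------------------------------------------------
# HWE exact test


def hwe_enumeration_oracle(n_aa, n_ab, n_bb):
    """Exact-rational enumeration of the conditional het-count distribution."""
    n = n_aa + n_ab + n_bb
    rare = min(2 * n_aa + n_ab, 2 * n_bb + n_ab)
    if rare == 0:
        return Fraction(1)
    weights = {}
    for h in range(rare % 2, rare + 1, 2):
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        weights[h] = Fraction(
            math.factorial(n),
            math.factorial(hom_rare) * math.factorial(h) * math.factorial(hom_common),
        ) * Fraction(2) ** h
    total = sum(weights.values())
    obs = weights[n_ab]
    return sum(w for w in weights.values() if w <= obs) / total


def test_hwe_equilibrium_counts_near_one():
    assert hwe_exact_p(25, 50, 25) >= 0.999
    assert hwe_exact_p(25, 50, 25) == pytest.approx(
        float(hwe_enumeration_oracle(25, 50, 25)), abs=1e-12
    )


def test_hwe_het_deficit_rejected_at_threshold():
    p = hwe_exact_p(50, 0, 50)
    assert p < 1e-6
    assert p == pytest.approx(float(hwe_enumeration_oracle(50, 0, 50)), abs=1e-12)


def test_hwe_monomorphic_is_one_and_empty_is_none():
    assert hwe_exact_p(10, 0, 0) == 1.0
    assert hwe_exact_p(0, 0, 0) is None


def test_hwe_filter_removes_violating_marker():
    calls = np.concatenate(
        [
            np.repeat([0, 1, 2], [6, 12, 6])[:, None],  # near-HWE
            np.repeat([0, 2], [12, 12])[:, None],  # no hets at p=0.5, p<1e-6
        ],
        axis=1,
    ).astype(np.int8)
    g, st = filter_hwe(make_matrix(calls), 1e-6)
    assert st.removed_markers == ["snp1"]


# ---------------------------------------------------------------------------
# relatedness


def test_duplicate_sample_detected_and_one_removed(rng):
    calls = rng.binomial(2, rng.uniform(0.2, 0.8, 400), (50, 400)).astype(np.int8)
    calls[49] = calls[0]  # duplicate of sample 0
    calls[49, :5] = MISSING  # duplicate has the lower call rate
    g = make_matrix(calls)
    G = relatedness_matrix(g)
    assert G[0, 49] > 0.95
    g2, st = drop_related(g, 0.95)
    assert st.removed_samples == ["s49"]


def test_unrelated_samples_off_diagonal_at_finite_sample_expectation(rng):
    # with in-sample allele frequencies the rows of Z sum to ~0, so the
    # expected off-diagonal is -mean(diag)/(n-1), vanishing as n grows
    n = 40
    calls = rng.binomial(2, rng.uniform(0.2, 0.8, 2000), (n, 2000)).astype(np.int8)
    G = relatedness_matrix(make_matrix(calls))
    off = G[np.triu_indices(n, k=1)]
    assert abs(off.mean() + G.diagonal().mean() / (n - 1)) <= 0.005


def test_relatedness_threshold_above_self_removes_nothing(rng):
    calls = rng.binomial(2, 0.5, (6, 100)).astype(np.int8)
    calls[5] = calls[0]
    g2, st = drop_related(make_matrix(calls), 1.01)
    assert not st.removed_samples


# ---------------------------------------------------------------------------
# LD pruning


def test_duplicated_snp_pair_pruned(rng):
    base = rng.binomial(2, 0.5, (30, 1)).astype(np.int8)
    other = rng.binomial(2, 0.5, (30, 3)).astype(np.int8)
    calls = np.concatenate([base, base, other], axis=1)
    g = make_matrix(calls)
    assert ld_r2(g, 0, 1) == pytest.approx(1.0)
    g2, st = prune_ld(g, LdPruneParams(window_snps=5, step_snps=2, r2_max=0.5))
    assert len(st.removed_markers) >= 1
    assert not ({"snp0", "snp1"} <= set(g2.markers["marker_id"]))


def test_r2_max_one_prunes_nothing(rng):
    calls = rng.binomial(2, 0.5, (20, 10)).astype(np.int8)
    calls[:, 1] = calls[:, 0]
    g2, st = prune_ld(make_matrix(calls), LdPruneParams(window_snps=5, step_snps=2, r2_max=1.0))
    assert not st.removed_markers


def brute_force_prune(calls, positions, maf, r2_max):
    """Exhaustive greedy pruning over the full pair set (single-window case)."""
    active = list(range(calls.shape[1]))
    changed = True
    while changed:
        changed = False
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                i, j = active[ai], active[bi]
                x = calls[:, i].astype(float)
                y = calls[:, j].astype(float)
                ok = (x != MISSING) & (y != MISSING)
                x, y = x[ok], y[ok]
                if len(x) < 2 or x.std() == 0 or y.std() == 0:
                    continue
                r2 = np.corrcoef(x, y)[0, 1] ** 2
                if r2 > r2_max:
                    victim = j if maf[j] <= maf[i] else i
                    active.remove(victim)
                    changed = True
                    break
            if changed:
                break
    return set(active)


@pytest.mark.parametrize("trial", range(4))
def test_prune_matches_exhaustive_oracle_in_one_window(trial):
    rng = np.random.default_rng(1000 + trial)
    n, m = 50, 12
    p = rng.uniform(0.1, 0.9, m)
    calls = rng.binomial(2, p, (n, m)).astype(np.int8)
    calls[:, 1] = calls[:, 0]  # guarantee at least one high-LD pair
    g = make_matrix(calls)
    maf = np.nan_to_num(g.maf(), nan=0.0)
    g2, _ = prune_ld(g, LdPruneParams(window_snps=m + 1, step_snps=1, r2_max=0.5))
    kept = {int(s[3:]) for s in g2.markers["marker_id"]}
    assert kept == brute_force_prune(g.calls, g.markers["position_bp"].to_numpy(), maf, 0.5)


# ---------------------------------------------------------------------------
# profiles


def test_branch_profiles_match_workflow():
    s = qc_profile("structure")
    assert s.maf_min == 0.05 and s.hwe_p_min == 1e-6 and s.ld_prune is not None
    r = qc_profile("roh")
    assert r.marker_call_rate_min == 0.95 and r.maf_min is None and r.hwe_p_min is None
    f = qc_profile("fst")
    assert f.maf_min is None and f.hwe_p_min == 1e-6 and f.ld_prune is None
    with pytest.raises(ValueError):
        qc_profile("nope")
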