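"""ROH calling: the L formula, window scanning, segment assembly and F_ROH."""

import math

import numpy as np
import pandas as pd
import pytest

from rohscan.datamodel import MISSING
from rohscan.roh import (
    RohParams,
    assemble_segments,
    call_roh,
    compute_L,
    froh,
    mean_observed_het,
    window_flags,
    window_scan,
)

from conftest import make_matrix


# ---------------------------------------------------------------------------
# L parameter


def test_L_formula_matches_direct_evaluation():
    expected = math.ceil(math.log(0.05 / (36_964 * 30)) / math.log(1 - 0.28))
    assert compute_L(36_964, 30, 0.28) == max(expected, 20)
    assert expected == 52  # frozen from evaluating the formula numerically


def test_L_nondecreasing_as_alpha_shrinks():
    a = compute_L(30_000, 30, 0.3, alpha=0.05)
    b = compute_L(30_000, 30, 0.3, alpha=0.025)
    assert b >= a


def test_L_floor_applies_in_high_het_limit():
    assert compute_L(100, 2, 0.99) == 20


def test_L_rejects_degenerate_heterozygosity():
    with pytest.raises(ValueError):
        compute_L(100, 10, 0.0)
    with pytest.raises(ValueError):
        compute_L(100, 10, 1.0)


# ---------------------------------------------------------------------------
# window scan


def brute_window_flags(calls_1d, L, params):
    """Explicit per-window enumeration of the flagging rule."""
    calls = np.asarray(calls_1d)
    m = len(calls)
    if m < L:
        return np.zeros(m, dtype=bool)
    n_win = m - L + 1
    ok = []
    for w in range(n_win):
        win = calls[w : w + L]
        ok.append(
            (win == 1).sum() <= params.max_het_per_window
            and (win == MISSING).sum() <= params.max_missing_per_window
        )
    flags = np.zeros(m, dtype=bool)
    for j in range(m):
        cov = [w for w in range(max(0, j - L + 1), min(j, n_win - 1) + 1)]
        frac = sum(ok[w] for w in cov) / len(cov)
        flags[j] = frac >= params.window_overlap_min
    return flags


def test_all_homozygous_chromosome_fully_flagged():
    params = RohParams()
    calls = np.zeros(40, dtype=np.int8)
    assert window_scan(calls, 10, params).all()


def test_single_het_clears_neighbourhood():
    params = RohParams(window_overlap_min=1.0)
    calls = np.zeros(60, dtype=np.int8)
    calls[30] = 1
    flags = window_scan(calls, 10, params)
    np.testing.assert_array_equal(flags, brute_window_flags(calls, 10, params))
    assert not flags[21:40].any()  # every window covering SNP 30 fails
    assert flags[:21].all() and flags[40:].all()


def test_two_missing_in_every_window_blocks_flags():
    params = RohParams()
    calls = np.zeros(30, dtype=np.int8)
    calls[::4] = MISSING  # 2+ missing in any 10-SNP window
    assert not window_scan(calls, 10, params).any()


def test_short_chromosome_yields_no_flags():
    assert not window_scan(np.zeros(5, dtype=np.int8), 10, RohParams()).any()


@pytest.mark.parametrize("trial", range(10))
def test_window_flags_match_brute_enumeration(trial):
    rng = np.random.default_rng(42 + trial)
    params = RohParams()
    L = int(rng.integers(4, 15))
    m = int(rng.integers(L, 120))
    calls = rng.choice(
        np.array([0, 1, 2, MISSING], dtype=np.int8), size=m, p=[0.45, 0.15, 0.3, 0.1]
    )
    got = window_scan(calls, L, params)
    np.testing.assert_array_equal(got, brute_window_flags(calls, L, params))


# ---------------------------------------------------------------------------
# segment assembly


def test_assembled_run_has_expected_class():
    params = RohParams()
    # 60 flagged SNPs spanning 5.4 Mb, max gap < 1 Mb, L = 50
    positions = np.linspace(10_000_000, 15_400_000, 60).astype(np.int64)
    flags = np.ones(60, dtype=bool)
    segs = assemble_segments(flags, positions, params, min_snps=50)
    assert segs == [(0, 59)]
    length = positions[59] - positions[0]
    assert 4e6 <= length < 8e6


def test_gap_splits_run_into_retested_pieces():
    params = RohParams()
    pos_a = np.arange(1_000_000, 1_000_000 + 30 * 50_000, 50_000)
    pos_b = pos_a[-1] + 1_200_000 + np.arange(0, 30 * 50_000, 50_000)
    positions = np.concatenate([pos_a, pos_b])
    flags = np.ones(60, dtype=bool)
    segs = assemble_segments(flags, positions, params, min_snps=25)
    assert segs == [(0, 29), (30, 59)]
    # raising the minimum above each piece kills both
    assert assemble_segments(flags, positions, params, min_snps=40) == []


def test_sparse_run_fails_density_rule():
    params = RohParams()
    positions = np.linspace(1, 9_000_000, 20).astype(np.int64)  # 450 kb/SNP
    flags = np.ones(20, dtype=bool)
    assert assemble_segments(flags, positions, params, min_snps=20) == []


# ---------------------------------------------------------------------------
# brute-force oracle over the full caller


def brute_force_segments(calls_1d, positions, L, params, min_snps):
    """Independent enumeration: flags per window, then every candidate run
    checked against each rule explicitly."""
    flags = brute_window_flags(calls_1d, L, params)
    segs = []
    run = []
    for j in range(len(flags) + 1):
        if j < len(flags) and flags[j]:
            run.append(j)
            continue
        if run:
            pieces = [[run[0]]]
            for k in run[1:]:
                if positions[k] - positions[pieces[-1][-1]] > params.max_gap_bp:
                    pieces.append([k])
                else:
                    pieces[-1].append(k)
            for piece in pieces:
                n = len(piece)
                length = positions[piece[-1]] - positions[piece[0]]
                if n >= min_snps and length / n <= params.min_density_bp_per_snp:
                    segs.append((piece[0], piece[-1]))
            run = []
    return segs


@pytest.mark.parametrize("trial", range(15))
def test_caller_matches_brute_force_on_random_instances(trial):
    rng = np.random.default_rng(7_000 + trial)
    params = RohParams()
    L = int(rng.integers(5, 20))
    m = int(rng.integers(L + 5, 300))
    positions = np.sort(rng.choice(np.arange(1, 20_000_000, 1_000), m, replace=False))
    calls = rng.choice(
        np.array([0, 1, 2, MISSING], dtype=np.int8), size=m, p=[0.60, 0.04, 0.32, 0.04]
    )
    flags = window_scan(calls, L, params)
    got = assemble_segments(flags, positions, params, min_snps=L)
    assert got == brute_force_segments(calls, positions, L, params, min_snps=L)


# ---------------------------------------------------------------------------
# F_ROH


def _seg_row(sample, chrom, start, end, n):
    from rohscan.datamodel import length_class

    return {
        "sample_id": sample,
        "chromosome": chrom,
        "start_bp": start,
        "end_bp": end,
        "n_snps": n,
        "length_bp": end - start,
        "length_class": length_class(end - start),
    }


def test_froh_arithmetic_by_class():
    segs = pd.DataFrame(
        [
            _seg_row("s0", "1", 1_000_000, 4_000_000, 30),  # 3 Mb -> class 2-4
            _seg_row("s0", "2", 5_000_000, 15_000_000, 80),  # 10 Mb -> class 8-16
        ]
    )
    out = froh(segs, coverage_bp=100_000_000, sample_ids=["s0", "s1"])
    row = out.set_index("sample_id").loc["s0"]
    assert row["froh_all"] == pytest.approx(0.13)
    assert row["froh_2-4"] == pytest.approx(0.03)
    assert row["froh_8-16"] == pytest.approx(0.10)
    assert out.set_index("sample_id").loc["s1", "froh_all"] == 0.0


def test_froh_class_sum_equals_total():
    rng = np.random.default_rng(5)
    rows = []
    for k in range(30):
        start = int(rng.integers(1, 80_000_000))
        rows.append(_seg_row("s0", str(rng.integers(1, 5)), start, start + int(rng.integers(5e5, 2e7)), 50))
    out = froh(pd.DataFrame(rows), coverage_bp=400_000_000)
    row = out.iloc[0]
    class_sum = sum(row[c] for c in out.columns if c.startswith("froh_") and c != "froh_all")
    assert row["froh_all"] == pytest.approx(class_sum, abs=1e-12)


def test_froh_requires_positive_coverage():
    with pytest.raises(ValueError):
        froh(pd.DataFrame(columns=["sample_id", "length_bp", "length_class"]), 0)


def test_whole_map_segment_gives_froh_one():
    segs = pd.DataFrame([_seg_row("s0", "1", 1, 10_000_001, 100)])
    out = froh(segs, coverage_bp=10_000_000, sample_ids=["s0"])
    assert out.iloc[0]["froh_all"] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# cohort-level behaviour


def test_het_call_never_lengthens_segments(rng):
    calls = np.zeros((1, 100), dtype=np.int8)
    g = make_matrix(calls, positions=(np.arange(100) + 1) * 50_000)
    params = RohParams(window_snps=20)
    base = call_roh(g, params)
    calls2 = calls.copy()
    calls2[0, 50] = 1
    g2 = make_matrix(calls2, positions=(np.arange(100) + 1) * 50_000)
    pert = call_roh(g2, params)
    assert pert["length_bp"].sum() <= base["length_bp"].sum()


def test_no_subtwo_megabase_segments_on_chip_density_map():
    """With L from the formula at chip density, short runs cannot pass."""
    rng = np.random.default_rng(99)
    n, per_chrom = 20, 1000
    calls = rng.binomial(2, rng.uniform(0.2, 0.8, 2 * per_chrom), (n, 2 * per_chrom)).astype(np.int8)
    pos = np.concatenate([np.sort(rng.choice(np.arange(1, 60_000_000, 100), per_chrom, False))] * 2)
    chroms = ["1"] * per_chrom + ["2"] * per_chrom
    g = make_matrix(calls, positions=pos, chromosomes=chroms)
    segs = call_roh(g, RohParams())
    assert (segs["length_bp"] >= 2_000_000).all()


def test_mean_observed_het_ignores_missing():
    calls = np.array([[1, 1, 0, MISSING], [0, 0, 0, 0]], dtype=np.int8)
    g = make_matrix(calls)
    assert mean_observed_het(g) == pytest.approx((2 / 3) / 2)
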