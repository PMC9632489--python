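import numpy as np
import pandas as pd
import pytest

from rohscan.datamodel import GenotypeMatrix


def make_matrix(calls, positions=None, chromosomes=None, populations=None, alleles=None):
    """Build a small GenotypeMatrix from an explicit call array."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    positions = positions if positions is not None else (np.arange(m) + 1) * 1000
    chromosomes = chromosomes if chromosomes is not None else ["1"] * m
    populations = populations if populations is not None else ["POP"] * n
    if alleles is None:
        alleles = [("A", "B")] * m
    markers = pd.DataFrame(
        {
            "marker_id": [f"snp{j}" for j in range(m)],
            "chromosome": chromosomes,
            "position_bp": positions,
            "allele_a": [a for a, _ in alleles],
            "allele_b": [b for _, b in alleles],
        }
    )
    samples = pd.DataFrame(
        {"sample_id": [f"s{i}" for i in range(n)], "population": populations}
    )
    return GenotypeMatrix(calls, samples, markers)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_matrix(rng, n=8, m=40, n_chrom=2, missing_rate=0.05):
    """Random valid GenotypeMatrix for round-trip property tests."""
    calls = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    mask = rng.random((n, m)) < missing_rate
    calls[mask] = -1
    chroms, pos = [], []
    sizes = np.bincount(rng.integers(0, n_chrom, m), minlength=n_chrom)
    for c, size in enumerate(sizes):
        chroms += [str(c + 1)] * int(size)
        pos.append(np.sort(rng.choice(np.arange(1, 10_000_000), int(size), replace=False)))
    return make_matrix(calls, positions=np.concatenate(pos), chromosomes=chroms)
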