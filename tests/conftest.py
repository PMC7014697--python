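import numpy as np
import pandas as pd
import pytest

from hapscan import (
    GenotypeMatrix,
    SimSpec,
    compute_rrm,
    simulate_genotypes,
    spectral_decompose,
)


def make_G(calls, chrom=None, pos=None, sample_ids=None):
    """Build a GenotypeMatrix from a raw 0/1 array with a default marker map."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if chrom is None:
        chrom = ["1"] * m
    if pos is None:
        pos = list(range(100, 100 + 100 * m, 100))
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(n)]
    markers = pd.DataFrame(
        {"id": [f"m{j}" for j in range(m)], "chrom": [str(c) for c in chrom], "pos": pos}
    )
    return GenotypeMatrix(calls, sample_ids, markers)


@pytest.fixture(scope="session")
def sim_panel():
    """A medium simulated panel shared by the slower model-level tests."""
    spec = SimSpec(n_samples=200, n_snps=400, seed=7)
    G = simulate_genotypes(spec)
    km = compute_rrm(G)
    eig = spectral_decompose(km)
    return {"spec": spec, "G": G, "K": km, "eig": eig}


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
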