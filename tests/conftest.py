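import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from ednacompare import CommunityMatrix, MarkerProfile, SyntheticConfig


def make_cm(rows, sample_ids=None, otu_ids=None, marker="test", plot_of=None,
            subplot_of=None):
    rows = np.asarray(rows, dtype=float)
    n, s = rows.shape
    sample_ids = sample_ids or [f"s{i+1}" for i in range(n)]
    otu_ids = otu_ids or [f"o{i+1}" for i in range(s)]
    df = pd.DataFrame(rows, index=sample_ids, columns=otu_ids)
    return CommunityMatrix(df, marker=marker, plot_of=plot_of or {},
                           subplot_of=subplot_of or {})


def random_cm(rng, n_samples=5, n_otus=10, max_count=20):
    """Random integer community matrix with no empty rows/columns."""
    while True:
        counts = rng.integers(0, max_count + 1, size=(n_samples, n_otus))
        if (counts.sum(axis=1) > 0).all() and (counts.sum(axis=0) > 0).any():
            keep = counts.sum(axis=0) > 0
            counts = counts[:, keep]
            if counts.shape[1] >= 2:
                return make_cm(counts)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_gradient_bundle():
    """A fast, fully structured synthetic bundle shared across tests."""
    from ednacompare import simulate_gradient_metacommunity

    cfg = SyntheticConfig(
        profiles={"eDNA": MarkerProfile(species_pool=80, reads_per_sample=600)},
        seed=42,
    )
    return simulate_gradient_metacommunity(cfg)
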