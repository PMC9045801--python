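import numpy as np
import pytest

import fwdfungi as f


@pytest.fixture(scope="session")
def default_design():
    return f.generate_design(4, 6, seed=0)


@pytest.fixture(scope="session")
def small_community():
    """Small simulated study reused across tests: 1 block, 4 years, 40 taxa."""
    design = f.generate_design(1, 4, seed=0)
    taxa = f.generate_taxa(40, specialist_fraction=0.5, temporal_range=(1.0, 4.0), seed=11)
    counts, truth = f.generate_community_counts(design, taxa, depth=800, overdispersion=0.01, seed=5)
    return design, taxa, counts, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
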