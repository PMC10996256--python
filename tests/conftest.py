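import numpy as np
import pytest

import sirtest as st


@pytest.fixture(scope="session")
def small_dataset():
    """Aligned null dataset: n=150, k=4 SNPs, q=3 traits."""
    rng = np.random.default_rng(42)
    G = st.simulate_genotypes(150, 4, rng=rng)
    Y = st.simulate_phenotypes(G, np.zeros((4, 3)), 0.3, rng)
    return Y, G


@pytest.fixture(scope="session")
def signal_dataset():
    """Scenario-1-Case-1-style dataset with a strong SNP-3 effect."""
    rng = np.random.default_rng(7)
    G = st.simulate_genotypes(400, 5, rng=rng)
    Y = st.simulate_phenotypes(G, st.scenario_effects(1, 1), 0.2, rng)
    return Y, G
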