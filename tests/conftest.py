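import numpy as np
import pytest

from finemapkit import simulate_haplotype_panel


@pytest.fixture(scope="session")
def panel():
    """A mid-sized phased panel shared by LD / fine-mapping tests."""
    return simulate_haplotype_panel(n_hap=200, n_variants=300, seed=42)


@pytest.fixture(scope="session")
def tight_ld_panel():
    """Few founders + low recombination: long blocks, many strong proxies."""
    return simulate_haplotype_panel(
        n_hap=300, n_variants=60, recombination_rate=2e-6, n_founders=4, seed=7
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
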