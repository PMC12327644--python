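import numpy as np
import pytest

import blrfine as bf


@pytest.fixture(scope="session")
def small_design():
    """A small LD-structured design: n=2000, m=40, moderate LD."""
    G = bf.simulate_genotypes(2000, 40, ld_rho=0.6, seed=42)
    return G, bf.scale_genotypes(G)


@pytest.fixture(scope="session")
def ga1_sim(small_design):
    _, W = small_design
    return bf.simulate_ga1(W, m_causal=4, h2=0.3, seed=7)
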