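import numpy as np
import pytest

from stratafish.synthetic import (
    default_genes,
    default_section_spec,
    default_subtypes,
    generate_reference,
    generate_section,
)


@pytest.fixture(scope="session")
def genes():
    return default_genes()


@pytest.fixture(scope="session")
def subtypes(genes):
    return default_subtypes(genes, seed=0)


@pytest.fixture(scope="session")
def small_section(genes, subtypes):
    """A reduced-density section (~3.5k cells) shared across tests."""
    spec = default_section_spec(seed=3)
    spec.densities = {k: v * 0.2 for k, v in spec.densities.items()}
    return generate_section(spec, subtypes, genes)


@pytest.fixture(scope="session")
def reference(genes, subtypes):
    return generate_reference(subtypes, n_cells=4000, seed=2, genes=genes)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def annulus_points(n, r_in, r_out, span, seed, center=(0.0, 0.0)):
    """Area-uniform random points in an annular arc around angle pi/2."""
    g = np.random.default_rng(seed)
    r = np.sqrt(g.uniform(r_in**2, r_out**2, n))
    th = g.uniform(np.pi / 2 - span / 2, np.pi / 2 + span / 2, n)
    return np.c_[center[0] + r * np.cos(th), center[1] + r * np.sin(th)], r
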