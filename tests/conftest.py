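import numpy as np
import pytest

from unicorn_hic import simulate
from unicorn_hic.hic_io import ContactMap


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_map(rng):
    """Random symmetric non-negative 30-bin contact map."""
    m = rng.poisson(3.0, size=(30, 30)).astype(float)
    return ContactMap((m + m.T) / 2)


@pytest.fixture(scope="session")
def chain60():
    """Fixed 60-locus chain and its noiseless contact map (alpha=1)."""
    cfg = simulate.SimulationConfig(n_loci=60, alpha_true=1.0, seed=11)
    s = simulate.generate_structure(cfg)
    cm = simulate.structure_to_contacts(s, cfg)
    return cfg, s, cm


def make_noisy_maps(n_maps, seed0, n_loci=120):
    """Poisson-noise contact maps with TAD blocks, for training tests."""
    maps = []
    blocks = [(n_loci // 12, n_loci // 3, 2.0),
              (n_loci // 2, (5 * n_loci) // 6, 1.8)]
    for k in range(n_maps):
        cfg = simulate.SimulationConfig(
            n_loci=n_loci, alpha_true=1.0, count_scale=30.0, noise="poisson",
            seed=seed0 + k, tad_blocks=blocks)
        s = simulate.generate_structure(cfg)
        maps.append(simulate.structure_to_contacts(s, cfg))
    return maps
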