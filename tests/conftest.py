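import numpy as np
import pytest

import stepcore as sc


@pytest.fixture
def trio():
    """Two unrelated founders A, B and their offspring C."""
    return sc.build_pedigree([("C", "A", "B")])


@pytest.fixture
def three_gen():
    """Four founder grandparents, two parents, one grandchild."""
    return sc.build_pedigree([
        ("P1", "G1", "G2"),
        ("P2", "G3", "G4"),
        ("X", "P1", "P2"),
    ])


def random_distance_matrix(rng, n):
    X = rng.random((n, n))
    vals = (X + X.T) / 2.0
    np.fill_diagonal(vals, 0.0)
    return sc.RelationshipMatrix([f"g{k}" for k in range(n)], vals, "D")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_sim():
    """A modest simulated breeding program shared by read-only tests."""
    cfg = sc.SimConfig(seed=7, n_subpops=2, n_founders=5, generations=3,
                       crosses_per_generation=4, offspring_per_cross=2,
                       n_markers=500)
    true_ped, observed = sc.simulate_pedigree(cfg)
    drop = sc.gene_drop(true_ped, cfg.n_markers, cfg.freq_range, seed=8,
                        compute_ibd=False)
    return cfg, true_ped, observed, drop
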