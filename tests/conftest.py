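import numpy as np
import pytest

from raretax.datatypes import OtuTable
from raretax.simulate import SimulationConfig, simulate_dataset


@pytest.fixture
def tiny_table():
    counts = np.array([[1, 2], [3, 4]])
    return OtuTable(("s1", "s2"), ("o1", "o2"), counts)


@pytest.fixture
def tiny_tree_file(tmp_path):
    path = tmp_path / "tree.nwk"
    path.write_text("((A:1,B:1):1,C:2);\n")
    return path


@pytest.fixture(scope="session")
def small_dataset():
    """One modest synthetic dataset shared by read-only tests."""
    cfg = SimulationConfig(n_otus=150, n_samples_per_group=8, depth=5000,
                           assembly_mode="variable_filtering", seed=11)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """A dataset at the generator's default study conditions."""
    return simulate_dataset(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def neutral_dataset():
    cfg = SimulationConfig(n_otus=120, n_samples_per_group=8, depth=5000,
                           assembly_mode="neutral", seed=7)
    return simulate_dataset(cfg)


def random_table(rng, n_samples=6, n_otus=12, lam=30):
    counts = rng.poisson(lam, size=(n_samples, n_otus))
    counts[0, :] += 1  # guard against an all-zero sample
    return OtuTable(tuple(f"s{i}" for i in range(n_samples)),
                    tuple(f"o{j}" for j in range(n_otus)), counts)
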