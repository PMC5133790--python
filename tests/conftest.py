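import numpy as np
import pytest

from pepscreen import compile_align, synthetic
from pepscreen.reference import load_reference_panel
from pepscreen.synthetic import SimConfig, generate, matrix_from_panel_table


@pytest.fixture(scope="session")
def small_sim():
    """A scaled-down seeded dataset for cheap unit tests."""
    cfg = SimConfig(n_peptides=60, n_planted=8, seed=11)
    runs, truth = generate(cfg)
    return runs, truth


@pytest.fixture(scope="session")
def small_matrix(small_sim):
    runs, _ = small_sim
    return compile_align.compile_dataset(runs)


@pytest.fixture(scope="session")
def default_sim():
    """One full-size study-condition dataset (888 peptides, 55 planted)."""
    cfg = SimConfig(seed=7)
    runs, truth = generate(cfg)
    matrix = compile_align.compile_dataset(runs)
    return runs, truth, matrix


@pytest.fixture(scope="session")
def reference_panel():
    return load_reference_panel()


@pytest.fixture(scope="session")
def reference_matrix(reference_panel):
    """Synthetic abundance matrix reproducing the printed panel summaries."""
    return matrix_from_panel_table(reference_panel)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
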