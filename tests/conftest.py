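import numpy as np
import pytest

from spatialnmf.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_dataset():
    """A quick 10×10 / 3-domain dataset for unit-level pipeline checks."""
    return generate_dataset(
        SyntheticConfig(rows=10, cols=10, k=3, n_genes=90, n_markers_per_domain=8, seed=7)
    )


@pytest.fixture(scope="session")
def benchmark_config():
    """The reference synthetic conditions used by the end-to-end checks."""
    return SyntheticConfig(
        rows=20,
        cols=20,
        k=4,
        layout="stripes",
        n_genes=300,
        n_markers_per_domain=10,
        baseline_mean=2.0,
        effect_size=5.0,
        dropout_rate=0.3,
        noise="poisson",
    )


@pytest.fixture
def visium_bundle(tmp_path, small_dataset):
    """A synthetic Visium-style bundle on disk."""
    from spatialnmf.io import write_visium_bundle

    out = tmp_path / "bundle"
    write_visium_bundle(out, small_dataset.counts, small_dataset.coords)
    return out
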