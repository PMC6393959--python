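import pytest

from coldatlas import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small six-organ synthetic dataset shared across read-only tests."""
    cfg = SimConfig(n_genes=600, seed=11)
    counts, design, lengths, annotations, truth = generate_dataset(cfg)
    return cfg, counts, design, lengths, annotations, truth
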