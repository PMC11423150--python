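"""Shared lightweight fixtures: tiny models and small synthetic worlds."""

import numpy as np
import pytest

from nldnn.model import ModelConfig, build_nldnn
from nldnn.synthetic import SyntheticSpec, make_genome


def tiny_model_config(seed: int = 0, **overrides) -> ModelConfig:
    kwargs = dict(
        conv_channels=(8, 8, 8),
        conv_kernels=(7, 3, 3),
        pool_sizes=(5, 2, 2),
        dropout=0.0,
        gru_hidden=4,
        rrb_channels=8,
        sppm_scales=(1, 2),
        seed=seed,
    )
    kwargs.update(overrides)
    return ModelConfig(**kwargs)


@pytest.fixture(scope="session")
def tiny_model():
    """An untrained miniature network for contract/oracle tests."""
    model = build_nldnn(tiny_model_config(seed=0))
    model.eval()
    return model


@pytest.fixture(scope="session")
def small_world():
    """A small single-species world: genome, truth, and its spec."""
    spec = SyntheticSpec(
        genome_length_per_chrom=30_000,
        chrom_names=("chr1", "chr2"),
        n_peaks=8,
        seed=3,
    )
    genome, truth = make_genome(spec, "A")
    return spec, genome, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
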