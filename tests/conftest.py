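import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_fixture():
    """A small synthetic dataset shared across tests (not the benchmark
    conditions: short chromosomes keep unit tests fast)."""
    from epimodal.synthetic import SyntheticConfig, generate_fixture

    cfg = SyntheticConfig(n_chroms=3, chrom_length=8000, window_length=1000,
                          resolution=2000, n_events=6, n_variants=10, seed=7)
    return generate_fixture(cfg)


@pytest.fixture(scope="session")
def tiny_model(small_fixture):
    """An untrained miniature multimodal model bound to the small fixture."""
    from epimodal.encoders import (
        MultimodalModel,
        SequenceEncoderConfig,
        StructureEncoderConfig,
        build_sequence_encoder,
        build_structure_encoder,
    )

    seq = build_sequence_encoder(
        SequenceEncoderConfig.miniature("cnn", window_length=1000, embed_dim=16),
        seed=0,
    )
    struct = build_structure_encoder(
        StructureEncoderConfig.miniature("mlp", struct_embed_dim=8),
        small_fixture.matrix, seed=1,
    )
    return MultimodalModel(seq, struct, n_events=6, rng=np.random.default_rng(2))
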