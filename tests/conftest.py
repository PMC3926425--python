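import numpy as np
import pytest

from textsnake import pipeline, synthetic


@pytest.fixture(scope="session")
def phantom_config():
    return pipeline.PipelineConfig.for_phantoms()


@pytest.fixture(scope="session")
def phantom_training():
    """Six annotated phantom images covering all four object classes."""
    return [
        synthetic.generate_phantom(synthetic.biopsy_phantom_spec(100 + k))
        for k in range(6)
    ]


@pytest.fixture(scope="session")
def phantom_model(phantom_training, phantom_config):
    return pipeline.train_model(phantom_training, phantom_config)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
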