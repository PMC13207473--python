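import numpy as np
import pytest

import octsaliency as oc


@pytest.fixture(scope="session")
def tiny_model():
    return oc.tiny_backbone(seed=0)


@pytest.fixture(scope="session")
def synth_batch():
    """Twelve model-ready synthetic scans, two per class."""
    return oc.make_dataset(2, side=32, seed=11)


@pytest.fixture(scope="session")
def synth_input(synth_batch):
    x, _ = synth_batch
    return x[0]
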