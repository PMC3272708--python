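import pytest

from snfba import ToyModelConfig, generate_toy_snf_model


@pytest.fixture(scope="session")
def toy():
    """Default toy bacteroid model + ground truth (malate medium, 8 branches)."""
    return generate_toy_snf_model(ToyModelConfig(seed=0))


@pytest.fixture()
def toy_model(toy):
    model, _ = toy
    return model.copy()


@pytest.fixture(scope="session")
def toy_ground(toy):
    return toy[1]
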