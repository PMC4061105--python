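import pytest

from hmmdissect import fixtures as fx


@pytest.fixture
def spec():
    return fx.FixtureSpec(seed=1, model_length=8, n_sequences=8)


@pytest.fixture
def model_and_text(spec):
    return fx.make_model(spec)


@pytest.fixture
def model(model_and_text):
    return model_and_text[0]


@pytest.fixture
def path(spec, model):
    return fx.make_path(spec, model)
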