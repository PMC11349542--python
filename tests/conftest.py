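import pytest

from pembrocea import evaluate_model, load_config


@pytest.fixture(scope="session")
def china():
    return load_config("china")


@pytest.fixture(scope="session")
def us():
    return load_config("us")


@pytest.fixture(scope="session")
def china_result(china):
    return evaluate_model(china)


@pytest.fixture(scope="session")
def us_result(us):
    return evaluate_model(us)
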