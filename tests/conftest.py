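import pytest

from anthoqsar import synthetic_data


@pytest.fixture(scope="session")
def bundle():
    return synthetic_data.fixtures()


@pytest.fixture(scope="session")
def registry(bundle):
    return bundle.registry()


@pytest.fixture(scope="session")
def pm6_pairs(bundle):
    return bundle.prediction_pairs("PM6")


@pytest.fixture(scope="session")
def pm7_pairs(bundle):
    return bundle.prediction_pairs("PM7")
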