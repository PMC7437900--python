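import pytest

from barcodepci import build_distance_matrix, make_misannotation_fixture


@pytest.fixture(scope="session")
def fixture_dataset():
    return make_misannotation_fixture()


@pytest.fixture(scope="session")
def fixture_matrix(fixture_dataset):
    return build_distance_matrix(fixture_dataset)


@pytest.fixture(scope="session")
def corrected_dataset(fixture_dataset):
    return fixture_dataset.relabel("x", "S")


@pytest.fixture(scope="session")
def corrected_matrix(corrected_dataset):
    return build_distance_matrix(corrected_dataset)
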