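import pytest

from cfirf import (
    load_taxonomy,
    read_mapping_records,
    reconstruct_participants,
    score_study,
    table2_fixture,
)
from cfirf.synthesis import bundled_mapping_path


@pytest.fixture(scope="session")
def study_constraint():
    return table2_fixture()


@pytest.fixture(scope="session")
def study_dataset(study_constraint):
    return reconstruct_participants(study_constraint, seed=11)


@pytest.fixture(scope="session")
def study_results(study_dataset):
    return score_study(study_dataset)


@pytest.fixture(scope="session")
def taxonomy():
    return load_taxonomy()


@pytest.fixture(scope="session")
def mapping_records(taxonomy):
    return read_mapping_records(bundled_mapping_path(), taxonomy)
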