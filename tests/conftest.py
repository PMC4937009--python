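import pytest

from aexapr.infer_params import infer_all_tables
from aexapr.reference_data import load_reference_table


@pytest.fixture(scope="session")
def records():
    return load_reference_table()


@pytest.fixture(scope="session")
def apr(records):
    return [r for r in records if r.group == "APR"]


@pytest.fixture(scope="session")
def tregitopes(records):
    return [r for r in records if r.group == "TREGITOPE"]


@pytest.fixture(scope="session")
def controls(records):
    return [r for r in records if r.group == "CONTROL"]


@pytest.fixture(scope="session")
def inferred(records):
    """Per-descriptor inference results fitted on the full reference table."""
    return infer_all_tables(records)


@pytest.fixture(scope="session")
def inferred_tables(inferred):
    return {desc: res.table for desc, res in inferred.items()}
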