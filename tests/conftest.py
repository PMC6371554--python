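import pytest

from packfit import audit, paper_fixture


@pytest.fixture(scope="session")
def fixture_data():
    """(packages, regimens, reimbursement table) from the packaged dataset."""
    return paper_fixture()


@pytest.fixture(scope="session")
def fixture_rows(fixture_data):
    packages, regimens, _table = fixture_data
    return audit(packages, regimens)
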