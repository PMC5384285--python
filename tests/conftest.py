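import pandas as pd
import pytest

from restage.assay_io import load_paper_fixture


@pytest.fixture(scope="session")
def table1():
    return load_paper_fixture("table1")


@pytest.fixture(scope="session")
def table2():
    return load_paper_fixture("table2")


@pytest.fixture(scope="session")
def table3():
    return load_paper_fixture("table3")


@pytest.fixture
def write_csv(tmp_path):
    """Write a list of row-dicts to a temporary CSV and return its path."""

    def _write(rows, name="table.csv", columns=None):
        path = tmp_path / name
        pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
        return path

    return _write
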