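import pytest

from cellgate.fixtures import build_fixture_catalog, load_fixture_indexes


@pytest.fixture(scope="session")
def catalog_dir(tmp_path_factory):
    path = tmp_path_factory.mktemp("catalogs")
    build_fixture_catalog(path)
    return path


@pytest.fixture(scope="session")
def indexes(catalog_dir):
    return load_fixture_indexes(catalog_dir)


@pytest.fixture(scope="session")
def marker_index(indexes):
    return indexes[0]


@pytest.fixture(scope="session")
def cell_index(indexes):
    return indexes[1]
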