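import pytest

from spongeprey import reference, synthetic_data
from spongeprey.prey_data import PreyObservation


@pytest.fixture(scope="session")
def published_universe():
    return reference.published_universe()


@pytest.fixture(scope="session")
def published_pooled():
    return reference.published_pooled_counts()


@pytest.fixture(scope="session")
def published_observations():
    return reference.published_observations()


@pytest.fixture(scope="session")
def default_catalog():
    return synthetic_data.make_default_catalog()


@pytest.fixture()
def published_fixture_dir(tmp_path, published_observations, published_universe):
    """The published pooled counts expanded to observation + annotation files."""
    paths = synthetic_data.write_fixture(
        published_observations, published_universe, tmp_path / "published"
    )
    return paths


def make_obs(
    family="Pinguipedidae",
    mode="sponging",
    site_kind="transect",
    transect_id="T1",
    replicate=1,
    length_cm=12.0,
    identified=True,
    species=None,
    dive_id=None,
):
    return PreyObservation(
        dive_id=dive_id or f"{transect_id or 'V1'}-{mode}-r{replicate}",
        site_kind=site_kind,
        transect_id=transect_id,
        replicate=replicate,
        mode=mode,
        family=family,
        species=species,
        length_cm=length_cm,
        identified=identified,
    )
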