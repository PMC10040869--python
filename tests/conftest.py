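import pytest

from hitfinder import FixtureSpec, generate_fixture


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """A scaled-down synthetic world shared by the faster integration tests."""
    spec = FixtureSpec(
        seed=11,
        n_actives_per_target=12,
        n_inactives_per_target=36,
        library_size=300,
    )
    paths = generate_fixture(spec, tmp_path_factory.mktemp("small_fixture"))
    return spec, paths
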