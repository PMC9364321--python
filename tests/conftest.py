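import pytest

from dockbench import fixtures as fx


@pytest.fixture(scope="session")
def small_library() -> list[str]:
    """300 synthetic druglike molecules, deterministic."""
    return fx.generate_library(fx.SyntheticLibrarySpec(n_molecules=300, seed=0))


@pytest.fixture(scope="session")
def library_2000() -> list[str]:
    """Larger library for correlation and optimizer studies."""
    return fx.generate_library(fx.SyntheticLibrarySpec(n_molecules=2000, seed=0))


@pytest.fixture(scope="session")
def mini_target():
    return fx.make_mini_target_fixture()
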