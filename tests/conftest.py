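import pytest

from critsoil import default_traits, load_soil_table


@pytest.fixture(scope="session")
def table():
    return load_soil_table()


@pytest.fixture(scope="session")
def traits():
    return default_traits()


@pytest.fixture(scope="session")
def fast_kwargs():
    """Reduced grid resolution for threshold calls inside loops."""
    return {"n_psi": 200, "n_trajectory": 800}
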