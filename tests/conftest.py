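import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def pocket_pair():
    """The shape-complementary pocket/plug fixture pair."""
    from fftdock.structures import make_complementary_pair

    return make_complementary_pair()


@pytest.fixture(scope="session")
def shape_only_config():
    """Scaled-down shape-only run config (90° step, 24 rotations, 1 Å pitch)."""
    from fftdock.config import RunConfig

    return RunConfig(
        pitch=1.0,
        margin=0,
        rotation_step=90.0,
        n_theta_cap=None,
        w_elec=0.0,
        w_desolv=0.0,
        top_k=30,
    )


@pytest.fixture(scope="session")
def pocket_result(pocket_pair, shape_only_config):
    """One shared docking run of the pocket/plug pair."""
    from fftdock.fft_search import dock

    receptor, ligand = pocket_pair
    return dock(receptor, ligand, shape_only_config)
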