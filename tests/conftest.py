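import numpy as np
import pytest
from hypothesis import settings

import dbtrecon as d

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_geom():
    return d.default_geometry("small-test")


@pytest.fixture(scope="session")
def dense_m(small_geom):
    return d.build_dense_matrix(small_geom)


@pytest.fixture(scope="session")
def consistent_problem(small_geom):
    """Noiseless data from a known nonnegative volume (exact fit exists)."""
    rng = np.random.default_rng(0)
    x_true = d.Volume(rng.uniform(0.02, 0.1, small_geom.grid_shape), small_geom)
    b = d.forward_project(x_true)
    return x_true, b


@pytest.fixture(scope="session")
def textured_fixture(small_geom):
    """Seeded noisy projections of a two-tissue textured slab."""
    spec = d.PhantomSpec(background=d.BackgroundSpec(seed=11, texture_scale_mm=0.4))
    truth = d.generate_phantom(spec, small_geom)
    b, noise_norm = d.simulate_projections(
        truth, small_geom, d.SimulationSpec(photon_count_p0=1e5, poisson=True, seed=42)
    )
    return truth, b, noise_norm


@pytest.fixture(scope="session")
def piecewise_constant_fixture(small_geom):
    """Low-dose noisy projections of a genuinely piecewise-constant slab."""
    spec = d.PhantomSpec(
        background=d.BackgroundSpec(mu_adipose=0.05, mu_gland=0.05, seed=1),
        masses=(d.MassSpec(center_mm=(0.0, 0.0, 2.0), diameter_mm=1.2),),
        mc_clusters=(
            d.MCClusterSpec(
                center_mm=(0.6, -0.6, 2.5), n_specks=2, speck_diameter_um=230,
                spread_mm=0.2, seed=3,
            ),
        ),
    )
    truth = d.generate_phantom(spec, small_geom)
    b, noise_norm = d.simulate_projections(
        truth, small_geom, d.SimulationSpec(photon_count_p0=5e3, poisson=True, seed=42)
    )
    return truth, b, noise_norm


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
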