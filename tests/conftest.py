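import numpy as np
import pytest

import rvenet as rv


@pytest.fixture(scope="session")
def tiny_fixture():
    """Tiny deterministic configuration + network (5^3 mesh, 20 fibers)."""
    return rv.make_fixture("tiny")


@pytest.fixture(scope="session")
def tiny_beam(tiny_fixture):
    config, network = tiny_fixture
    return rv.discretize_fibers(network, config.fiber.element_length)


@pytest.fixture(scope="session")
def tiny_model(tiny_fixture, tiny_beam):
    config, _ = tiny_fixture
    return rv.ScaffoldModel(
        config.rve_geometry(),
        tiny_beam,
        config.beam_section(),
        config.fiber_material(),
        config.matrix.bulk_ratio,
    )


@pytest.fixture(scope="session")
def tiny_solution(tiny_model):
    """Tiny coupled RVE solved at the baseline matrix shear modulus (11 Pa)."""
    return tiny_model.solve(11.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
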