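import numpy as np
import pytest

import seegplan as sp


@pytest.fixture(scope="session")
def phantom1() -> sp.Phantom:
    """One shared default phantom; treated as read-only by all tests."""
    return sp.make_phantom(1)


@pytest.fixture(scope="session")
def table2():
    """Fixture cohorts plus the priors built with the fixture's own settings."""
    fx = sp.make_table2_fixture(1)
    priors = sp.build_priors(fx.training, fx.affines, **fx.build_params)
    return fx, priors


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_vessel_tree(rng: np.random.Generator, n_segments: int, extent: float = 60.0) -> sp.VesselTree:
    """Small random vessel scene for risk-score property tests."""
    segs = []
    for _ in range(n_segments):
        p0 = rng.uniform(-extent, extent, 3)
        p1 = p0 + rng.uniform(5.0, 25.0) * _unit(rng.standard_normal(3))
        segs.append((sp.Segment3(sp.Point3.from_array(p0), sp.Point3.from_array(p1)),
                     float(rng.uniform(0.5, 2.0))))
    return sp.VesselTree(segs)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)
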