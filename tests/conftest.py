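import numpy as np
import pytest

from betamag.transport import HitCloud, TransportConfig, run_simulation


def make_cloud(points, dE=None, config=None):
    """HitCloud from an (n, 3) array of positions (unit deposits by default)."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    n = pts.shape[0]
    if dE is None:
        dE = np.ones(n)
    return HitCloud(pts[:, 0], pts[:, 1], pts[:, 2], dE,
                    np.arange(n, dtype=np.int32),
                    initial_energy=np.asarray(dE, dtype=float),
                    escaped_energy=np.zeros(n),
                    final_position=pts, config=config)


@pytest.fixture(scope="session")
def small_run_0T():
    """2 MeV, B = 0, 2000 histories — shared across cheap transport checks."""
    cfg = TransportConfig(source_energy=2.0, n_particles=2000, B_magnitude=0.0,
                          seed=11)
    return run_simulation(cfg)


@pytest.fixture(scope="session")
def small_run_3T():
    cfg = TransportConfig(source_energy=2.0, n_particles=2000, B_magnitude=3.0,
                          seed=11)
    return run_simulation(cfg)
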