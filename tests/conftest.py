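import numpy as np
import pytest

import spatialcode as sc


@pytest.fixture(scope="session")
def traj40():
    """Two-minute random walk in the 40 cm arena."""
    cfg = sc.SyntheticConfig(seed=11, arena_side=40.0, duration=120.0)
    return sc.synthetic.gen_trajectory(cfg)


@pytest.fixture(scope="session")
def small_mec_session():
    """Short MEC-style session with a few units of each class."""
    cfg = sc.synthetic.mec_config(
        seed=5, duration=600.0,
        cell_counts={"grid": 3, "interneuron": 3, "border": 3,
                     "aperiodic_spatial": 3})
    return sc.gen_session(cfg)


@pytest.fixture(scope="session")
def place_session():
    """CA1-style session long enough for decoder unit tests
    (reduced encoding/decoding spans)."""
    cfg = sc.SyntheticConfig(seed=21, arena_side=40.0, duration=180.0,
                             cell_counts={"place": 25})
    return sc.gen_session(cfg)


def serpentine_trajectory(extent=40.0, bin_size=2.0, dwell_per_bin=0.5,
                          sample_rate=30.0):
    """Raster scan visiting every bin center for an equal time."""
    n = int(extent / bin_size)
    xs, ys = [], []
    frames = int(dwell_per_bin * sample_rate)
    for i in range(n):
        cols = range(n) if i % 2 == 0 else range(n - 1, -1, -1)
        for j in cols:
            xs.extend([(j + 0.5) * bin_size] * frames)
            ys.extend([(i + 0.5) * bin_size] * frames)
    t = np.arange(len(xs)) / sample_rate
    return sc.Trajectory(t=t, x=np.array(xs), y=np.array(ys),
                         sample_rate=sample_rate)


@pytest.fixture(scope="session")
def sweep_traj():
    return serpentine_trajectory()
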