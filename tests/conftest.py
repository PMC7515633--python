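import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import epibolykit as ek

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def scattered_points(rng, n=50, min_sep=8.0, lo=10.0, hi=110.0):
    """Random points in a box with a minimum pairwise separation."""
    pts = []
    while len(pts) < n:
        p = rng.uniform(lo, hi, size=3)
        if all(np.linalg.norm(p - q) >= min_sep for q in pts):
            pts.append(p)
    return np.array(pts)


def nucleus_frame(points, intensity=1000.0, frame=0):
    points = np.atleast_2d(points)
    inten = np.broadcast_to(np.asarray(intensity, dtype=float), len(points))
    return pd.DataFrame(
        {
            "frame": frame,
            "nucleus_id": np.arange(len(points)),
            "x_um": points[:, 0],
            "y_um": points[:, 1],
            "z_um": points[:, 2],
            "intensity": inten,
        }
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def control_truth():
    """A well-separated control simulation without divisions (session-wide)."""
    cfg = ek.SimulationConfig(
        n_initial_nuclei=250,
        division_interval=None,
        n_frames=40,
        motion_noise_sd=0.3,
        epiboly_speed=0.3,
        min_separation=6.0,
        rng_seed=7,
    )
    return ek.simulate_epiboly(cfg)
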