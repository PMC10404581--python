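import numpy as np
import pytest

import srmotion as sm


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def center_out():
    """Default centre-out reach: v0=1.4 m/s, T=0.07 s, dt=0.01 s."""
    return sm.gen_center_out()


@pytest.fixture
def gentle_reach():
    """Longer, slower reach with pursuit-scale kinematics."""
    return sm.gen_center_out(profile=sm.BellProfile(v0=0.2, T=0.35), dt=0.01)


def make_targets(rng, n, box=0.12, min_step=0.06):
    """Random pursuit way-points in a (2*box)-metre workspace."""
    pts = [np.zeros(2)]
    while len(pts) < n:
        cand = rng.uniform(-box, box, 2)
        if np.linalg.norm(cand - pts[-1]) > min_step:
            pts.append(cand)
    return [tuple(p) for p in pts]


@pytest.fixture
def pursuit():
    """Three-segment pursuit trajectory with ground-truth labels."""
    spec = sm.PursuitSpec(targets=[(0, 0), (0.1, 0), (0.1, 0.1), (0, 0.1)],
                          dt=0.01, seed=0)
    return sm.gen_random_pursuit(spec)
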