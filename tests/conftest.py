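import numpy as np
import pytest
import trimesh

import vnsim


@pytest.fixture(scope="session")
def anatomy():
    """Default synthetic anatomy (26 mm wall + forbidden organs), seed 7."""
    return vnsim.generate_anatomy(seed=7)


@pytest.fixture(scope="session")
def wall_only():
    """Anatomy with the default wall stack and no organs."""
    return vnsim.generate_anatomy(organ_layout="none", seed=7)


@pytest.fixture
def ideal_profile():
    """Noiseless perfect trainee: exact 45 degrees, no tremor, no overshoot."""
    return vnsim.TraineeProfile(
        angle_bias=0.0,
        angle_sd=0.0,
        speed=1.0,
        speed_jitter_sd=0.0,
        overshoot_prob=0.0,
        lateral_tremor_sd=0.0,
        learning_gain=0.8,
    )


@pytest.fixture
def tetrahedron():
    """Unit tetrahedron mesh (4 vertices, 4 faces), watertight."""
    v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return trimesh.Trimesh(vertices=v, faces=f, process=False)


def ideal_trajectory(anatomy, **kw):
    prof = vnsim.TraineeProfile(
        angle_bias=kw.pop("angle_bias", 0.0),
        angle_sd=0.0,
        speed=kw.pop("speed", 1.0),
        speed_jitter_sd=0.0,
        overshoot_prob=0.0,
        lateral_tremor_sd=0.0,
        learning_gain=kw.pop("learning_gain", 0.8),
    )
    return vnsim.generate_attempt(prof, anatomy, kw.pop("attempt", "A"), seed=kw.pop("seed", 1))
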