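import numpy as np
import pytest

from scapmob import build_default
from scapmob.mobilizers import PinMobilizer
from scapmob.multibody import Body, Joint, ModelTree
from scapmob.noise_study import run_noise_experiment, synthesize_motion


@pytest.fixture(scope="session")
def model():
    """The default four-segment shoulder model."""
    return build_default()


@pytest.fixture(scope="session")
def flexion(model):
    """Reference flexion motion and its noise-free marker trajectory."""
    return synthesize_motion(model, "flexion", duration=2.0, rate=120.0)


@pytest.fixture(scope="session")
def noise_table(model, flexion):
    """The scaled-down noise experiment: flexion, 5-40 mm step 5, 20 trials.

    Session-scoped because it is by far the most expensive computation in
    the suite; several tests interrogate different aspects of the same
    table.
    """
    motion, traj = flexion
    return run_noise_experiment(
        model, motion, traj, levels_mm=list(range(5, 41, 5)), trials=20, seed=0
    )


@pytest.fixture(scope="session")
def passive_swing(model, flexion):
    """Conservative 2 s passive swing from peak flexion at accuracy 1e-4."""
    from scapmob.dynamics_analysis import PassiveForceSet, simulate_passive_swing

    motion, _ = flexion
    q0 = motion.coordinates[len(motion.times) // 2]
    passive = PassiveForceSet.for_model(model)
    return simulate_passive_swing(
        model, q0, duration=2.0, accuracy=1e-4, passive=passive
    )


def make_pendulum(mass=1.7, com_dist=0.23, inertia_com=0.02, gravity=-9.81):
    """Single pin pendulum about Z with known closed-form dynamics."""
    ground = Body("ground")
    m = ModelTree(ground, gravity=(0.0, gravity, 0.0))
    rod = Body(
        "rod",
        mass=mass,
        inertia=np.diag([inertia_com + 1e-3, inertia_com + 1e-3, inertia_com]),
        com=(0.0, -com_dist, 0.0),
    )
    m.add_body(rod, Joint("pin", "ground", "rod", PinMobilizer((0, 0, 1))))
    return m


@pytest.fixture
def pendulum():
    return make_pendulum()
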