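"""Shared fixtures: surrogate trajectories with known ground truth.

Session-scoped so the Langevin integrations (and the numba JIT warm-up they
trigger) are paid once.
"""

import numpy as np
import pytest

from spikescape import LangevinSpec, simulate_langevin, analytic_references


@pytest.fixture(scope="session")
def ou_spec():
    # pure Ornstein-Uhlenbeck: rotational family with omega = 0
    return LangevinSpec(family="linear_rotational", k=1.0, omega=0.0,
                        D=4.0, dt=0.005, duration=4000.0, seed=11,
                        record_stride=4)


@pytest.fixture(scope="session")
def ou_traj(ou_spec):
    return simulate_langevin(ou_spec)


@pytest.fixture(scope="session")
def rot_spec():
    return LangevinSpec(family="linear_rotational", k=1.0, omega=1.5,
                        D=4.0, dt=0.005, duration=4000.0, seed=12,
                        record_stride=4)


@pytest.fixture(scope="session")
def rot_traj(rot_spec):
    return simulate_langevin(rot_spec)


@pytest.fixture(scope="session")
def dw_spec():
    # barrier 2 D-units: transitions every few hundred seconds
    return LangevinSpec(family="double_well", barrier_height=2.0,
                        well_half_separation=10.0, k_y=1.0, D=1.0,
                        dt=0.01, duration=30_000.0, seed=13,
                        record_stride=5)


@pytest.fixture(scope="session")
def dw_traj(dw_spec):
    return simulate_langevin(dw_spec)


@pytest.fixture(scope="session")
def tw_spec():
    return LangevinSpec(family="triple_well", mixture_sigma=3.0, D=9.0,
                        dt=0.005, duration=6000.0, seed=14, record_stride=4)


@pytest.fixture(scope="session")
def tw_traj(tw_spec):
    return simulate_langevin(tw_spec)


@pytest.fixture(scope="session")
def refs():
    return analytic_references
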