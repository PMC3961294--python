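"""Shared fixtures: nominal parameters and a few reusable simulations.

Long simulations are session-scoped so their cost is paid once.
Synthetic trajectories (hand-built label patterns) are provided for the
hypnogram tests so labeling semantics can be checked exactly.
"""

import numpy as np
import pytest

import sleepswitch as sw
from sleepswitch.integrate import Trajectory
from sleepswitch.params import SECONDS_PER_DAY


@pytest.fixture(scope="session")
def nominal():
    return sw.ModelParameters.nominal()


@pytest.fixture(scope="session")
def det_traj(nominal):
    """Noise-free 8-day nominal run (3-day equilibration + 5 retained)."""
    init = sw.initial_state(nominal)
    return sw.integrate_deterministic(nominal, init, (0.0, 8 * SECONDS_PER_DAY))


@pytest.fixture(scope="session")
def det_retained(det_traj):
    return det_traj.window(3 * SECONDS_PER_DAY, 8 * SECONDS_PER_DAY + 1.0)


@pytest.fixture(scope="session")
def em_result(nominal):
    """Noisy 5-day nominal scenario (2 retained days)."""
    spec = sw.ScenarioSpec(duration_days=2, equilibration_days=3, seed=11)
    return sw.run_scenario(spec)


@pytest.fixture(scope="session")
def knockout_result():
    """Orexin-removed (nu_mo = 0) noisy scenario, 2 retained days."""
    spec = sw.ScenarioSpec(overrides={"nu_mo": 0.0}, duration_days=2,
                          equilibration_days=3, seed=12)
    return sw.run_scenario(spec)


def make_label_trajectory(pattern, step=1.0, params=None, amplitude=5.0):
    """Synthetic trajectory whose wake/sleep labels follow ``pattern``.

    ``pattern`` is a list of (duration_s, is_wake); V_m - V_v = +-amplitude
    encodes the target label, other state entries are neutral.
    """
    params = params or sw.ModelParameters.nominal()
    total = sum(d for d, _ in pattern)
    n = int(round(total / step))
    times = np.arange(n) * step
    wake = np.zeros(n, dtype=bool)
    t0 = 0.0
    for dur, is_wake in pattern:
        i0, i1 = int(round(t0 / step)), int(round((t0 + dur) / step))
        wake[i0:i1] = is_wake
        t0 += dur
    states = np.zeros((n, 4))
    states[:, 1] = np.where(wake, amplitude, -amplitude)   # V_m
    states[:, 0] = -states[:, 1]                           # V_v
    states[:, 3] = 1.0                                     # H
    return Trajectory(times=times, states=states, params=params,
                      kind="synthetic")


@pytest.fixture
def label_traj_factory():
    return make_label_trajectory
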