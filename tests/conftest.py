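import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from latticeshed import SimParams, run_simulation

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


# Desk-scale study conditions: the published parameter set (b=0.7, s=0.1,
# mu=1e-3, d1=0.1) with the lattice halved linearly — detection at radius 45
# instead of 90 and termination at 15,000 instead of 60,000 voxels, with the
# sanctuary radii halved to match (10 / 30 voxels).
DD_PARAMS = SimParams(
    b=0.7, s=0.1, mu=1e-3, d1=0.1, d2=0.9,
    R=10, detection_radius=45, max_voxels=15_000,
)
DI_PARAMS = dataclasses.replace(DD_PARAMS, d2=0.69, R=30)


@pytest.fixture()
def rng():
    """Fresh deterministic generator per test (no cross-test coupling)."""
    return np.random.default_rng(20240844)


def _surviving_runs(base, n, record_every):
    """First n replicates that reach the final size (runs are conditioned on
    non-extinction: a founder lineage dies outright in ~15% of attempts)."""
    runs = []
    seed = 0
    while len(runs) < n and seed < 20 * n:
        seed += 1
        traj = run_simulation(
            dataclasses.replace(base, seed=seed),
            record_every=record_every,
            max_sweeps=60_000,
        )
        if traj.terminal == "max_size":
            runs.append(traj)
    return runs


@pytest.fixture(scope="session")
def dd_runs():
    """Ten replicates of the scaled proliferative driver-dependent scenario."""
    return _surviving_runs(DD_PARAMS, 10, record_every=5.0)


@pytest.fixture(scope="session")
def di_runs():
    """Five replicates of the scaled driver-independent, large-sanctuary scenario."""
    return _surviving_runs(DI_PARAMS, 5, record_every=2.0)
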