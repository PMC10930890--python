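import dataclasses

import numpy as np
import pytest
from scipy.stats import ks_2samp

from latticeshed import (
    CloneLedger,
    LatticeState,
    SimParams,
    birth_probability,
    check_detection,
    death_rate_of,
    detection_threshold,
    disc_voxel_count,
    draw_driver_count,
    make_fixture,
    moore_neighbors,
    run_simulation,
    step,
)
from latticeshed.fixtures import FixtureRegion


class ScriptedRNG:
    """Deterministic stand-in for a Generator with pre-scripted draws."""

    def __init__(self, integers=(), randoms=(), poissons=()):
        self._i = iter(integers)
        self._r = iter(randoms)
        self._p = iter(poissons)

    def integers(self, n):
        return next(self._i) % n

    def random(self):
        return next(self._r)

    def poisson(self, lam):
        return next(self._p)


# ---------------------------------------------------------------- neighbors
def test_moore_neighbors_of_interior_point():
    nbrs = moore_neighbors((5, 5), (11, 11))
    assert len(nbrs) == 8
    assert set(nbrs) == {
        (4, 4), (4, 5), (4, 6), (5, 4), (5, 6), (6, 4), (6, 5), (6, 6)
    }


@pytest.mark.parametrize("pos", [(0, 0), (0, 5), (10, 10), (5, 0), (11, 5)])
def test_moore_neighbors_boundary_is_an_error(pos):
    with pytest.raises(IndexError, match="grid too small"):
        moore_neighbors(pos, (11, 11))


def test_moore_neighbors_always_eight_for_interior():
    for pos in [(1, 1), (3, 7), (9, 9)]:
        assert len(moore_neighbors(pos, (11, 11))) == 8


# ------------------------------------------------------------------- rates
@pytest.mark.parametrize(
    "b, s, n, expected",
    [(0.7, 0.1, 0, 0.7), (0.7, 0.1, 2, 0.847), (0.7, 0.1, 4, 1.0)],
)
def test_birth_probability(b, s, n, expected):
    assert birth_probability(b, s, n) == pytest.approx(expected)


def test_death_rate_core_edge_and_predetection():
    params = SimParams(d1=0.1, d2=0.9, R=20, detection_radius=60)
    state = LatticeState.initial(80)
    cy, cx = state.center
    state.detected = True
    assert death_rate_of((cy + 10, cx), 0, state, params) == pytest.approx(0.1)
    assert death_rate_of((cy + 30, cx), 0, state, params) == pytest.approx(0.9)
    # distance exactly R belongs to the core
    assert death_rate_of((cy + 20, cx), 0, state, params) == pytest.approx(0.1)
    state.detected = False
    assert death_rate_of((cy + 30, cx), 0, state, params) == pytest.approx(0.1)


def test_death_rate_selection_variant_compounds_per_driver():
    params = SimParams(d1=0.1, d2=0.9, s=0.1, selection_variant="death")
    state = LatticeState.initial(100)
    assert death_rate_of(state.center, 2, state, params) == pytest.approx(0.081)


def test_regime_classification():
    assert SimParams(d1=0.1, b=0.7, d2=0.9).regime == "driver-dependent"
    assert SimParams(d1=0.1, b=0.7, d2=0.69).regime == "driver-independent"
    assert SimParams(d1=0.1, b=0.1, d2=0.1).regime == "other"


# --------------------------------------------------------------- mutations
def test_driver_count_zero_rate_is_always_zero(rng):
    assert all(draw_driver_count(0.0, rng) == 0 for _ in range(100))


def test_driver_count_mean_matches_rate(rng):
    mu = 1e-3
    n = 1_000_000
    draws = rng.poisson(mu, size=n)  # vectorized equivalent of the op
    se = np.sqrt(mu / n)
    assert abs(draws.mean() - mu) < 3 * se
    assert draw_driver_count(mu, rng) in (0, 1, 2)


def test_mutation_ids_unique_across_a_run(dd_runs):
    ledger = dd_runs[0].ledger
    seen = []
    for clone in ledger.clones():
        seen.extend(clone.new_driver_ids)
    assert len(seen) == len(set(seen)) == ledger.n_mutations


# --------------------------------------------------------------- detection
def test_detection_threshold_is_disc_area():
    params = SimParams(detection_radius=90)
    assert detection_threshold(params) == 25_447
    # integer-lattice disc count agrees with the area formula to <0.5%
    assert abs(disc_voxel_count(90) - 25_447) / 25_447 < 5e-3


def test_detection_latch():
    params = SimParams(detection_radius=90)
    state = LatticeState.initial(5)
    state.occupied_count = 100
    assert not check_detection(state, params)
    state.occupied_count = 25_447
    assert check_detection(state, params)
    state.occupied_count = 10  # shrinkage does not undo detection
    assert check_detection(state, params)


# -------------------------------------------------------------- step (ref)
def _block_state(hole=None):
    state = LatticeState.initial(3)
    state.grid[:] = 0
    state.grid[2:5, 2:5] = 1
    if hole is not None:
        state.grid[hole] = 0
    state.occupied_count = int(np.count_nonzero(state.grid))
    return state


def test_step_surrounded_proliferative_cell_cannot_divide_but_dies():
    state = _block_state()
    params = SimParams(b=1.0, d1=1.0, d2=1.0, R=1, detection_radius=3)
    # index 4 in row-major order is the center cell (3,3), fully surrounded
    rec = step(state, CloneLedger(), params, ScriptedRNG(integers=(4,), randoms=(0.0,)))
    assert rec.position == (3, 3) and not rec.divided and rec.died
    assert state.grid[3, 3] == 0 and state.occupied_count == 8


def test_step_surrounded_quiescent_cell_is_immortal():
    state = _block_state()
    params = SimParams(
        b=1.0, d1=1.0, d2=1.0, R=1, detection_radius=3, growth_variant="quiescent"
    )
    rec = step(state, CloneLedger(), params, ScriptedRNG(integers=(4,)))
    assert not rec.divided and not rec.died
    assert state.occupied_count == 9


def test_step_certain_division_with_single_empty_neighbor():
    state = _block_state(hole=(2, 2))
    params = SimParams(b=1.0, d1=0.0, d2=0.0, R=1, detection_radius=3)
    rng = ScriptedRNG(integers=(3, 0), randoms=(0.0, 0.9), poissons=(0,))
    rec = step(state, CloneLedger(), params, rng)  # picks (3,3); empty nbr (2,2)
    assert rec.divided and rec.daughter_position == (2, 2) and not rec.died
    assert state.occupied_count == 9


def test_step_bookkeeping_matches_grid_scan(rng):
    state = LatticeState.initial(25)
    ledger = CloneLedger()
    params = SimParams(b=0.8, d1=0.05, d2=0.3, mu=0.02, R=6, detection_radius=15,
                       max_voxels=2000)
    for i in range(2500):
        if state.occupied_count == 0:
            break
        step(state, ledger, params, rng)
        if i % 250 == 0:
            state.validate()
    state.validate()
    # every nonzero grid entry references a registered clone
    for cid in np.unique(state.grid[state.grid > 0]):
        assert int(cid) in ledger


def test_quiescent_cells_never_die_while_surrounded(rng):
    state, ledger, _ = make_fixture(
        [FixtureRegion(label="A", r_outer=6.0)], detected=False
    )
    params = SimParams(b=0.0, d1=1.0, d2=1.0, R=6, detection_radius=7,
                       growth_variant="quiescent")
    deaths = 0
    for _ in range(600):
        if state.occupied_count == 0:
            break
        before = state.grid.copy()
        rec = step(state, ledger, params, rng)
        if rec.died:
            deaths += 1
            r, c = rec.position
            neighborhood = before[r - 1 : r + 2, c - 1 : c + 2]
            assert (neighborhood == 0).any(), "a surrounded cell was removed"
    assert deaths > 0  # the rim does erode


# --------------------------------------------------------- run_simulation
def test_no_births_means_extinction():
    traj = run_simulation(
        SimParams(b=0.0, d1=0.5, d2=0.5, R=5, detection_radius=10, max_voxels=500, seed=1)
    )
    assert traj.terminal == "extinct"
    assert traj.records[-1].occupied_count == 0


def test_pure_eden_growth_is_monotone_to_max_size():
    traj = run_simulation(
        SimParams(b=1.0, d1=0.0, d2=0.0, mu=0.0, R=5, detection_radius=10,
                  max_voxels=2000, seed=1)
    )
    sizes = [r.occupied_count for r in traj.records]
    assert traj.terminal == "max_size"
    assert all(a <= b for a, b in zip(sizes, sizes[1:]))
    assert sizes[-1] >= 2000


def test_fixed_seed_reproducibility():
    params = SimParams(R=10, detection_radius=30, max_voxels=4000, seed=7)
    a = run_simulation(params, max_sweeps=30_000)
    b = run_simulation(params, max_sweeps=30_000)
    assert a.n_events == b.n_events and a.n_sweeps == b.n_sweeps
    assert np.array_equal(a.final_state.grid, b.final_state.grid)
    for ra, rb in zip(a.records, b.records):
        assert ra.sweep == rb.sweep
        assert np.array_equal(ra.clone_ids, rb.clone_ids)
        assert np.array_equal(ra.core_counts, rb.core_counts)
        assert np.array_equal(ra.edge_counts, rb.edge_counts)


def test_final_census_matches_grid(dd_runs):
    traj = dd_runs[0]
    traj.final_state.validate()
    last = traj.records[-1]
    assert last.core_counts.sum() + last.edge_counts.sum() == traj.final_state.occupied_count
    # grid clone ids agree with the recorded live set
    grid_ids = set(np.unique(traj.final_state.grid[traj.final_state.grid > 0]))
    assert grid_ids == set(int(c) for c in last.clone_ids)


def test_no_net_growth_beyond_detection_without_selection():
    # driver-dependent barrier with s=0: no clone can ever outgrow d2
    params = SimParams(b=0.7, s=0.0, mu=1e-3, d1=0.1, d2=0.9, R=10,
                       detection_radius=25, max_voxels=4000, seed=3)
    traj = run_simulation(params, max_sweeps=400)
    assert traj.terminal == "sweep_cap"
    thr = detection_threshold(params)
    post = [r.occupied_count for r in traj.records if r.detected]
    assert post and max(post) <= 1.2 * thr


def test_clone_dynamics_invariant_to_sanctuary_radius_when_rates_equal():
    # with d1 = d2 the core/edge split has no dynamical effect, so summary
    # statistics across seeds must be statistically indistinguishable in R
    def sweeps_to_finish(R, seed):
        params = SimParams(b=0.7, d1=0.3, d2=0.3, mu=1e-3, R=R,
                           detection_radius=20, max_voxels=2500, seed=seed)
        return run_simulation(params, max_sweeps=30_000).n_sweeps

    small = [sweeps_to_finish(5, s) for s in range(10)]
    large = [sweeps_to_finish(15, 100 + s) for s in range(10)]
    assert ks_2samp(small, large).pvalue > 1e-3


def test_invalid_params_are_rejected():
    with pytest.raises(ValueError):
        SimParams(b=1.5)
    with pytest.raises(ValueError):
        SimParams(R=100, detection_radius=90)
    with pytest.raises(ValueError):
        SimParams(growth_variant="necrotic")
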