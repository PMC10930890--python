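"""Stochastic boundary-driven tumor growth on a 2D lattice.

The model grows a tumor from a single founder voxel on a square lattice with
Moore (8-cell) neighborhoods.  Per event, a uniformly chosen cell attempts
division into an empty neighbor with probability b*(1+s)^n (n = its driver
count) and then dies with its regional death probability.  Before the tumor
reaches the detection size all cells die at rate d1; afterwards cells beyond
the sanctuary radius R die at rate d2, creating a selective barrier at the
tumor edge.  Two growth variants (proliferative / quiescent) and two
selection variants (birth-rate / death-rate) are supported.

Two regimes follow from the rates: "driver-dependent" invasion (d1 < b < d2,
only clones with enough drivers can expand past R) and "driver-independent"
invasion (d1 < d2 < b, all clones can expand, more slowly).

:func:`step` is a readable single-event reference used by the test oracles;
:func:`run_simulation` drives the compiled kernel in :mod:`._kernel` for
full runs and records per-clone region censuses on a sweep cadence (one
sweep = m cell-pick events at population size m).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from . import _kernel
from .clone_ledger import CloneLedger

__all__ = [
    "SimParams",
    "LatticeState",
    "EventRecord",
    "TrajectoryRecord",
    "Trajectory",
    "moore_neighbors",
    "birth_probability",
    "clone_birth_probability",
    "death_rate_of",
    "draw_driver_count",
    "check_detection",
    "detection_threshold",
    "step",
    "run_simulation",
]


@dataclass(frozen=True)
class SimParams:
    """All model knobs for one simulation run.

    Rates are per-event probabilities; R and detection_radius are in voxels.
    """

    b: float = 0.7
    s: float = 0.1
    mu: float = 1e-3
    d1: float = 0.1
    d2: float = 0.9
    R: float = 20.0
    detection_radius: float = 90.0
    max_voxels: int = 60_000
    growth_variant: Literal["proliferative", "quiescent"] = "proliferative"
    selection_variant: Literal["birth", "death"] = "birth"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("b", "d1", "d2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if self.mu < 0 or self.s < 0:
            raise ValueError("mu and s must be non-negative")
        if self.R > self.detection_radius:
            raise ValueError("sanctuary radius R cannot exceed the detection radius")
        if self.max_voxels < 1:
            raise ValueError("max_voxels must be positive")
        if self.growth_variant not in ("proliferative", "quiescent"):
            raise ValueError(f"unknown growth variant {self.growth_variant!r}")
        if self.selection_variant not in ("birth", "death"):
            raise ValueError(f"unknown selection variant {self.selection_variant!r}")

    @property
    def regime(self) -> str:
        """Invasion regime implied by the rates."""
        if self.d1 < self.b < self.d2:
            return "driver-dependent"
        if self.d1 < self.d2 < self.b:
            return "driver-independent"
        return "other"


def detection_threshold(params: SimParams) -> int:
    """Occupied-voxel count at which the tumor counts as detected.

    The detection condition is a size condition: the voxel count of a disc of
    the detection radius, ceil(pi * r^2).  A count threshold is robust to
    ragged growth fronts, unlike a geometric radius estimate.
    """
    return math.ceil(math.pi * params.detection_radius**2)


@dataclass
class LatticeState:
    """Dense occupancy grid mapping voxel -> clone id (0 = empty)."""

    grid: np.ndarray
    center: tuple[int, int]
    occupied_count: int
    event_index: int = 0
    detected: bool = False
    _dist: np.ndarray | None = field(default=None, repr=False, compare=False)

    @classmethod
    def initial(cls, half_width: int, founder_clone: int = 1) -> "LatticeState":
        """Founder-only state on a (2*half_width+1)^2 grid, founder centered."""
        L = 2 * half_width + 1
        grid = np.zeros((L, L), dtype=np.int32)
        c = (half_width, half_width)
        grid[c] = founder_clone
        return cls(grid=grid, center=c, occupied_count=1)

    def distance_grid(self) -> np.ndarray:
        """Euclidean distance of every voxel center from the founder voxel."""
        if self._dist is None or self._dist.shape != self.grid.shape:
            rr, cc = np.indices(self.grid.shape)
            self._dist = np.hypot(rr - self.center[0], cc - self.center[1])
        return self._dist

    def validate(self) -> None:
        """Check the occupancy bookkeeping against a full grid scan."""
        actual = int(np.count_nonzero(self.grid))
        if actual != self.occupied_count:
            raise AssertionError(
                f"occupied_count={self.occupied_count} but grid has {actual} voxels"
            )


def moore_neighbors(pos: tuple[int, int], shape: tuple[int, int]) -> list[tuple[int, int]]:
    """The 8 Moore neighbors of ``pos``, in fixed row-major offset order.

    Raises ``IndexError`` for positions on the outermost ring (or outside the
    grid): a tumor reaching the boundary means the grid was sized too small.
    """
    r, c = pos
    if not (0 < r < shape[0] - 1 and 0 < c < shape[1] - 1):
        raise IndexError(
            f"position {pos} is on or outside the grid boundary {shape}: grid too small"
        )
    return [
        (r - 1, c - 1), (r - 1, c), (r - 1, c + 1),
        (r, c - 1), (r, c + 1),
        (r + 1, c - 1), (r + 1, c), (r + 1, c + 1),
    ]


def birth_probability(b: float, s: float, n: int) -> float:
    """Division probability b*(1+s)^n, clamped to 1 (it is a Bernoulli parameter)."""
    if n < 0:
        raise ValueError("driver count must be non-negative")
    return min(1.0, b * (1.0 + s) ** n)


def clone_birth_probability(params: SimParams, n: int) -> float:
    """Division probability of a clone with n drivers under the configured variant."""
    if params.selection_variant == "birth":
        return birth_probability(params.b, params.s, n)
    return min(1.0, params.b)


def death_rate_of(
    pos: tuple[int, int], n: int, state: LatticeState, params: SimParams
) -> float:
    """Death probability of the cell at ``pos`` with driver count ``n``.

    d1 applies pre-detection and inside the sanctuary (distance <= R, ties to
    the core); d2 applies on the detected tumor's edge.  Under death-rate
    selection the regional rate is reduced multiplicatively per driver.
    """
    dist = math.hypot(pos[0] - state.center[0], pos[1] - state.center[1])
    d = params.d1 if (not state.detected or dist <= params.R) else params.d2
    if params.selection_variant == "death":
        d *= (1.0 - params.s) ** n
    return d


def draw_driver_count(mu: float, rng: np.random.Generator) -> int:
    """Number of new drivers acquired by a daughter cell: Poisson(mu)."""
    if mu < 0:
        raise ValueError("mu must be non-negative")
    return int(rng.poisson(mu))


def check_detection(state: LatticeState, params: SimParams) -> bool:
    """Latch ``detected`` once the occupied count reaches the detection size."""
    if not state.detected and state.occupied_count >= detection_threshold(params):
        state.detected = True
    return state.detected


@dataclass(frozen=True)
class EventRecord:
    """What happened in one event of the reference :func:`step` loop."""

    position: tuple[int, int]
    clone_id: int
    divided: bool
    daughter_position: tuple[int, int] | None
    n_new_drivers: int
    daughter_clone_id: int | None
    died: bool


def step(
    state: LatticeState,
    ledger: CloneLedger,
    params: SimParams,
    rng: np.random.Generator,
) -> EventRecord:
    """Advance the model by exactly one event (reference implementation).

    Semantics match the compiled kernel: pick a cell uniformly, attempt
    division (needs an empty Moore neighbor), then apply death to the same
    chosen cell.  The daughter placed this event is not a death candidate,
    but it does count as occupying space for the quiescent death check.
    """
    if state.occupied_count < 1:
        raise ValueError("cannot step an empty lattice")
    grid = state.grid
    occupied = np.argwhere(grid > 0)  # deterministic row-major order
    pos = tuple(int(x) for x in occupied[rng.integers(len(occupied))])
    cid = int(grid[pos])
    state.event_index += 1

    divided = False
    daughter_pos: tuple[int, int] | None = None
    daughter_clone: int | None = None
    k = 0
    empties = [q for q in moore_neighbors(pos, grid.shape) if grid[q] == 0]
    n = ledger[cid].n
    if empties and rng.random() < clone_birth_probability(params, n):
        daughter_pos = empties[rng.integers(len(empties))]
        k = draw_driver_count(params.mu, rng)
        daughter_clone = cid
        if k > 0:
            new_ids = ledger.allocate_mutation_ids(k)
            daughter_clone = ledger.register_division(
                cid, new_ids, birth_event=state.event_index
            )
        grid[daughter_pos] = daughter_clone
        state.occupied_count += 1
        divided = True
    check_detection(state, params)

    died = False
    surrounded = all(grid[q] != 0 for q in moore_neighbors(pos, grid.shape))
    if not (params.growth_variant == "quiescent" and surrounded):
        if rng.random() < death_rate_of(pos, n, state, params):
            grid[pos] = 0
            state.occupied_count -= 1
            died = True
    return EventRecord(
        position=pos,
        clone_id=cid,
        divided=divided,
        daughter_position=daughter_pos,
        n_new_drivers=k,
        daughter_clone_id=daughter_clone,
        died=died,
    )


@dataclass(frozen=True)
class TrajectoryRecord:
    """Per-clone region census at one recorded sweep."""

    sweep: float
    occupied_count: int
    detected: bool
    clone_ids: np.ndarray
    core_counts: np.ndarray
    edge_counts: np.ndarray
    dist_sums: np.ndarray


@dataclass
class Trajectory:
    """Full result of one simulation run."""

    params: SimParams
    records: list[TrajectoryRecord]
    ledger: CloneLedger
    terminal: str  # max_size | extinct | boundary_abort | sweep_cap
    n_sweeps: float
    n_events: int
    detect_sweep: float | None
    detect_event: int | None
    final_state: LatticeState

    @property
    def regime(self) -> str:
        return self.params.regime

    def to_frame(self) -> pd.DataFrame:
        """Long table: sweep, clone_id, region, voxel_count."""
        rows = []
        for rec in self.records:
            for cid, nc, ne in zip(rec.clone_ids, rec.core_counts, rec.edge_counts):
                rows.append((rec.sweep, int(cid), "core", int(nc)))
                rows.append((rec.sweep, int(cid), "edge", int(ne)))
        return pd.DataFrame(rows, columns=["sweep", "clone_id", "region", "voxel_count"])

    def distance_frame(self) -> pd.DataFrame:
        """Long table: sweep, clone_id, mean_distance (voxels from center)."""
        rows = []
        for rec in self.records:
            tot = rec.core_counts + rec.edge_counts
            with np.errstate(invalid="ignore"):
                md = np.where(tot > 0, rec.dist_sums / np.maximum(tot, 1), np.nan)
            for cid, d in zip(rec.clone_ids, md):
                rows.append((rec.sweep, int(cid), float(d)))
        return pd.DataFrame(rows, columns=["sweep", "clone_id", "mean_distance"])


def _grid_half_width(params: SimParams) -> int:
    # safety margin: 4x the radius of a disc holding max_voxels, and never
    # tighter than the detection radius footprint
    by_size = 4.0 * math.sqrt(params.max_voxels / math.pi)
    return int(math.ceil(max(by_size, params.detection_radius + 10))) + 2


def run_simulation(
    params: SimParams,
    *,
    record_every: float = 1.0,
    max_sweeps: float = float("inf"),
    clone_capacity: int = 4096,
) -> Trajectory:
    """Run one tumor from a single founder cell to termination.

    Terminates on extinction or when the population reaches
    ``params.max_voxels`` (or, as a safety valve, ``max_sweeps``).  The
    per-clone region census is recorded every ``record_every`` sweeps and at
    termination.  Identical params (including seed) give bit-identical
    trajectories.
    """
    half = _grid_half_width(params)
    L = 2 * half + 1
    center_flat = half * L + half

    grid = np.zeros(L * L, dtype=np.int32)
    occ = np.zeros(params.max_voxels + 8, dtype=np.int64)
    slot = np.full(L * L, -1, dtype=np.int64)
    rr, cc = np.indices((L, L))
    distg = np.hypot(rr - half, cc - half).ravel()
    core = (distg <= params.R).astype(np.uint8)

    grid[center_flat] = 1
    occ[0] = center_flat
    slot[center_flat] = 0

    cap = clone_capacity
    clone_birth = np.zeros(cap, dtype=np.float64)
    clone_dmult = np.zeros(cap, dtype=np.float64)
    clone_n = np.zeros(cap, dtype=np.int64)
    cnt_core = np.zeros(cap, dtype=np.int64)
    cnt_edge = np.zeros(cap, dtype=np.int64)
    dist_sum = np.zeros(cap, dtype=np.float64)
    log_parent = np.zeros(cap, dtype=np.int64)
    log_k = np.zeros(cap, dtype=np.int64)
    log_event = np.zeros(cap, dtype=np.int64)
    log_sweep = np.zeros(cap, dtype=np.float64)

    clone_birth[1] = clone_birth_probability(params, 0)
    clone_dmult[1] = 1.0
    cnt_core[1] = 1  # founder sits at the center, inside any core
    # founder distance is 0; dist_sum[1] starts at 0

    istate = np.zeros(8, dtype=np.int64)
    istate[_kernel.I_M] = 1
    istate[_kernel.I_NCLONES] = 2
    fstate = np.zeros(4, dtype=np.float64)

    birth_factor = 1.0 + params.s if params.selection_variant == "birth" else 1.0
    death_factor = 1.0 - params.s if params.selection_variant == "death" else 1.0
    quiescent = 1 if params.growth_variant == "quiescent" else 0

    _kernel.seed_rng(params.seed % 2**32)

    ledger = CloneLedger()
    records: list[TrajectoryRecord] = []
    n_registered_log = 0
    next_record = record_every
    terminal = None

    def grow(arr: np.ndarray) -> np.ndarray:
        out = np.zeros(arr.shape[0] * 2, dtype=arr.dtype)
        out[: arr.shape[0]] = arr
        return out

    def snapshot() -> None:
        ncl = int(istate[_kernel.I_NCLONES])
        totals = cnt_core[1:ncl] + cnt_edge[1:ncl]
        live = np.nonzero(totals > 0)[0] + 1
        records.append(
            TrajectoryRecord(
                sweep=float(fstate[_kernel.F_SWEEP]),
                occupied_count=int(istate[_kernel.I_M]),
                detected=bool(istate[_kernel.I_DETECTED]),
                clone_ids=live.copy(),
                core_counts=cnt_core[live].copy(),
                edge_counts=cnt_edge[live].copy(),
                dist_sums=dist_sum[live].copy(),
            )
        )

    while terminal is None:
        code = _kernel.run_chunk(
            grid, L, occ, slot, core, distg,
            clone_birth, clone_dmult, clone_n,
            cnt_core, cnt_edge, dist_sum,
            log_parent, log_k, log_event, log_sweep,
            istate, fstate,
            params.d1, params.d2, params.mu,
            birth_factor, death_factor, quiescent,
            detection_threshold(params), params.max_voxels,
            next_record, max_sweeps,
        )
        # register newly founded clones; kernel ids are sequential from 2 and
        # must line up with the ledger's own sequential assignment
        nlog = int(istate[_kernel.I_NLOG])
        for i in range(n_registered_log, nlog):
            ids = ledger.allocate_mutation_ids(int(log_k[i]))
            child = ledger.register_division(
                int(log_parent[i]),
                ids,
                birth_event=int(log_event[i]),
                birth_sweep=float(log_sweep[i]),
            )
            assert child == i + 2, "kernel/ledger clone id streams diverged"
        n_registered_log = nlog

        if code == _kernel.RECORD:
            snapshot()
            next_record += record_every
        elif code == _kernel.BUFFERS_FULL:
            clone_birth = grow(clone_birth)
            clone_dmult = grow(clone_dmult)
            clone_n = grow(clone_n)
            cnt_core = grow(cnt_core)
            cnt_edge = grow(cnt_edge)
            dist_sum = grow(dist_sum)
            log_parent = grow(log_parent)
            log_k = grow(log_k)
            log_event = grow(log_event)
            log_sweep = grow(log_sweep)
        elif code == _kernel.MAX_SIZE:
            terminal = "max_size"
        elif code == _kernel.EXTINCT:
            terminal = "extinct"
        elif code == _kernel.BOUNDARY:
            terminal = "boundary_abort"
        elif code == _kernel.SWEEP_CAP:
            terminal = "sweep_cap"
        else:  # pragma: no cover
            raise RuntimeError(f"unknown kernel return code {code}")

    snapshot()  # terminal census

    detected = bool(istate[_kernel.I_DETECTED])
    final_state = LatticeState(
        grid=grid.reshape(L, L),
        center=(half, half),
        occupied_count=int(istate[_kernel.I_M]),
        event_index=int(istate[_kernel.I_EVENT]),
        detected=detected,
    )
    if terminal == "boundary_abort":
        raise RuntimeError(
            "tumor reached the lattice boundary; increase the grid safety margin"
        )
    return Trajectory(
        params=params,
        records=records,
        ledger=ledger,
        terminal=terminal,
        n_sweeps=float(fstate[_kernel.F_SWEEP]),
        n_events=int(istate[_kernel.I_EVENT]),
        detect_sweep=float(fstate[_kernel.F_DETECT_SWEEP]) if detected else None,
        detect_event=int(istate[_kernel.I_DETECT_EVENT]) if detected else None,
        final_state=final_state,
    )
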