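"""Clone genealogy and driver-mutation bookkeeping.

Clones are identified with unique driver genotypes: a division that adds at
least one new driver creates a new clone whose driver set is the parent's set
plus the new mutation ids.  Mutation ids are globally unique (infinite-sites
assumption), so every mutation has a single originating clone and its carrier
set is exactly that clone's genealogical subtree.  This makes per-mutation
census work (tissue frequency f_m, carrier mean death rate d_bar_m, mean
carrier distance from the tumor center) a linear pass over the clone table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Clone",
    "CloneLedger",
    "RegionCounts",
    "InfiniteSitesViolation",
    "region_counts",
    "tissue_clone_fractions",
    "mutation_summary",
    "mutation_summary_from_clone_stats",
]


class InfiniteSitesViolation(ValueError):
    """Raised when a mutation id is assigned more than once."""


@dataclass(frozen=True)
class Clone:
    """One node of the clone genealogy.

    ``new_driver_ids`` holds only the drivers gained at this clone's founding
    division; the full driver set is the union along the ancestry and is
    served (cached) by :meth:`CloneLedger.driver_set`.
    """

    id: int
    parent_id: int  # 0 for the founder clone
    new_driver_ids: tuple[int, ...]
    n: int  # total driver count |driver set|
    birth_event: int = 0
    birth_sweep: float = 0.0


class CloneLedger:
    """Registry of clones forming a tree rooted at the founder.

    The founder clone (id 1, parent 0, no drivers) is created on
    construction.  Clone ids are assigned sequentially, so every child id is
    strictly greater than its parent's — downstream aggregation relies on
    this ordering.
    """

    def __init__(self) -> None:
        self._clones: dict[int, Clone] = {}
        self._used_mutations: dict[int, int] = {}  # mutation id -> origin clone
        self._driver_cache: dict[int, frozenset[int]] = {0: frozenset()}
        self._next_mutation_id = 1
        founder = Clone(id=1, parent_id=0, new_driver_ids=(), n=0)
        self._clones[1] = founder

    # -- basic access -----------------------------------------------------
    @property
    def founder_id(self) -> int:
        return 1

    def __len__(self) -> int:
        return len(self._clones)

    def __contains__(self, clone_id: int) -> bool:
        return clone_id in self._clones

    def __getitem__(self, clone_id: int) -> Clone:
        return self._clones[clone_id]

    def clones(self) -> list[Clone]:
        return [self._clones[i] for i in sorted(self._clones)]

    @property
    def n_mutations(self) -> int:
        return len(self._used_mutations)

    def mutation_origins(self) -> dict[int, int]:
        """Mapping mutation id -> clone id in which it first appeared."""
        return dict(self._used_mutations)

    def driver_set(self, clone_id: int) -> frozenset[int]:
        """Full driver set of a clone (union along its ancestry)."""
        cached = self._driver_cache.get(clone_id)
        if cached is not None:
            return cached
        clone = self._clones[clone_id]
        full = self.driver_set(clone.parent_id) | frozenset(clone.new_driver_ids)
        self._driver_cache[clone_id] = full
        return full

    # -- registration -----------------------------------------------------
    def allocate_mutation_ids(self, k: int) -> tuple[int, ...]:
        """Reserve ``k`` fresh globally-unique mutation ids."""
        ids = tuple(range(self._next_mutation_id, self._next_mutation_id + k))
        self._next_mutation_id += k
        return ids

    def register_division(
        self,
        parent_id: int,
        new_driver_ids: tuple[int, ...] = (),
        *,
        birth_event: int = 0,
        birth_sweep: float = 0.0,
    ) -> int:
        """Record a division; returns the clone id of the daughter cell.

        With no new drivers the daughter belongs to the parent clone.
        Otherwise a child clone is created.  Reusing a mutation id raises
        :class:`InfiniteSitesViolation`.
        """
        if parent_id not in self._clones:
            raise KeyError(f"unknown parent clone {parent_id}")
        if not new_driver_ids:
            return parent_id
        for mid in new_driver_ids:
            if mid in self._used_mutations:
                raise InfiniteSitesViolation(
                    f"mutation id {mid} already assigned (infinite-sites violation)"
                )
        child_id = max(self._clones) + 1
        parent = self._clones[parent_id]
        clone = Clone(
            id=child_id,
            parent_id=parent_id,
            new_driver_ids=tuple(new_driver_ids),
            n=parent.n + len(new_driver_ids),
            birth_event=birth_event,
            birth_sweep=birth_sweep,
        )
        self._clones[child_id] = clone
        for mid in new_driver_ids:
            self._used_mutations[mid] = child_id
        if self._next_mutation_id <= max(new_driver_ids):
            self._next_mutation_id = max(new_driver_ids) + 1
        return child_id

    # -- export -----------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Ledger as a table: clone_id, parent_id, n, birth_event, driver_ids."""
        rows = [
            {
                "clone_id": c.id,
                "parent_id": c.parent_id,
                "n": c.n,
                "birth_event": c.birth_event,
                "birth_sweep": c.birth_sweep,
                "driver_ids": ";".join(str(m) for m in sorted(self.driver_set(c.id))),
            }
            for c in self.clones()
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CloneLedger":
        """Rebuild a ledger from its :meth:`to_frame` table."""
        ledger = cls()
        known = {0: frozenset(), 1: frozenset()}
        for row in df.sort_values("clone_id").itertuples():
            if row.clone_id == 1:
                continue
            drivers = frozenset(
                int(x) for x in str(row.driver_ids).split(";") if x not in ("", "nan")
            )
            new_ids = tuple(sorted(drivers - known[row.parent_id]))
            cid = ledger.register_division(
                int(row.parent_id),
                new_ids,
                birth_event=int(row.birth_event),
                birth_sweep=float(getattr(row, "birth_sweep", 0.0)),
            )
            assert cid == row.clone_id, "ledger table ids are not sequential"
            known[row.clone_id] = drivers
        return ledger


@dataclass
class RegionCounts:
    """Per-clone cell counts split into sanctuary core and edge.

    ``counts`` is indexed by clone id with integer columns ``core`` and
    ``edge``; ``d_core``/``d_edge`` are the death rates currently in force in
    each region (both equal to d1 before detection).
    """

    counts: pd.DataFrame
    d_core: float
    d_edge: float
    dist_sums: pd.Series | None = field(default=None)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


def region_counts(state, params) -> RegionCounts:
    """Exact census of a lattice state partitioned by the distance<=R rule.

    Voxels whose Euclidean distance from the founder voxel is <= R (ties
    included) belong to the core.  Before detection both regions share d1.
    """
    grid = state.grid
    occ = grid > 0
    dist = state.distance_grid()
    in_core = dist <= params.R
    clone_ids = grid[occ]
    core_flag = in_core[occ]
    dists = dist[occ]
    df = pd.DataFrame({"clone_id": clone_ids, "core": core_flag, "dist": dists})
    agg = df.groupby("clone_id").agg(
        core=("core", "sum"), total=("core", "size"), dist_sum=("dist", "sum")
    )
    counts = pd.DataFrame(
        {"core": agg["core"].astype(int), "edge": (agg["total"] - agg["core"]).astype(int)}
    )
    d_edge = params.d2 if state.detected else params.d1
    return RegionCounts(
        counts=counts, d_core=params.d1, d_edge=d_edge, dist_sums=agg["dist_sum"]
    )


def tissue_clone_fractions(rc: RegionCounts) -> pd.Series:
    """Clone fractions in the tissue: N_i / sum_i N_i."""
    totals = rc.counts.sum(axis=1)
    grand = totals.sum()
    if grand == 0:
        raise ValueError("empty tumor: no occupied voxels")
    return totals / grand


def _subtree_aggregate(ledger: CloneLedger, clone_ids: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Sum per-clone values over each clone's genealogical subtree.

    ``values`` has one row per entry of ``clone_ids``; returns an array of the
    same shape indexed identically, where each row holds the subtree total of
    that clone.  Relies on parent id < child id.
    """
    max_id = max((c.id for c in ledger.clones()), default=1)
    dense = np.zeros((max_id + 1,) + values.shape[1:], dtype=float)
    dense[clone_ids] = values
    for cid in range(max_id, 1, -1):
        if cid in ledger:
            dense[ledger[cid].parent_id] += dense[cid]
    return dense


def mutation_summary_from_clone_stats(
    ledger: CloneLedger,
    clone_ids: np.ndarray,
    core_counts: np.ndarray,
    edge_counts: np.ndarray,
    dist_sums: np.ndarray,
    d_core: float,
    d_edge: float,
) -> pd.DataFrame:
    """Per-mutation census from per-clone region counts.

    Carriers of a mutation are the cells of the originating clone's subtree.
    Returns columns: mutation_id, f_m, d_bar_m, mean_distance, clonal.
    """
    clone_ids = np.asarray(clone_ids, dtype=int)
    stats = np.column_stack([core_counts, edge_counts, dist_sums]).astype(float)
    total_cells = core_counts.sum() + edge_counts.sum()
    if total_cells == 0:
        raise ValueError("empty tumor: no occupied voxels")
    agg = _subtree_aggregate(ledger, clone_ids, stats)
    origins = ledger.mutation_origins()
    rows = []
    for mid in sorted(origins):
        core_m, edge_m, dsum_m = agg[origins[mid]]
        carriers = core_m + edge_m
        if carriers == 0:
            rows.append(
                {"mutation_id": mid, "f_m": 0.0, "d_bar_m": np.nan,
                 "mean_distance": np.nan, "clonal": False}
            )
            continue
        rows.append(
            {
                "mutation_id": mid,
                "f_m": carriers / total_cells,
                "d_bar_m": (d_core * core_m + d_edge * edge_m) / carriers,
                "mean_distance": dsum_m / carriers,
                "clonal": int(carriers) == int(total_cells),
            }
        )
    cols = ["mutation_id", "f_m", "d_bar_m", "mean_distance", "clonal"]
    return pd.DataFrame(rows, columns=cols)


def mutation_summary(state, ledger: CloneLedger, params) -> pd.DataFrame:
    """Per-mutation census of a lattice state (same columns as above)."""
    rc = region_counts(state, params)
    idx = rc.counts.index.to_numpy()
    return mutation_summary_from_clone_stats(
        ledger,
        idx,
        rc.counts["core"].to_numpy(),
        rc.counts["edge"].to_numpy(),
        rc.dist_sums.loc[idx].to_numpy(),
        rc.d_core,
        rc.d_edge,
    )
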