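"""Deterministic hand-constructable lattice states.

Builds small :class:`~latticeshed.lattice_engine.LatticeState` objects from a
geometric description (concentric discs and annuli of labeled clones with
given driver sets) together with a consistent clone ledger, so the shedding
and metrics stages can be exercised without running a simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clone_ledger import CloneLedger
from .lattice_engine import LatticeState

__all__ = ["FixtureRegion", "make_fixture", "disc_voxel_count"]


@dataclass(frozen=True)
class FixtureRegion:
    """An annulus r_inner < distance <= r_outer assigned to one clone.

    A disc is an annulus with ``r_inner`` = -1 (so the center voxel, at
    distance 0, is included).  ``drivers`` lists the mutation ids carried by
    the clone beyond its parent's; ``parent`` names another region's label
    (or None for a child of the founder clone).
    """

    label: str
    r_outer: float
    r_inner: float = -1.0
    drivers: tuple[int, ...] = ()
    parent: str | None = None


def disc_voxel_count(radius: float) -> int:
    """Number of integer lattice points within Euclidean distance ``radius``."""
    r = int(np.floor(radius))
    rr, cc = np.mgrid[-r : r + 1, -r : r + 1]
    return int((rr**2 + cc**2 <= radius**2).sum())


def make_fixture(
    regions: list[FixtureRegion],
    *,
    half_width: int | None = None,
    detected: bool = True,
) -> tuple[LatticeState, CloneLedger, dict[str, int]]:
    """Build a lattice state and ledger from disjoint annular regions.

    Returns (state, ledger, label->clone id map).  Overlapping regions and
    an empty region list are errors.  The first region is rooted at the
    founder clone; later regions descend from their named ``parent`` region,
    or from the first region's clone when no parent is given, keeping the
    genealogy a tree.
    """
    if not regions:
        raise ValueError("fixture needs at least one region")
    if half_width is None:
        half_width = int(np.ceil(max(r.r_outer for r in regions))) + 3
    state = LatticeState.initial(half_width)
    state.grid[state.center] = 0  # rebuilt below
    dist = state.distance_grid()

    ledger = CloneLedger()
    label_to_clone: dict[str, int] = {}
    # first pass: create clones in order so parents exist
    for i, reg in enumerate(regions):
        if i == 0:
            if reg.drivers:
                cid = ledger.register_division(ledger.founder_id, tuple(reg.drivers))
            else:
                cid = ledger.founder_id
        else:
            parent = (
                label_to_clone[reg.parent]
                if reg.parent is not None
                else label_to_clone[regions[0].label]
            )
            if not reg.drivers:
                raise ValueError(
                    f"region {reg.label!r}: a distinct clone needs at least one driver"
                )
            cid = ledger.register_division(parent, tuple(reg.drivers))
        label_to_clone[reg.label] = cid

    grid = state.grid
    for reg in regions:
        mask = (dist > reg.r_inner) & (dist <= reg.r_outer)
        if (grid[mask] != 0).any():
            raise ValueError(f"region {reg.label!r} overlaps a previous region")
        grid[mask] = label_to_clone[reg.label]
    state.occupied_count = int(np.count_nonzero(grid))
    state.detected = detected
    return state, ledger, label_to_clone
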