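"""Numba event loop for the boundary-driven lattice simulation.

The kernel advances the per-event dynamics on flat arrays and returns to
Python at recording points, terminal conditions, or when the clone/log
buffers need growing.  All stochasticity uses numba's internal RNG, seeded
once per run via :func:`seed_rng`, so a fixed seed reproduces the event
sequence bit-for-bit.

Event semantics (one event):
  1. pick an occupied voxel uniformly at random; advance the sweep clock by
     1/m (one "sweep" = m cell picks at the current population size m);
  2. the chosen cell attempts division with probability min(1, b*(1+s)^n)
     (birth-rate selection; plain b under death-rate selection).  Division
     requires an empty Moore neighbor; the daughter lands on a uniformly
     chosen empty neighbor and gains Poisson(mu) new drivers, founding a new
     clone if that count is positive;
  3. the SAME chosen cell then dies with its regional death probability
     (d1 in the sanctuary core or pre-detection, d2 on the edge, times
     (1-s)^n under death-rate selection).  In the quiescent variant death is
     skipped when the cell has no empty neighbor at this point (the daughter
     placed in step 2 counts as occupying).
The daughter placed in step 2 is never the death candidate of its own event.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# chunk return codes
RECORD = 0
MAX_SIZE = 1
EXTINCT = 2
BOUNDARY = 3
BUFFERS_FULL = 4
SWEEP_CAP = 5

# istate layout
I_M = 0           # occupied voxel count
I_EVENT = 1       # event index
I_DETECTED = 2    # 0/1 latch
I_NCLONES = 3     # next clone id to assign
I_NLOG = 4        # rows used in the mutation log
I_DETECT_EVENT = 5
# fstate layout
F_SWEEP = 0       # sweep clock
F_DETECT_SWEEP = 1


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def run_chunk(
    grid,            # (L*L,) int32 clone ids, 0 empty
    L,
    occ,             # (max_voxels+1,) flat positions of occupied voxels
    slot,            # (L*L,) position -> index in occ, -1 if empty
    core,            # (L*L,) uint8: 1 inside sanctuary (distance <= R)
    distg,           # (L*L,) float64 distance from founder voxel
    clone_birth,     # per-clone division probability (clamped at 1)
    clone_dmult,     # per-clone death multiplier ((1-s)^n or 1)
    clone_n,         # per-clone driver count
    cnt_core, cnt_edge, dist_sum,   # per-clone running census
    log_parent, log_k, log_event, log_sweep,  # mutation log
    istate, fstate,
    d1, d2, mu,
    birth_factor,    # (1+s) under birth selection, 1 otherwise
    death_factor,    # (1-s) under death selection, 1 otherwise
    quiescent,       # 0/1
    detect_threshold,
    max_voxels,
    next_record,     # sweep value at which to return for recording
    sweep_cap,       # hard stop on the sweep clock (safety)
):
    m = istate[I_M]
    ev = istate[I_EVENT]
    detected = istate[I_DETECTED]
    ncl = istate[I_NCLONES]
    nlog = istate[I_NLOG]
    t = fstate[F_SWEEP]
    clone_cap = clone_birth.shape[0]
    log_cap = log_parent.shape[0]

    off = np.empty(8, np.int64)
    off[0] = -L - 1; off[1] = -L; off[2] = -L + 1
    off[3] = -1;     off[4] = 1
    off[5] = L - 1;  off[6] = L;  off[7] = L + 1
    emp = np.empty(8, np.int64)

    code = RECORD
    while True:
        if m == 0:
            code = EXTINCT
            break
        if m >= max_voxels:
            code = MAX_SIZE
            break
        if t >= next_record:
            code = RECORD
            break
        if t >= sweep_cap:
            code = SWEEP_CAP
            break
        if ncl >= clone_cap or nlog >= log_cap:
            code = BUFFERS_FULL
            break

        pos = occ[np.random.randint(0, m)]
        cid = grid[pos]
        ev += 1
        t += 1.0 / m

        # --- division attempt ---
        ne = 0
        for k in range(8):
            q = pos + off[k]
            if grid[q] == 0:
                emp[ne] = q
                ne += 1
        if ne > 0 and np.random.random() < clone_birth[cid]:
            tgt = emp[np.random.randint(0, ne)]
            tr = tgt // L
            tc = tgt - tr * L
            if tr == 0 or tr == L - 1 or tc == 0 or tc == L - 1:
                code = BOUNDARY
                break
            kmut = np.random.poisson(mu)
            child = cid
            if kmut > 0:
                child = ncl
                bp = clone_birth[cid] * birth_factor**kmut
                if bp > 1.0:
                    bp = 1.0
                clone_birth[child] = bp
                clone_dmult[child] = clone_dmult[cid] * death_factor**kmut
                clone_n[child] = clone_n[cid] + kmut
                log_parent[nlog] = cid
                log_k[nlog] = kmut
                log_event[nlog] = ev
                log_sweep[nlog] = t
                nlog += 1
                ncl += 1
            grid[tgt] = child
            occ[m] = tgt
            slot[tgt] = m
            m += 1
            if core[tgt]:
                cnt_core[child] += 1
            else:
                cnt_edge[child] += 1
            dist_sum[child] += distg[tgt]
            if detected == 0 and m >= detect_threshold:
                detected = 1
                istate[I_DETECT_EVENT] = ev
                fstate[F_DETECT_SWEEP] = t

        # --- death of the chosen cell ---
        if quiescent:
            surrounded = True
            for k in range(8):
                if grid[pos + off[k]] == 0:
                    surrounded = False
                    break
            if surrounded:
                continue
        if detected == 0 or core[pos]:
            d = d1
        else:
            d = d2
        d *= clone_dmult[cid]
        if np.random.random() < d:
            j = slot[pos]
            last = occ[m - 1]
            occ[j] = last
            slot[last] = j
            m -= 1
            slot[pos] = -1
            grid[pos] = 0
            if core[pos]:
                cnt_core[cid] -= 1
            else:
                cnt_edge[cid] -= 1
            dist_sum[cid] -= distg[pos]

    istate[I_M] = m
    istate[I_EVENT] = ev
    istate[I_DETECTED] = detected
    istate[I_NCLONES] = ncl
    istate[I_NLOG] = nlog
    fstate[F_SWEEP] = t
    return code
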