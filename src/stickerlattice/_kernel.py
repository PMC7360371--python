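"""Compiled (numba) Gillespie loop, array-state mirror of :mod:`engine`.

The kernel keeps the exact semantics of the reference implementation —
full re-enumeration of the event set after every event, the same rate
formulas, the same draw order (waiting time first, then event) — but works
on flat arrays:

* ``grid``    : (L*L,) int32, -1 empty else particle id
* ``site_of`` : (N,) int32 flat site index per particle
* ``bonds``   : (N, 4) int16 bond multiplicity towards the neighbor in each
  direction (mirrored: ``bonds[p, d] == bonds[q, opposite(d)]``); bonds can
  only join adjacent particles, so this directional store is complete
* ``used``    : (N,) int16 engaged valency

Monomer hop rates are looked up in a precomputed Boltzmann table indexed by
(engaged bonds, occupied neighbors).  Equivalence with the pure-Python
enumeration is asserted by the test suite on randomized states.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .lattice import LatticeState, SimParams, init_lattice

# direction encoding matches lattice.DIRECTIONS: N, S, E, W
_OPP = (1, 0, 3, 2)

# event kinds
_MOVE, _CMOVE, _FORM, _BREAK = 0, 1, 2, 3

# advance() status codes
_REACHED, _EXHAUSTED, _EX_FULL, _REC_FULL = 0, 1, 2, 3


def build_neighbor_table(L: int) -> np.ndarray:
    """(L*L, 4) int32 table of periodic von Neumann neighbor site indices."""
    nbr = np.empty((L * L, 4), dtype=np.int32)
    for s in range(L * L):
        r, c = divmod(s, L)
        nbr[s, 0] = ((r - 1) % L) * L + c
        nbr[s, 1] = ((r + 1) % L) * L + c
        nbr[s, 2] = r * L + (c + 1) % L
        nbr[s, 3] = r * L + (c - 1) % L
    return nbr


def build_move_table(params: SimParams) -> np.ndarray:
    """Hop rate ``k_move * exp(-(b*eps_sp + n*eps_ns))`` for b<=lam, n<=4."""
    b = np.arange(params.lam + 1)[:, None]
    n = np.arange(5)[None, :]
    return params.k_move * np.exp(-(b * params.eps_sp + n * params.eps_ns))


@njit(cache=True, inline="always")
def _find(parent, i):
    root = i
    while parent[root] != root:
        root = parent[root]
    while parent[i] != root:
        nxt = parent[i]
        parent[i] = root
        i = nxt
    return root


@njit(cache=True)
def _enumerate(
    grid, site_of, bonds, used, nbr,
    lam, k_bond, k_break, k_diff_cluster,
    move_table,
    parent, csize, ok, nnb, root_of,
    ev_kind, ev_a, ev_b, ev_rate,
):
    """Fill the event arrays for the current state; return (n_events, r_total).

    Also refreshes ``parent``/``csize`` (cluster labeling) and ``nnb``
    (occupied-neighbor counts), which callers reuse.
    """
    n = site_of.shape[0]
    for p in range(n):
        parent[p] = p

    ne = 0
    rtot = 0.0
    for p in range(n):
        s = site_of[p]
        q0 = grid[nbr[s, 0]]
        q1 = grid[nbr[s, 1]]
        q2 = grid[nbr[s, 2]]
        q3 = grid[nbr[s, 3]]
        # union with the S and E neighbors: each adjacent pair seen once
        if q1 >= 0:
            rp = _find(parent, p)
            rq = _find(parent, q1)
            if rp != rq:
                if rp < rq:
                    parent[rq] = rp
                else:
                    parent[rp] = rq
        if q2 >= 0:
            rp = _find(parent, p)
            rq = _find(parent, q2)
            if rp != rq:
                if rp < rq:
                    parent[rq] = rp
                else:
                    parent[rp] = rq
        nb = 0
        if q0 >= 0:
            nb += 1
        if q1 >= 0:
            nb += 1
        if q2 >= 0:
            nb += 1
        if q3 >= 0:
            nb += 1
        nnb[p] = nb
        if nb < 4:
            # one aggregate entry for the particle's equal-rate hops; the
            # draw step subdivides it into equal per-direction slices
            rate = move_table[used[p], nb] * (4 - nb)
            ev_kind[ne] = _MOVE
            ev_a[ne] = p
            ev_b[ne] = -1
            ev_rate[ne] = rate
            rtot += rate
            ne += 1
        for d in range(1, 3):  # S, E: each adjacent pair once
            q = q1 if d == 1 else q2
            if q >= 0:
                if k_bond > 0.0 and used[p] < lam and used[q] < lam:
                    ev_kind[ne] = _FORM
                    ev_a[ne] = p
                    ev_b[ne] = d
                    ev_rate[ne] = k_bond
                    rtot += k_bond
                    ne += 1
                m = bonds[p, d]
                if m > 0:
                    rate = m * k_break
                    ev_kind[ne] = _BREAK
                    ev_a[ne] = p
                    ev_b[ne] = d
                    ev_rate[ne] = rate
                    rtot += rate
                    ne += 1

    any_cluster = False
    for p in range(n):
        csize[p] = 0
    for p in range(n):
        r = _find(parent, p)
        root_of[p] = r
        csize[r] += 1
        if csize[r] >= 2:
            any_cluster = True
    # --- rigid cluster translations ---
    for d in range(4):
        if not any_cluster:
            break
        for p in range(n):
            ok[p] = 1
        for p in range(n):
            rp = root_of[p]
            if csize[rp] < 2:
                continue
            q = grid[nbr[site_of[p], d]]
            if q >= 0 and root_of[q] != rp:
                ok[rp] = 0
        for p in range(n):
            if parent[p] == p and csize[p] >= 2 and ok[p] == 1:
                rate = k_diff_cluster / csize[p]
                ev_kind[ne] = _CMOVE
                ev_a[ne] = p  # cluster identified by its union-find root
                ev_b[ne] = d
                ev_rate[ne] = rate
                rtot += rate
                ne += 1
    return ne, rtot


@njit(cache=True)
def _apply(
    grid, site_of, bonds, used, nbr, root_of,
    kind, a, b, mem, newsite,
):
    if kind == _MOVE:
        s = site_of[a]
        for dd in range(4):
            m = bonds[a, dd]
            if m > 0:
                q = grid[nbr[s, dd]]
                bonds[q, _OPP[dd]] -= m
                used[q] -= m
                bonds[a, dd] = 0
        used[a] = 0
        t = nbr[s, b]
        grid[s] = -1
        grid[t] = a
        site_of[a] = t
    elif kind == _CMOVE:
        n = site_of.shape[0]
        nm = 0
        for p in range(n):
            if root_of[p] == a:
                mem[nm] = p
                newsite[nm] = nbr[site_of[p], b]
                nm += 1
        for i in range(nm):
            grid[site_of[mem[i]]] = -1
        for i in range(nm):
            grid[newsite[i]] = mem[i]
            site_of[mem[i]] = newsite[i]
    elif kind == _FORM:
        q = grid[nbr[site_of[a], b]]
        bonds[a, b] += 1
        bonds[q, _OPP[b]] += 1
        used[a] += 1
        used[q] += 1
    else:  # _BREAK
        q = grid[nbr[site_of[a], b]]
        bonds[a, b] -= 1
        bonds[q, _OPP[b]] -= 1
        used[a] -= 1
        used[q] -= 1


@njit(cache=True)
def _advance(
    grid, site_of, bonds, used, nbr,
    lam, k_bond, k_break, k_diff_cluster,
    move_table,
    parent, csize, ok, nnb, root_of, mem, newsite,
    ev_kind, ev_a, ev_b, ev_rate,
    t, t_target, rng,
    record_exchange, ex_open, ex_p, ex_b, ex_r, ex_count,
    record_events, rec_t, rec_kind, rec_a, rec_b, rec_count,
):
    """Run the Gillespie loop until ``t_target``; return (t, events, status)."""
    n = site_of.shape[0]
    n_events = 0
    while True:
        if record_exchange and ex_count[0] > ex_p.shape[0] - n:
            return t, n_events, _EX_FULL
        if record_events and rec_count[0] >= rec_t.shape[0]:
            return t, n_events, _REC_FULL
        ne, rtot = _enumerate(
            grid, site_of, bonds, used, nbr,
            lam, k_bond, k_break, k_diff_cluster,
            move_table,
            parent, csize, ok, nnb, root_of,
            ev_kind, ev_a, ev_b, ev_rate,
        )
        if record_exchange:
            # burial opens at full coordination, closes when fully free;
            # idempotent, so re-scanning after a chunk boundary is safe
            for p in range(n):
                if nnb[p] == 4:
                    if ex_open[p] < 0.0:
                        ex_open[p] = t
                elif nnb[p] == 0 and ex_open[p] >= 0.0:
                    k = ex_count[0]
                    ex_p[k] = p
                    ex_b[k] = ex_open[p]
                    ex_r[k] = t
                    ex_count[0] = k + 1
                    ex_open[p] = -1.0
        if rtot <= 0.0:
            return t, n_events, _EXHAUSTED
        dt = -math.log(1.0 - rng.random()) / rtot
        if t + dt >= t_target:
            return t_target, n_events, _REACHED
        target = rng.random() * rtot
        acc = 0.0
        idx = ne - 1
        for i in range(ne):
            acc += ev_rate[i]
            if target < acc:
                idx = i
                break
        kind = ev_kind[idx]
        a = ev_a[idx]
        b = ev_b[idx]
        if kind == _MOVE:
            # subdivide the aggregate hop entry into its equal-rate slices
            n_empty = 4 - nnb[a]
            slice_rate = ev_rate[idx] / n_empty
            which = int((target - (acc - ev_rate[idx])) / slice_rate)
            if which >= n_empty:
                which = n_empty - 1
            s = site_of[a]
            b = 3
            for d in range(4):
                if grid[nbr[s, d]] < 0:
                    if which == 0:
                        b = d
                        break
                    which -= 1
        t += dt
        n_events += 1
        if record_events:
            k = rec_count[0]
            rec_t[k] = t
            rec_kind[k] = kind
            rec_a[k] = a
            rec_b[k] = b
            rec_count[0] = k + 1
        _apply(
            grid, site_of, bonds, used, nbr, root_of,
            kind, a, b, mem, newsite,
        )


# ---------------------------------------------------------------------------
# Python-side wrappers
# ---------------------------------------------------------------------------

class _ArrayState:
    """Flat-array mirror of a LatticeState plus kernel scratch buffers."""

    def __init__(self, state: LatticeState, params: SimParams):
        n, L = state.n_particles, state.L
        if L < 3:
            raise ValueError("the kernel requires L >= 3 (unambiguous adjacency)")
        self.L = L
        self.n = n
        self.grid = np.ascontiguousarray(state.grid.reshape(-1).astype(np.int32))
        self.site_of = np.array(
            [r * L + c for r, c in state.positions], dtype=np.int32
        )
        self.nbr = build_neighbor_table(L)
        self.bonds = np.zeros((n, 4), dtype=np.int16)
        for (p, q), m in state.bonds.items():
            sp = self.site_of[p]
            for d in range(4):
                if self.nbr[sp, d] == self.site_of[q]:
                    self.bonds[p, d] = m
                    self.bonds[q, _OPP[d]] = m
                    break
            else:
                raise ValueError(f"bond {(p, q)} joins non-adjacent particles")
        self.used = state.used_valency.astype(np.int16)
        self.move_table = build_move_table(params)
        cap = 12 * n + 16
        self.ev_kind = np.empty(cap, dtype=np.int8)
        self.ev_a = np.empty(cap, dtype=np.int32)
        self.ev_b = np.empty(cap, dtype=np.int8)
        self.ev_rate = np.empty(cap, dtype=np.float64)
        self.parent = np.empty(n, dtype=np.int32)
        self.csize = np.empty(n, dtype=np.int32)
        self.ok = np.empty(n, dtype=np.uint8)
        self.nnb = np.empty(n, dtype=np.int8)
        self.root_of = np.empty(n, dtype=np.int32)
        self.mem = np.empty(n, dtype=np.int32)
        self.newsite = np.empty(n, dtype=np.int32)

    def to_state(self, time: float) -> LatticeState:
        L = self.L
        grid = self.grid.reshape(L, L).astype(np.int32).copy()
        positions = np.column_stack(divmod(self.site_of.astype(np.int64), L))
        bonds: dict[tuple[int, int], int] = {}
        for p in range(self.n):
            for d in (1, 2):  # S, E: each pair once
                m = int(self.bonds[p, d])
                if m > 0:
                    q = int(self.grid[self.nbr[self.site_of[p], d]])
                    bonds[(min(p, q), max(p, q))] = m
        return LatticeState(
            L=L,
            grid=grid,
            positions=positions,
            bonds=bonds,
            used_valency=self.used.astype(np.int64),
            time=time,
        )


def kernel_enumerate(state: LatticeState, params: SimParams):
    """Run the kernel enumeration once; return ({(kind, a, b): rate}, r_total).

    For comparison against the reference enumeration: bond events are keyed
    by the ordered particle pair (break events aggregated over
    multiplicity), cluster moves by the smallest member id.
    """
    ws = _ArrayState(state, params)
    ne, rtot = _enumerate(
        ws.grid, ws.site_of, ws.bonds, ws.used, ws.nbr,
        np.int64(params.lam), params.k_bond, params.k_break, params.k_move,
        ws.move_table,
        ws.parent, ws.csize, ws.ok, ws.nnb, ws.root_of,
        ws.ev_kind, ws.ev_a, ws.ev_b, ws.ev_rate,
    )
    kinds = {0: "monomer_move", 1: "cluster_move", 2: "bond_form", 3: "bond_break"}
    # canonical cluster id: smallest member of each union-find root
    root_min: dict[int, int] = {}
    for p in range(ws.n):
        r = int(ws.root_of[p])
        root_min[r] = min(root_min.get(r, p), p)
    out: dict[tuple, float] = {}
    for i in range(ne):
        kind = kinds[int(ws.ev_kind[i])]
        a, b = int(ws.ev_a[i]), int(ws.ev_b[i])
        if kind == "monomer_move":
            s = ws.site_of[a]
            n_empty = 4 - int(ws.nnb[a])
            slice_rate = float(ws.ev_rate[i]) / n_empty
            for d in range(4):
                if ws.grid[ws.nbr[s, d]] < 0:
                    key = (kind, a, d)
                    out[key] = out.get(key, 0.0) + slice_rate
            continue
        elif kind == "cluster_move":
            key = (kind, root_min[a], b)
        else:
            q = int(ws.grid[ws.nbr[ws.site_of[a], b]])
            key = (kind, min(a, q), max(a, q))
        out[key] = out.get(key, 0.0) + float(ws.ev_rate[i])
    return out, float(rtot)


def run_trajectory_fast(
    params: SimParams,
    observers=(),
    *,
    record_exchange: bool = False,
    record_events: bool = False,
    initial_state: LatticeState | None = None,
):
    """Compiled counterpart of :func:`engine.run_trajectory` (engine="python").

    Statistically equivalent to the reference loop and deterministic per
    seed; the two engines consume their RNG streams slightly differently
    around snapshot ticks, so per-seed trajectories are identical within an
    engine, not across engines.
    """
    from .engine import Trajectory, _snapshot_ticks
    from .observables import ExchangeEventLog

    state = init_lattice(params) if initial_state is None else initial_state
    ws = _ArrayState(state, params)
    rng = np.random.default_rng((params.seed, 7919))

    ex_cap = 1 << 16
    ex_open = np.full(ws.n, -1.0)
    ex_pbuf = np.empty(ex_cap, dtype=np.int32)
    ex_bbuf = np.empty(ex_cap, dtype=np.float64)
    ex_rbuf = np.empty(ex_cap, dtype=np.float64)
    ex_count = np.zeros(1, dtype=np.int64)
    rec_cap = 1 << 16 if record_events else 1
    rec_t = np.empty(rec_cap, dtype=np.float64)
    rec_kind = np.empty(rec_cap, dtype=np.int8)
    rec_a = np.empty(rec_cap, dtype=np.int32)
    rec_b = np.empty(rec_cap, dtype=np.int8)
    rec_count = np.zeros(1, dtype=np.int64)
    rec_chunks: list[tuple] = []

    times = [0.0]
    snaps = [state.copy()]
    for obs in observers:
        obs(0.0, state)

    t = 0.0
    n_events = 0
    early = False
    ticks = _snapshot_ticks(params)
    for tick_i, tick in enumerate(ticks):
        while True:
            t, ne, status = _advance(
                ws.grid, ws.site_of, ws.bonds, ws.used, ws.nbr,
                np.int64(params.lam), params.k_bond, params.k_break, params.k_move,
                ws.move_table,
                ws.parent, ws.csize, ws.ok, ws.nnb, ws.root_of, ws.mem, ws.newsite,
                ws.ev_kind, ws.ev_a, ws.ev_b, ws.ev_rate,
                t, tick, rng,
                record_exchange, ex_open, ex_pbuf, ex_bbuf, ex_rbuf, ex_count,
                record_events, rec_t, rec_kind, rec_a, rec_b, rec_count,
            )
            n_events += ne
            if status == _REACHED:
                break
            if status == _EXHAUSTED:
                early = True
                break
            if status == _EX_FULL:
                ex_cap *= 2
                ex_pbuf = np.concatenate([ex_pbuf, np.empty_like(ex_pbuf)])
                ex_bbuf = np.concatenate([ex_bbuf, np.empty_like(ex_bbuf)])
                ex_rbuf = np.concatenate([ex_rbuf, np.empty_like(ex_rbuf)])
            elif status == _REC_FULL:
                k = int(rec_count[0])
                rec_chunks.append(
                    (rec_t[:k].copy(), rec_kind[:k].copy(),
                     rec_a[:k].copy(), rec_b[:k].copy())
                )
                rec_count[0] = 0
        remaining = ticks[tick_i:] if early else [tick]
        for snap_time in remaining:  # early exit: frozen state fills the ticks
            snap = ws.to_state(snap_time)
            times.append(snap_time)
            snaps.append(snap)
            for obs in observers:
                obs(snap_time, snap)
        if early:
            break

    traj = Trajectory(
        params=params,
        snapshot_times=times,
        snapshots=snaps,
        n_events=n_events,
        terminated_early=early,
    )
    if record_exchange:
        k = int(ex_count[0])
        traj.exchange = ExchangeEventLog(
            particles=ex_pbuf[:k].astype(np.int64),
            burial=ex_bbuf[:k].copy(),
            release=ex_rbuf[:k].copy(),
            censored_burials=ex_open[ex_open >= 0].copy(),
        )
    if record_events:
        import pandas as pd

        k = int(rec_count[0])
        rec_chunks.append(
            (rec_t[:k].copy(), rec_kind[:k].copy(), rec_a[:k].copy(), rec_b[:k].copy())
        )
        kinds = {0: "monomer_move", 1: "cluster_move", 2: "bond_form", 3: "bond_break"}
        traj.event_log = pd.DataFrame(
            {
                "time": np.concatenate([c[0] for c in rec_chunks]),
                "kind": [kinds[int(x)] for c in rec_chunks for x in c[1]],
                "a": np.concatenate([c[2] for c in rec_chunks]),
                "b": np.concatenate([c[3] for c in rec_chunks]),
            }
        )
    return traj
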