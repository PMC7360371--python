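"""Gillespie (kinetic Monte Carlo) event engine for the lattice model.

The model is a continuous-time Markov jump process.  For a configuration of
the lattice the feasible events and their rates are:

* ``monomer_move`` — particle ``p`` hops one site into an empty target, at
  rate ``k_diff * exp(-E_p)`` per feasible direction, where ``E_p`` is the
  particle's total interaction energy (engaged bonds times ``eps_sp`` plus
  occupied-neighbor contacts times ``eps_ns``, in kT).  A hop severs all of
  the mover's bonds and contacts — this is how a monomer escapes a cluster.
* ``cluster_move`` — a whole adjacency-connected cluster of size
  ``S >= 2`` translates rigidly by one site, at rate ``k_diff / S`` per
  direction whose targets are all empty or belong to the same cluster.
* ``bond_form`` — an adjacent pair with spare valency on both sides gains
  one specific bond, at rate ``k_bond`` per pair.
* ``bond_break`` — an existing bond breaks at rate
  ``k_break = k_bond * exp(-eps_sp)`` per bond (counting multiplicity).

Between events the waiting time is exponential: ``dt = -ln(z) / r_total``.
Blocked moves are never listed (no null events: they would distort the
Gillespie time axis).  The engine re-enumerates the full event set after
every event; :mod:`stickerlattice._kernel` provides a compiled loop with the
same semantics for production runs, and this module is the readable
reference it is tested against.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .clusters import label_clusters
from .lattice import (
    DIRECTIONS,
    LatticeState,
    SimParams,
    init_lattice,
    interaction_energy,
    place_bond,
    remove_bond,
)

__all__ = [
    "Event",
    "EventSet",
    "Trajectory",
    "enumerate_events",
    "draw_event",
    "waiting_time",
    "apply_event",
    "run_trajectory",
]

MONOMER_MOVE = "monomer_move"
CLUSTER_MOVE = "cluster_move"
BOND_FORM = "bond_form"
BOND_BREAK = "bond_break"


@dataclass(frozen=True)
class Event:
    """One feasible transition.

    Payload semantics by kind:

    * ``monomer_move``: ``a`` = particle id, ``b`` = direction (0..3 = NSEW)
    * ``cluster_move``: ``a`` = cluster id (smallest member id),
      ``b`` = direction; ``members`` holds the member tuple
    * ``bond_form`` / ``bond_break``: ``(a, b)`` = ordered particle pair
    """

    kind: str
    a: int
    b: int
    members: tuple[int, ...] | None = None


@dataclass
class EventSet:
    events: list[Event]
    rates: np.ndarray
    r_total: float

    def __len__(self) -> int:
        return len(self.events)


def enumerate_events(state: LatticeState, params: SimParams) -> EventSet:
    """List every feasible event with its rate for the current state.

    This is the reference enumeration: a naive, complete re-scan of all
    particles, pairs and clusters.  An empty event set is legal and means
    the run must terminate (flagged by the caller).
    """
    if state.L < 3:
        raise ValueError("event enumeration requires L >= 3 (unambiguous adjacency)")
    events: list[Event] = []
    rates: list[float] = []
    k_move = params.k_move
    L = state.L

    # (a) monomer moves: every empty von Neumann target, Boltzmann-suppressed
    for p in range(state.n_particles):
        rate = k_move * math.exp(-interaction_energy(state, params, p))
        r, c = state.positions[p]
        for d in range(4):
            if state.grid[state.neighbor_site(r, c, d)] < 0:
                events.append(Event(MONOMER_MOVE, p, d))
                rates.append(rate)

    # (b) rigid cluster translations, rate scaled down by cluster size
    labeling = label_clusters(state)
    for lbl in range(labeling.n_clusters):
        size = int(labeling.sizes[lbl])
        if size < 2:
            continue
        members = labeling.members(lbl)
        cid = int(members.min())
        for d in range(4):
            dr, dc = DIRECTIONS[d]
            feasible = True
            for p in members:
                r, c = state.positions[p]
                q = state.grid[(r + dr) % L, (c + dc) % L]
                if q >= 0 and labeling.labels[q] != lbl:
                    feasible = False
                    break
            if feasible:
                events.append(
                    Event(CLUSTER_MOVE, cid, d, members=tuple(int(m) for m in members))
                )
                rates.append(k_move / size)

    # (c, d) bond events over adjacent pairs (S and E scan: each pair once)
    for p in range(state.n_particles):
        r, c = state.positions[p]
        for dr, dc in ((1, 0), (0, 1)):
            q = int(state.grid[(r + dr) % L, (c + dc) % L])
            if q < 0:
                continue
            lo, hi = min(p, q), max(p, q)
            if (
                params.k_bond > 0
                and state.used_valency[p] < params.lam
                and state.used_valency[q] < params.lam
            ):
                events.append(Event(BOND_FORM, lo, hi))
                rates.append(params.k_bond)
            mult = state.bonds.get((lo, hi), 0)
            if mult:
                k_break = params.k_break
                for _ in range(mult):  # one event per bond, counting multiplicity
                    events.append(Event(BOND_BREAK, lo, hi))
                    rates.append(k_break)

    rates_arr = np.asarray(rates, dtype=np.float64)
    return EventSet(events, rates_arr, float(rates_arr.sum()))


def draw_event(events: EventSet, u: float) -> Event:
    """Select the event whose cumulative-rate interval contains ``u * r_total``."""
    if events.r_total <= 0:
        raise ValueError("cannot draw from an empty event set (r_total = 0)")
    if not 0 <= u < 1:
        raise ValueError("u must lie in [0, 1)")
    target = u * events.r_total
    acc = 0.0
    for ev, rate in zip(events.events, events.rates):
        acc += rate
        if target < acc:
            return ev
    return events.events[-1]  # guard against accumulation round-off


def waiting_time(r_total: float, u: float) -> float:
    """Exponential Gillespie waiting time ``-ln(u) / r_total``."""
    if r_total <= 0:
        raise ValueError("r_total must be positive")
    if not 0 < u <= 1:
        raise ValueError("u must lie in (0, 1]")
    return -math.log(u) / r_total


def apply_event(state: LatticeState, params: SimParams, event: Event) -> LatticeState:
    """Execute one event, mutating and returning the state."""
    if event.kind == MONOMER_MOVE:
        p = event.a
        r, c = state.positions[p]
        nr, nc = state.neighbor_site(r, c, event.b)
        if state.grid[nr, nc] >= 0:
            raise ValueError(f"stale event: target site {(nr, nc)} occupied")
        # a hop severs every bond of the mover
        for key in [k for k in state.bonds if p in k]:
            q = key[0] if key[1] == p else key[1]
            m = state.bonds.pop(key)
            state.used_valency[p] -= m
            state.used_valency[q] -= m
        state.grid[r, c] = -1
        state.grid[nr, nc] = p
        state.positions[p] = (nr, nc)
    elif event.kind == CLUSTER_MOVE:
        members = event.members
        dr, dc = DIRECTIONS[event.b]
        L = state.L
        member_set = set(members)
        targets = {}
        for p in members:
            r, c = state.positions[p]
            t = ((r + dr) % L, (c + dc) % L)
            occ = state.grid[t]
            if occ >= 0 and int(occ) not in member_set:
                raise ValueError("stale event: cluster translation collides")
            targets[p] = t
        for p in members:
            r, c = state.positions[p]
            state.grid[r, c] = -1
        for p, t in targets.items():
            state.grid[t] = p
            state.positions[p] = t
        # internal bonds ride along: relative geometry is unchanged
    elif event.kind == BOND_FORM:
        place_bond(state, params, event.a, event.b)
    elif event.kind == BOND_BREAK:
        remove_bond(state, params, event.a, event.b)
    else:
        raise ValueError(f"unknown event kind {event.kind!r}")
    return state


@dataclass
class Trajectory:
    """Result of one kMC run: snapshots plus optional event-level records."""

    params: SimParams
    snapshot_times: list[float]
    snapshots: list[LatticeState]
    n_events: int = 0
    terminated_early: bool = False
    exchange: "object | None" = None      # ExchangeEventLog when recorded
    event_log: "object | None" = None     # DataFrame (time, kind, a, b) when recorded

    @property
    def final_state(self) -> LatticeState:
        return self.snapshots[-1]


def _snapshot_ticks(params: SimParams) -> list[float]:
    """Snapshot times after t=0 (the initial state is always recorded)."""
    if params.t_end <= 0:
        return []
    if params.snapshot_interval is None or params.snapshot_interval <= 0:
        return [params.t_end]
    ticks = list(
        np.arange(params.snapshot_interval, params.t_end, params.snapshot_interval)
    )
    ticks.append(params.t_end)
    return ticks


def run_trajectory(
    params: SimParams,
    observers: Sequence[Callable[[float, LatticeState], None]] = (),
    *,
    record_exchange: bool = False,
    record_events: bool = False,
    engine: str = "fast",
    initial_state: LatticeState | None = None,
) -> Trajectory:
    """Simulate one seeded trajectory until ``t_end``.

    ``observers`` are called as ``f(time, state)`` at every snapshot tick
    (including the initial state).  ``engine="fast"`` uses the compiled
    kernel; ``engine="python"`` the reference loop here (which can also log
    every single event when ``record_events`` is set).  Identical seeds give
    identical trajectories within an engine.
    """
    if engine == "fast":
        from ._kernel import run_trajectory_fast

        return run_trajectory_fast(
            params,
            observers,
            record_exchange=record_exchange,
            record_events=record_events,
            initial_state=initial_state,
        )
    if engine != "python":
        raise ValueError("engine must be 'fast' or 'python'")

    from .observables import ExchangeTracker

    # dynamics stream is decoupled from the placement stream (params.seed)
    rng = np.random.default_rng((params.seed, 7919))
    state = init_lattice(params) if initial_state is None else initial_state.copy()
    tracker = ExchangeTracker(state.n_particles) if record_exchange else None
    if tracker is not None:
        for p in range(state.n_particles):
            tracker.update(p, state.neighbor_count(p), 0.0)

    times: list[float] = [0.0]
    snaps: list[LatticeState] = [state.copy()]
    for obs in observers:
        obs(0.0, state)
    log_rows: list[tuple[float, str, int, int]] = []

    ticks = _snapshot_ticks(params)
    tick_i = 0
    t = 0.0
    n_events = 0
    early = False
    while t < params.t_end:
        evset = enumerate_events(state, params)
        if evset.r_total <= 0:
            warnings.warn("no feasible events; trajectory terminated early")
            early = True
            break
        dt = waiting_time(evset.r_total, 1.0 - rng.random())  # z in (0, 1]
        t_next = t + dt
        while tick_i < len(ticks) and ticks[tick_i] <= min(t_next, params.t_end):
            state.time = ticks[tick_i]
            times.append(ticks[tick_i])
            snaps.append(state.copy())
            for obs in observers:
                obs(ticks[tick_i], state)
            tick_i += 1
        if t_next >= params.t_end:
            t = params.t_end
            break
        ev = draw_event(evset, rng.random())
        apply_event(state, params, ev)
        t = t_next
        state.time = t
        n_events += 1
        if record_events:
            log_rows.append((t, ev.kind, ev.a, ev.b))
        if tracker is not None:
            for p in range(state.n_particles):
                tracker.update(p, state.neighbor_count(p), t)
    # flush remaining ticks (early termination: state persists to t_end)
    while tick_i < len(ticks):
        state.time = ticks[tick_i]
        times.append(ticks[tick_i])
        snaps.append(state.copy())
        for obs in observers:
            obs(ticks[tick_i], state)
        tick_i += 1

    traj = Trajectory(
        params=params,
        snapshot_times=times,
        snapshots=snaps,
        n_events=n_events,
        terminated_early=early,
    )
    if tracker is not None:
        traj.exchange = tracker.finish(params.t_end)
    if record_events:
        import pandas as pd

        traj.event_log = pd.DataFrame(log_rows, columns=["time", "kind", "a", "b"])
    return traj
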