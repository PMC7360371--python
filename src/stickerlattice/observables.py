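"""Trajectory-level observables and parameter-sweep drivers.

* Monomer exchange times: the mean first-passage time (MFPT) for a particle
  to go from *buried* (four occupied neighbors, full coordination on the
  square lattice) to *completely free* (zero occupied neighbors).  This is
  the model's analogue of FRAP-style molecular exchange between a droplet
  and the dilute phase.  Burials still open when the run ends are counted
  as censored and never averaged in.
* Valency utilization inside vs outside the largest cluster.
* Phase classification of a parameter point into {NoPS, microphase,
  macrophase} from replicate-averaged order parameters.
* Cartesian parameter sweeps, the critical interaction strength
  (smallest ``eps_sp`` whose mean ``L_clus`` reaches 0.5), and the
  diffusion-rate scan.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .clusters import ClusterLabeling, label_clusters, largest_cluster_fraction
from .engine import Trajectory, run_trajectory
from .lattice import LatticeState, SimParams

__all__ = [
    "ExchangeEventLog",
    "ExchangeTracker",
    "MFPTResult",
    "PhasePoint",
    "record_exchange_events",
    "mean_exchange_time",
    "km_mean_lower_bound",
    "valency_utilization",
    "classify_phase",
    "sweep",
    "phase_table",
    "epsilon_scan",
    "critical_epsilon",
    "diffusion_scan",
    "replicate_seed",
    "mfpt_experiment",
]

BURIED_NEIGHBORS = 4  # full von Neumann coordination opens a burial
FREE_NEIGHBORS = 0    # zero occupied neighbors closes it


@dataclass
class ExchangeEventLog:
    """Completed and censored burial->release first-passage events."""

    particles: np.ndarray        # (n,) int64, particle id per completed event
    burial: np.ndarray           # (n,) float64, burial times (s)
    release: np.ndarray          # (n,) float64, release times (s)
    censored_burials: np.ndarray  # burial times still open at t_end

    @property
    def passage_times(self) -> np.ndarray:
        return self.release - self.burial

    @property
    def n_completed(self) -> int:
        return len(self.burial)

    @property
    def n_censored(self) -> int:
        return len(self.censored_burials)


class ExchangeTracker:
    """Streaming state machine detecting burial/release transitions.

    Feed it the current occupied-neighbor count of a particle whenever the
    state changes; a burial opens when the count reaches 4 while closed and
    closes (one completed event) when it next reaches 0.  Repeated burials
    without an intervening release never nest: the open interval persists.
    """

    def __init__(self, n_particles: int) -> None:
        self.open_since = np.full(n_particles, -1.0)
        self._particles: list[int] = []
        self._burial: list[float] = []
        self._release: list[float] = []

    def update(self, p: int, n_neighbors: int, t: float) -> None:
        if n_neighbors >= BURIED_NEIGHBORS and self.open_since[p] < 0:
            self.open_since[p] = t
        elif n_neighbors <= FREE_NEIGHBORS and self.open_since[p] >= 0:
            self._particles.append(p)
            self._burial.append(self.open_since[p])
            self._release.append(t)
            self.open_since[p] = -1.0

    def finish(self, t_end: float) -> ExchangeEventLog:
        del t_end  # open intervals are censored regardless of horizon
        return ExchangeEventLog(
            particles=np.asarray(self._particles, dtype=np.int64),
            burial=np.asarray(self._burial),
            release=np.asarray(self._release),
            censored_burials=self.open_since[self.open_since >= 0].copy(),
        )


def record_exchange_events(source) -> ExchangeEventLog:
    """Extract the exchange log from a trajectory or a transition stream.

    ``source`` may be a :class:`Trajectory` run with
    ``record_exchange=True``, or an iterable of ``(time, particle,
    neighbor_count)`` transition records (replayed through the state
    machine, e.g. for scripted test sequences).
    """
    if isinstance(source, Trajectory):
        if source.exchange is None:
            raise ValueError(
                "trajectory carries no exchange log; rerun with record_exchange=True"
            )
        return source.exchange
    records = list(source)
    n = max((p for _, p, _ in records), default=-1) + 1
    tracker = ExchangeTracker(n)
    for t, p, nnb in records:
        tracker.update(p, nnb, t)
    return tracker.finish(records[-1][0] if records else 0.0)


@dataclass
class MFPTResult:
    mean: float
    sd: float
    n_events: int
    n_censored: int

    @property
    def censoring_fraction(self) -> float:
        total = self.n_events + self.n_censored
        return self.n_censored / total if total else 0.0


def mean_exchange_time(log: ExchangeEventLog) -> MFPTResult:
    """Arithmetic mean of completed passage times, with censoring report.

    With zero completed events the mean is NaN (sentinel) and the
    censoring fraction still reports how many burials never resolved.
    """
    times = log.passage_times
    if len(times) == 0:
        return MFPTResult(math.nan, math.nan, 0, log.n_censored)
    sd = float(times.std(ddof=1)) if len(times) > 1 else 0.0
    return MFPTResult(float(times.mean()), sd, len(times), log.n_censored)


def km_mean_lower_bound(log: ExchangeEventLog, t_end: float) -> float:
    """Kaplan-Meier restricted-mean passage time including censored burials.

    Treats each open burial as right-censored at ``t_end``; the restricted
    mean (integral of the KM survival curve up to the largest observed
    duration) is a conservative cross-check that the naive mean of
    completed events is not biased low by dropping censored intervals.
    """
    durations = np.concatenate([log.passage_times, t_end - log.censored_burials])
    observed = np.concatenate(
        [np.ones(log.n_completed, bool), np.zeros(log.n_censored, bool)]
    )
    if len(durations) == 0:
        return math.nan
    order = np.argsort(durations)
    durations, observed = durations[order], observed[order]
    n = len(durations)
    surv, t_prev, mean = 1.0, 0.0, 0.0
    for i, (d, obs) in enumerate(zip(durations, observed)):
        mean += surv * (d - t_prev)
        t_prev = d
        if obs:
            surv *= 1.0 - 1.0 / (n - i)
    return float(mean)


def valency_utilization(
    state: LatticeState, labeling: ClusterLabeling, lam: int
) -> tuple[float, float]:
    """Fraction of free valencies inside vs outside the largest cluster.

    Returns ``(inside, outside)`` where each is ``1 - sum(used) / (lam *
    count)`` over the respective particle set (NaN when the set is empty).
    """
    if lam < 1:
        raise ValueError("valency utilization is undefined for lam = 0")
    inside = labeling.labels == 0  # canonical label 0 is the largest cluster
    out = ~inside

    def frac(mask: np.ndarray) -> float:
        count = int(mask.sum())
        if count == 0:
            return math.nan
        return 1.0 - float(state.used_valency[mask].sum()) / (lam * count)

    return frac(inside), frac(out)


def classify_phase(
    mean_l_clus: float,
    mean_bonds_per_particle: float,
    n_tot: int,
    *,
    macro_threshold: float = 0.5,
    nops_l_clus: float | None = None,
    nops_bonds: float = 0.5,
) -> str:
    """Classify a replicate-averaged parameter point.

    ``macrophase`` when the largest cluster holds at least 50% of all
    monomers (the operational system-spanning criterion); ``NoPS`` when the
    largest cluster stays at the few-particle level
    (``L_clus <= max(5/N_tot, 0.05)``) with negligible bonding; otherwise
    ``microphase`` (many coexisting clusters).  Thresholds are arguments,
    not constants.
    """
    if math.isnan(mean_l_clus):
        raise ValueError("mean L_clus unavailable (missing replicates?)")
    if nops_l_clus is None:
        nops_l_clus = max(5.0 / n_tot, 0.05)
    if mean_l_clus >= macro_threshold:
        return "macrophase"
    if mean_l_clus <= nops_l_clus and mean_bonds_per_particle < nops_bonds:
        return "NoPS"
    return "microphase"


# ---------------------------------------------------------------------------
# Sweep drivers
# ---------------------------------------------------------------------------

def replicate_seed(base_seed: int, cell_index: int, replicate: int) -> int:
    """Deterministic per-replicate seed, independent of execution order."""
    ss = np.random.SeedSequence((int(base_seed), int(cell_index), int(replicate)))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PhasePoint:
    """Replicate-averaged summary of one sweep grid cell."""

    coords: dict[str, float]
    mean_l_clus: float
    sd_l_clus: float
    mean_n_clusters: float
    mean_bonds_per_particle: float
    classification: str
    n_replicates: int
    seeds: list[int] = field(default_factory=list)
    l_clus_values: list[float] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)


def _final_metrics(traj: Trajectory) -> tuple[float, int, float]:
    state = traj.final_state
    lab = label_clusters(state)
    l_clus = largest_cluster_fraction(lab, state.n_particles)
    bonds_pp = sum(state.bonds.values()) / state.n_particles
    return l_clus, lab.n_clusters, bonds_pp


def sweep(
    grid: dict[str, Sequence],
    template: SimParams,
    replicates: int,
    base_seed: int,
    *,
    engine: str = "fast",
) -> list[PhasePoint]:
    """Run the Cartesian product of ``grid`` over seeded replicates.

    Each replicate is an independent trajectory of ``template.t_end``
    simulated seconds whose seed derives from ``(base_seed, cell index,
    replicate index)``, so results do not depend on execution order.
    Failures in one cell are recorded and do not abort the sweep.
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("sweep grid must be a non-empty Cartesian product")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    names = list(grid)
    points: list[PhasePoint] = []
    for cell_index, combo in enumerate(itertools.product(*(grid[k] for k in names))):
        coords = dict(zip(names, combo))
        seeds, l_vals, n_vals, b_vals, errors = [], [], [], [], []
        for rep in range(replicates):
            seed = replicate_seed(base_seed, cell_index, rep)
            seeds.append(seed)
            try:
                params = template.with_(seed=seed, **coords)
                traj = run_trajectory(params, engine=engine)
                l_clus, n_clus, bonds_pp = _final_metrics(traj)
                l_vals.append(l_clus)
                n_vals.append(n_clus)
                b_vals.append(bonds_pp)
            except Exception as exc:  # record, keep sweeping
                errors.append(f"rep {rep}: {exc}")
        if l_vals:
            mean_l = float(np.mean(l_vals))
            sd_l = float(np.std(l_vals, ddof=1)) if len(l_vals) > 1 else 0.0
            n_tot = template.with_(**coords).n_particles
            cls = classify_phase(mean_l, float(np.mean(b_vals)), n_tot)
        else:
            mean_l, sd_l, cls = math.nan, math.nan, "failed"
        points.append(
            PhasePoint(
                coords=coords,
                mean_l_clus=mean_l,
                sd_l_clus=sd_l,
                mean_n_clusters=float(np.mean(n_vals)) if n_vals else math.nan,
                mean_bonds_per_particle=float(np.mean(b_vals)) if b_vals else math.nan,
                classification=cls,
                n_replicates=len(l_vals),
                seeds=seeds,
                l_clus_values=l_vals,
                errors=errors,
            )
        )
    return points


def phase_table(points: Iterable[PhasePoint]) -> pd.DataFrame:
    """Flatten sweep results into a DataFrame (one row per grid cell)."""
    rows = []
    for pt in points:
        row = dict(pt.coords)
        row.update(
            mean_l_clus=pt.mean_l_clus,
            sd_l_clus=pt.sd_l_clus,
            mean_n_clusters=pt.mean_n_clusters,
            mean_bonds_per_particle=pt.mean_bonds_per_particle,
            classification=pt.classification,
            n_replicates=pt.n_replicates,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def epsilon_scan(
    template: SimParams,
    eps_values: Sequence[float],
    replicates: int,
    base_seed: int,
    *,
    engine: str = "fast",
) -> pd.DataFrame:
    """Mean ``L_clus`` versus specific-interaction strength (one sweep row)."""
    points = sweep(
        {"eps_sp": list(eps_values)}, template, replicates, base_seed, engine=engine
    )
    return phase_table(points)


def critical_epsilon(
    eps_values: Sequence[float],
    mean_l_clus: Sequence[float],
    threshold: float = 0.5,
) -> float:
    """Smallest grid ``eps_sp`` whose mean ``L_clus`` reaches ``threshold``.

    The grid must be sorted ascending.  Returns NaN (sentinel) when the
    threshold is never reached.
    """
    eps = np.asarray(eps_values, dtype=float)
    if len(eps) == 0 or (np.diff(eps) <= 0).any():
        raise ValueError("eps_sp grid must be non-empty and sorted ascending")
    means = np.asarray(mean_l_clus, dtype=float)
    hits = np.flatnonzero(means >= threshold)
    return float(eps[hits[0]]) if len(hits) else math.nan


def diffusion_scan(
    k_diff_values: Sequence[float],
    template: SimParams,
    replicates: int,
    base_seed: int,
    *,
    engine: str = "fast",
) -> pd.DataFrame:
    """Mean ``L_clus`` at fixed simulated ``t_end`` for varying ``k_diff``.

    ``k_bond`` stays fixed at the template value while the diffusion rate
    changes, mimicking a viscosity change: slower diffusion leaves less
    time for clusters to grow within the same simulated window.
    """
    points = sweep(
        {"k_diff": list(k_diff_values)}, template, replicates, base_seed, engine=engine
    )
    df = phase_table(points)
    df["l_clus_values"] = [pt.l_clus_values for pt in points]
    return df


def mfpt_experiment(
    template: SimParams,
    replicates: int,
    base_seed: int,
    *,
    engine: str = "fast",
) -> tuple[MFPTResult, ExchangeEventLog]:
    """Pool exchange events across seeded replicate trajectories.

    Events are pooled over particles and replicates (each completed
    burial->free passage is one sample).
    """
    logs: list[ExchangeEventLog] = []
    for rep in range(replicates):
        seed = replicate_seed(base_seed, 0, rep)
        traj = run_trajectory(
            template.with_(seed=seed), record_exchange=True, engine=engine
        )
        logs.append(traj.exchange)
    pooled = ExchangeEventLog(
        particles=np.concatenate([lg.particles for lg in logs]),
        burial=np.concatenate([lg.burial for lg in logs]),
        release=np.concatenate([lg.release for lg in logs]),
        censored_burials=np.concatenate([lg.censored_burials for lg in logs]),
    )
    return mean_exchange_time(pooled), pooled
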