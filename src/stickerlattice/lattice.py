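"""2D lattice data model for multivalent sticker-spacer particles.

Particles live on an L x L square lattice with periodic boundaries and a
von Neumann (4-site) neighborhood.  Each particle carries a fixed valency
``lam``: the maximum number of specific (saturable) bonds it can engage in.
A pair of nearest-neighbor particles may share *several* specific bonds, as
long as neither side exceeds its valency — the bond container is therefore a
multiset over unordered particle pairs.  Occupying adjacent sites also incurs
a non-saturable, isotropic contact attraction of strength ``eps_ns``.

All energies are in units of kT; all rates in 1/s; the lattice constant is 1.
Coordinates are 0-based ``(row, col)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, TextIO

import numpy as np

__all__ = [
    "DIRECTIONS",
    "DIR_NAMES",
    "OPPOSITE",
    "SimParams",
    "LatticeState",
    "init_lattice",
    "interaction_energy",
    "place_bond",
    "remove_bond",
    "write_snapshot",
    "read_snapshot",
]

# Direction encoding shared by every module: N, S, E, W.
DIRECTIONS: np.ndarray = np.array([(-1, 0), (1, 0), (0, 1), (0, -1)], dtype=np.int64)
DIR_NAMES: tuple[str, ...] = ("N", "S", "E", "W")
OPPOSITE: tuple[int, ...] = (1, 0, 3, 2)


@dataclass(frozen=True)
class SimParams:
    """Parameter set for one kinetic Monte Carlo run.

    Either ``n_particles`` or ``phi_lattice`` must be given; the other is
    derived (``N_tot = round(phi_lattice * L**2)``).

    Parameters
    ----------
    L : int
        Lattice sites per side.
    lam : int
        Valency: maximum specific bonds per particle (>= 0).
    eps_sp, eps_ns : float
        Specific-bond and non-specific contact energies, in kT (>= 0).
    k_diff, k_bond : float
        Free-diffusion rate per direction and bond-formation rate per
        eligible pair, in 1/s.  The bond breakage rate is never stored: it
        is always recomputed as ``k_bond * exp(-eps_sp)``.
    t_end : float
        Simulated duration in seconds.
    seed : int
        Base seed for the trajectory RNG.
    snapshot_interval : float or None
        Simulated seconds between recorded snapshots (None: only the
        initial and final states are kept).
    move_rate_convention : str
        ``"per_direction"`` (default): each feasible direction is one event
        at rate ``k_diff``.  ``"total"``: the per-direction rate is
        ``k_diff / 4`` so that an isolated particle hops at total rate
        ``k_diff``.
    """

    L: int
    lam: int
    eps_sp: float
    eps_ns: float = 0.35
    n_particles: int | None = None
    phi_lattice: float | None = None
    k_diff: float = 1.0
    k_bond: float = 1.0
    t_end: float = 7200.0
    seed: int = 0
    snapshot_interval: float | None = None
    move_rate_convention: str = "per_direction"

    def __post_init__(self) -> None:
        if self.L < 2:
            raise ValueError(f"lattice size L={self.L} must be >= 2")
        if self.n_particles is None and self.phi_lattice is None:
            raise ValueError("one of n_particles or phi_lattice is required")
        if self.n_particles is None:
            if not 0.0 < self.phi_lattice <= 1.0:
                raise ValueError(
                    f"phi_lattice={self.phi_lattice} must lie in (0, 1]"
                )
            object.__setattr__(
                self, "n_particles", int(round(self.phi_lattice * self.L**2))
            )
        if self.phi_lattice is None:
            object.__setattr__(self, "phi_lattice", self.n_particles / self.L**2)
        if not 0 < self.n_particles <= self.L**2:
            raise ValueError(
                f"n_particles={self.n_particles} must lie in (0, L^2={self.L**2}]"
            )
        if self.lam < 0:
            raise ValueError("valency lam must be >= 0")
        if self.eps_sp < 0 or self.eps_ns < 0:
            raise ValueError("interaction energies must be >= 0 (kT)")
        if self.k_diff <= 0:
            raise ValueError("k_diff must be > 0")
        if self.k_bond < 0:
            raise ValueError("k_bond must be >= 0")
        if self.t_end < 0:
            raise ValueError("t_end must be >= 0")
        if self.move_rate_convention not in ("per_direction", "total"):
            raise ValueError(
                "move_rate_convention must be 'per_direction' or 'total'"
            )

    @property
    def n_tot(self) -> int:
        return self.n_particles

    @property
    def k_break(self) -> float:
        """Bond breakage rate ``k_bond * exp(-eps_sp)`` (detailed balance)."""
        return self.k_bond * float(np.exp(-self.eps_sp))

    @property
    def k_move(self) -> float:
        """Per-direction hop rate implied by the rate convention."""
        return self.k_diff if self.move_rate_convention == "per_direction" else self.k_diff / 4.0

    def with_(self, **kwargs) -> "SimParams":
        """Return a copy with fields replaced (re-validated)."""
        if "phi_lattice" in kwargs and "n_particles" not in kwargs:
            kwargs.setdefault("n_particles", None)
        return replace(self, **kwargs)


@dataclass
class LatticeState:
    """Mutable configuration of the lattice system.

    Attributes
    ----------
    L : int
        Lattice side length.
    grid : (L, L) int32 array
        Site occupancy: -1 for empty, else the particle id.
    positions : (N, 2) int64 array
        ``positions[p] = (row, col)``; consistent with ``grid``.
    bonds : dict[(int, int), int]
        Multiset of specific bonds: unordered pair (min id, max id) ->
        multiplicity >= 1.
    used_valency : (N,) int64 array
        Specific bonds currently engaged per particle.
    time : float
        Simulated seconds.
    """

    L: int
    grid: np.ndarray
    positions: np.ndarray
    bonds: dict[tuple[int, int], int] = field(default_factory=dict)
    used_valency: np.ndarray = None
    time: float = 0.0

    def __post_init__(self) -> None:
        if self.used_valency is None:
            self.used_valency = np.zeros(len(self.positions), dtype=np.int64)

    @property
    def n_particles(self) -> int:
        return len(self.positions)

    def neighbor_site(self, r: int, c: int, d: int) -> tuple[int, int]:
        dr, dc = DIRECTIONS[d]
        return (r + dr) % self.L, (c + dc) % self.L

    def neighbors_of(self, p: int) -> Iterator[tuple[int, int]]:
        """Yield ``(direction, particle id)`` for occupied adjacent sites."""
        r, c = self.positions[p]
        for d in range(4):
            q = self.grid[self.neighbor_site(r, c, d)]
            if q >= 0:
                yield d, int(q)

    def neighbor_count(self, p: int) -> int:
        return sum(1 for _ in self.neighbors_of(p))

    def bond_multiplicity(self, p: int, q: int) -> int:
        return self.bonds.get((min(p, q), max(p, q)), 0)

    def copy(self) -> "LatticeState":
        return LatticeState(
            L=self.L,
            grid=self.grid.copy(),
            positions=self.positions.copy(),
            bonds=dict(self.bonds),
            used_valency=self.used_valency.copy(),
            time=self.time,
        )

    def validate(self, lam: int | None = None) -> None:
        """Check the structural invariants; raise AssertionError on violation."""
        occ = np.argwhere(self.grid >= 0)
        assert len(occ) == self.n_particles, "grid/positions count mismatch"
        for p, (r, c) in enumerate(self.positions):
            assert self.grid[r, c] == p, f"grid/positions disagree for particle {p}"
        used = np.zeros(self.n_particles, dtype=np.int64)
        for (p, q), m in self.bonds.items():
            assert p < q and m >= 1, "bond keys must be ordered pairs with m >= 1"
            rp, cp = self.positions[p]
            adjacent = any(
                tuple(self.positions[q]) == self.neighbor_site(rp, cp, d)
                for d in range(4)
            )
            assert adjacent, f"bond {(p, q)} connects non-adjacent sites"
            used[p] += m
            used[q] += m
        assert np.array_equal(used, self.used_valency), "used_valency out of sync"
        if lam is not None:
            assert (self.used_valency <= lam).all(), "valency exceeded"


def init_lattice(params: SimParams, rng_seed: int | None = None) -> LatticeState:
    """Place ``N_tot`` particles uniformly at random on distinct sites.

    No bonds exist initially and the clock starts at 0.  The same seed
    reproduces the same configuration bit for bit.
    """
    n, L = params.n_particles, params.L
    rng = np.random.default_rng(params.seed if rng_seed is None else rng_seed)
    sites = rng.choice(L * L, size=n, replace=False)
    grid = np.full((L, L), -1, dtype=np.int32)
    positions = np.empty((n, 2), dtype=np.int64)
    for p, s in enumerate(sites):
        r, c = divmod(int(s), L)
        grid[r, c] = p
        positions[p] = (r, c)
    return LatticeState(L=L, grid=grid, positions=positions)


def interaction_energy(state: LatticeState, params: SimParams, p: int) -> float:
    """Total interaction energy of particle ``p`` in kT.

    ``used_valency[p] * eps_sp + (occupied neighbor sites) * eps_ns``: every
    engaged specific bond contributes ``eps_sp`` and every occupied adjacent
    site one ``eps_ns`` contact (once per pair, not per direction).
    """
    if not 0 <= p < state.n_particles:
        raise KeyError(f"unknown particle id {p}")
    return float(
        state.used_valency[p] * params.eps_sp
        + state.neighbor_count(p) * params.eps_ns
    )


def _require_adjacent(state: LatticeState, p: int, q: int) -> None:
    rp, cp = state.positions[p]
    if not any(
        tuple(state.positions[q]) == state.neighbor_site(rp, cp, d) for d in range(4)
    ):
        raise ValueError(f"particles {p} and {q} are not nearest neighbors")


def place_bond(state: LatticeState, params: SimParams, p: int, q: int) -> LatticeState:
    """Add one specific bond between adjacent particles ``p`` and ``q``.

    Both particles must have spare valency.  Returns the mutated state.
    """
    if p == q:
        raise ValueError("cannot bond a particle to itself")
    _require_adjacent(state, p, q)
    if state.used_valency[p] >= params.lam or state.used_valency[q] >= params.lam:
        raise ValueError(
            f"valency exceeded: bond {p}-{q} with lam={params.lam}, "
            f"used={state.used_valency[p]},{state.used_valency[q]}"
        )
    key = (min(p, q), max(p, q))
    state.bonds[key] = state.bonds.get(key, 0) + 1
    state.used_valency[p] += 1
    state.used_valency[q] += 1
    return state


def remove_bond(state: LatticeState, params: SimParams, p: int, q: int) -> LatticeState:
    """Remove one specific bond between ``p`` and ``q`` (multiplicity -1)."""
    key = (min(p, q), max(p, q))
    m = state.bonds.get(key, 0)
    if m < 1:
        raise ValueError(f"no bond between {p} and {q} to remove")
    if m == 1:
        del state.bonds[key]
    else:
        state.bonds[key] = m - 1
    state.used_valency[p] -= 1
    state.used_valency[q] -= 1
    return state


# ---------------------------------------------------------------------------
# Snapshot serialization (plain text, deterministic ordering)
# ---------------------------------------------------------------------------

def write_snapshot(state: LatticeState, fh: TextIO) -> None:
    """Write the documented plain-text snapshot format.

    Header lines ``#L`` and ``#time``; one line per particle
    ``id<TAB>row<TAB>col<TAB>used_valency`` in ascending id order; one line
    per bond ``p<TAB>q<TAB>multiplicity`` ordered by the (min, max) pair.
    Coordinates are 0-based (row, col).
    """
    fh.write(f"#L\t{state.L}\n")
    fh.write(f"#time\t{float(state.time)!r}\n")
    for p, (r, c) in enumerate(state.positions):
        fh.write(f"{p}\t{r}\t{c}\t{state.used_valency[p]}\n")
    for (p, q) in sorted(state.bonds):
        fh.write(f"{p}\t{q}\t{state.bonds[(p, q)]}\n")


def read_snapshot(fh: TextIO) -> LatticeState:
    """Parse a snapshot written by :func:`write_snapshot`."""
    L = None
    time = 0.0
    particles: list[tuple[int, int, int, int]] = []
    bonds: dict[tuple[int, int], int] = {}
    for line in fh:
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith("#L"):
            L = int(line.split("\t")[1])
        elif line.startswith("#time"):
            time = float(line.split("\t")[1])
        else:
            parts = line.split("\t")
            if len(parts) == 4:
                particles.append(tuple(int(x) for x in parts))
            elif len(parts) == 3:
                p, q, m = (int(x) for x in parts)
                bonds[(p, q)] = m
            else:
                raise ValueError(f"malformed snapshot line: {line!r}")
    if L is None:
        raise ValueError("snapshot missing #L header")
    particles.sort()
    grid = np.full((L, L), -1, dtype=np.int32)
    positions = np.empty((len(particles), 2), dtype=np.int64)
    used = np.zeros(len(particles), dtype=np.int64)
    for p, r, c, uv in particles:
        grid[r, c] = p
        positions[p] = (r, c)
        used[p] = uv
    state = LatticeState(
        L=L, grid=grid, positions=positions, bonds=bonds,
        used_valency=used, time=time,
    )
    state.validate()
    return state
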