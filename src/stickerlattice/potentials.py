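"""Bead-spring force-field energy evaluators and specific-bond rules.

The off-lattice picture behind the lattice model: a multivalent protein is
a chain of small linker beads (diameter 4.2 A, roughly an amino acid)
interrupted by large adhesive domain beads (20 A, roughly a folded SH3-like
domain).  Three static energy terms act on a conformation:

* stretching — harmonic springs between consecutive beads,
  ``E = k_s * sum (r - r0)^2`` (a ``half_prefactor`` flag switches to the
  ``1/2 k (r-r0)^2`` convention);
* bending — ``E = kappa * sum (1 - cos theta_i)`` over consecutive bond
  pairs;
* non-bonded — truncated 12-6 Lennard-Jones,
  ``E = 4 eps_ns * sum [(sigma/r)^12 - (sigma/r)^6]`` for ``r < 2.5 sigma``
  (plain truncation, no shift), excluding directly bonded pairs.

Specific (saturable) interactions are stochastic springs between
complementary domain beads: a free A-B pair within the capture radius bonds
with probability ``p_form``; a bond stretched more than ``delta_break``
beyond its rest length breaks with probability 1 (or never, in the
irreversible mode).  Each domain bead holds at most one specific bond, so a
chain's valency is its domain-bead count.

These are evaluators only — there is no integrator.  Internal energy unit
is kcal/mol; spring constants are quoted in kT/A^2 and converted at 310 K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "KT_TO_KCAL",
    "ChainTopology",
    "ChainConformation",
    "ForceFieldParams",
    "stretch_energy",
    "bend_energy",
    "lj_energy",
    "total_energy",
    "try_form_specific_bonds",
    "try_break_specific_bonds",
    "build_chain",
]

#: 1 kT in kcal/mol at T = 310 K
KT_TO_KCAL = 0.61596

LINKER = "linker"
DOMAIN_A = "A"
DOMAIN_B = "B"
_DOMAIN_TYPES = (DOMAIN_A, DOMAIN_B)


@dataclass(frozen=True)
class ChainTopology:
    """Bead types of one or more chains plus their connectivity.

    ``bead_types[i]`` is ``"linker"``, ``"A"`` or ``"B"`` (A and B are the
    complementary adhesive domain types).  ``chain_bonds`` lists the
    consecutive-bead springs as index pairs.
    """

    bead_types: tuple[str, ...]
    chain_bonds: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        for t in self.bead_types:
            if t not in (LINKER, DOMAIN_A, DOMAIN_B):
                raise ValueError(f"unknown bead type {t!r}")

    @property
    def n_beads(self) -> int:
        return len(self.bead_types)

    @property
    def domain_indices(self) -> tuple[int, ...]:
        return tuple(
            i for i, t in enumerate(self.bead_types) if t in _DOMAIN_TYPES
        )

    @property
    def valency(self) -> int:
        """Chain valency: number of adhesive domain beads."""
        return len(self.domain_indices)


@dataclass
class ChainConformation:
    """Bead coordinates (Angstrom) plus the active specific bonds."""

    topology: ChainTopology
    coords: np.ndarray                      # (M, 3) float64, Angstrom
    specific_bonds: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.shape != (self.topology.n_beads, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} != ({self.topology.n_beads}, 3)"
            )
        self._check_bond_valency()

    def _check_bond_valency(self) -> None:
        seen: set[int] = set()
        for i, j in self.specific_bonds:
            for k in (i, j):
                if self.topology.bead_types[k] not in _DOMAIN_TYPES:
                    raise ValueError(f"bead {k} is not an adhesive domain")
                if k in seen:
                    raise ValueError(f"domain bead {k} holds more than one bond")
                seen.add(k)

    def copy(self) -> "ChainConformation":
        return ChainConformation(
            self.topology, self.coords.copy(), set(self.specific_bonds)
        )


@dataclass(frozen=True)
class ForceFieldParams:
    """Force-field constants with explicit units.

    ``k_s`` is quoted in kT/A^2 (5 for chain springs, 2 for specific-bond
    springs), ``kappa`` and ``eps_ns`` in kcal/mol; all lengths in
    Angstrom.  Conversion between kT and kcal/mol is fixed at 310 K.
    """

    k_s_kt: float = 5.0            # kT/A^2, chain-connectivity springs
    k_s_specific_kt: float = 2.0   # kT/A^2, specific-bond springs
    r0_linker: float = 4.5         # A, rest length of chain bonds
    r0_specific: float = 20.0      # A, rest length of specific bonds
    kappa_kcal: float = 2.0        # kcal/mol, bending stiffness
    eps_ns_kcal: float = 0.1       # kcal/mol, LJ depth
    sigma_linker: float = 4.2      # A
    sigma_domain: float = 20.0     # A
    cutoff_mult: float = 2.5       # LJ truncation at cutoff_mult * sigma
    r_capture: float = 22.5        # A, specific-bond formation radius
    delta_break: float = 2.2       # A stretch beyond r0 at which bonds break
    p_form: float = 1.0
    half_prefactor: bool = False   # True: E = (1/2) k (r - r0)^2
    irreversible: bool = False     # True: bonds never break

    def __post_init__(self) -> None:
        for name in ("k_s_kt", "k_s_specific_kt", "r0_linker", "r0_specific",
                     "kappa_kcal", "eps_ns_kcal", "sigma_linker",
                     "sigma_domain", "cutoff_mult", "r_capture", "delta_break"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.p_form <= 1.0:
            raise ValueError("p_form must lie in [0, 1]")

    def with_(self, **kw) -> "ForceFieldParams":
        return replace(self, **kw)

    def sigma(self, type_i: str, type_j: str) -> float:
        """Pair sigma: like pairs use their class value, mixed pairs the
        Lorentz arithmetic mean."""
        si = self.sigma_linker if type_i == LINKER else self.sigma_domain
        sj = self.sigma_linker if type_j == LINKER else self.sigma_domain
        return 0.5 * (si + sj)


def _as_units(energy_kcal: float, units: str) -> float:
    if units == "kcal/mol":
        return energy_kcal
    if units == "kT":
        return energy_kcal / KT_TO_KCAL
    raise ValueError(f"unknown energy units {units!r} (use 'kcal/mol' or 'kT')")


def stretch_energy(
    conf: ChainConformation, params: ForceFieldParams, units: str = "kcal/mol"
) -> float:
    """Harmonic stretching energy over consecutive chain bonds.

    ``k_s * sum (|r_i - r_i+1| - r0)^2`` as printed (no 1/2), halved when
    ``half_prefactor`` is set.  Chains of fewer than 2 beads contribute 0.
    """
    k_kcal = params.k_s_kt * KT_TO_KCAL
    if params.half_prefactor:
        k_kcal *= 0.5
    total = 0.0
    for i, j in conf.topology.chain_bonds:
        r = float(np.linalg.norm(conf.coords[i] - conf.coords[j]))
        total += k_kcal * (r - params.r0_linker) ** 2
    return _as_units(total, units)


def bend_energy(
    conf: ChainConformation, params: ForceFieldParams, units: str = "kcal/mol"
) -> float:
    """Cosine bending energy ``kappa * sum (1 - cos theta_i)``.

    ``theta_i`` is the angle between consecutive bond vectors; a
    zero-length bond makes the angle undefined and raises.
    """
    bonds = conf.topology.chain_bonds
    total = 0.0
    for (i, j), (j2, k) in zip(bonds, bonds[1:]):
        if j != j2:
            continue  # chain break: no angle across disjoint chains
        v1 = conf.coords[j] - conf.coords[i]
        v2 = conf.coords[k] - conf.coords[j]
        n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
        if n1 == 0.0 or n2 == 0.0:
            raise ValueError("zero-length bond: bending angle undefined")
        cos_t = float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))
        total += params.kappa_kcal * (1.0 - cos_t)
    return _as_units(total, units)


def lj_energy(
    conf: ChainConformation, params: ForceFieldParams, units: str = "kcal/mol"
) -> float:
    """Truncated 12-6 Lennard-Jones over all non-bonded bead pairs.

    ``4 eps_ns [(sigma/r)^12 - (sigma/r)^6]`` for ``r < cutoff_mult *
    sigma`` with plain truncation (no shift); directly bonded pairs are
    excluded; overlapping beads (r = 0) raise.
    """
    coords = conf.coords
    types = conf.topology.bead_types
    excluded = {tuple(sorted(b)) for b in conf.topology.chain_bonds}
    total = 0.0
    m = len(types)
    for i in range(m):
        for j in range(i + 1, m):
            if (i, j) in excluded:
                continue
            r = float(np.linalg.norm(coords[i] - coords[j]))
            if r == 0.0:
                raise ValueError(f"beads {i} and {j} overlap (r = 0)")
            sigma = params.sigma(types[i], types[j])
            if r >= params.cutoff_mult * sigma:
                continue
            sr6 = (sigma / r) ** 6
            total += 4.0 * params.eps_ns_kcal * (sr6 * sr6 - sr6)
    return _as_units(total, units)


def total_energy(
    conf: ChainConformation, params: ForceFieldParams, units: str = "kcal/mol"
) -> dict[str, float]:
    """Breakdown ``{stretch, bend, lj, total}`` in the requested units."""
    s = stretch_energy(conf, params, units)
    b = bend_energy(conf, params, units)
    nb = lj_energy(conf, params, units)
    return {"stretch": s, "bend": b, "lj": nb, "total": s + b + nb, "units": units}


def try_form_specific_bonds(
    conf: ChainConformation,
    params: ForceFieldParams,
    rng: np.random.Generator,
) -> ChainConformation:
    """Stochastically bond free complementary domain pairs within capture range.

    Every free A-B pair with separation below ``r_capture`` is visited in
    an rng-shuffled order (tie fairness when one bead has several eligible
    partners) and bonds with probability ``p_form``; a bead engages at most
    one bond.  Returns a new conformation.
    """
    new = conf.copy()
    types = conf.topology.bead_types
    engaged = {k for b in new.specific_bonds for k in b}
    candidates = []
    for i in conf.topology.domain_indices:
        for j in conf.topology.domain_indices:
            if i < j and types[i] != types[j]:
                r = float(np.linalg.norm(conf.coords[i] - conf.coords[j]))
                if r < params.r_capture:
                    candidates.append((i, j))
    order = rng.permutation(len(candidates))
    for idx in order:
        i, j = candidates[idx]
        if i in engaged or j in engaged:
            continue
        if rng.random() < params.p_form:
            new.specific_bonds.add((i, j))
            engaged.update((i, j))
    return new


def try_break_specific_bonds(
    conf: ChainConformation, params: ForceFieldParams
) -> ChainConformation:
    """Break every bond stretched beyond ``r0_specific + delta_break``.

    Breakage probability is 1 past the threshold and 0 below it; in the
    irreversible mode no bond ever breaks.
    """
    new = conf.copy()
    if params.irreversible:
        return new
    r_break = params.r0_specific + params.delta_break
    for i, j in list(new.specific_bonds):
        r = float(np.linalg.norm(new.coords[i] - new.coords[j]))
        if r > r_break:
            new.specific_bonds.discard((i, j))
    return new


def build_chain(
    n_domains: int = 5,
    linker_length: int = 35,
    spacing: float | None = None,
    domain_type: str = DOMAIN_A,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    params: ForceFieldParams | None = None,
) -> ChainConformation:
    """Straight equilibrium chain: domains separated by linker stretches.

    Default architecture: ``n_domains`` adhesive sites separated by
    ``linker_length``-bead linkers, laid out collinearly at the chain-bond
    rest length, so stretching and bending energies are exactly zero.
    """
    if params is None:
        params = ForceFieldParams()
    if spacing is None:
        spacing = params.r0_linker
    beads: list[str] = []
    for d in range(n_domains):
        beads.append(domain_type)
        if d < n_domains - 1:
            beads.extend([LINKER] * linker_length)
    topo = ChainTopology(
        bead_types=tuple(beads),
        chain_bonds=tuple((i, i + 1) for i in range(len(beads) - 1)),
    )
    coords = np.zeros((len(beads), 3))
    coords[:, 0] = origin[0] + spacing * np.arange(len(beads))
    coords[:, 1] = origin[1]
    coords[:, 2] = origin[2]
    return ChainConformation(topo, coords)
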