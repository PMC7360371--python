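"""Run configuration, deterministic fixtures, and output writers.

Configuration is a flat YAML mapping whose keys mirror ``SimParams`` field
names, plus optional sweep/driver keys (``grid``, ``replicates``, ``out``,
``log_level``, ``record_events``).  Unknown keys are rejected by name;
defaults follow the model conventions (``k_diff = 1`` 1/s so time is
measured in units of the free-diffusion step, ``eps_ns = 0.35`` kT,
``t_end = 7200`` s).  Scientific output files embed the resolved
configuration and the seeds so every table is reproducible from the file
alone; log output goes to stderr, never into data files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, TextIO

import numpy as np
import yaml

from .lattice import LatticeState, SimParams
from .potentials import ChainConformation, ChainTopology, build_chain

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "save_config",
    "configure_logging",
    "make_fixture",
    "FIXTURE_NAMES",
    "write_summary",
    "write_table",
    "write_conformation",
    "read_conformation",
]

logger = logging.getLogger("stickerlattice")


class ConfigError(ValueError):
    """Invalid or malformed run configuration (CLI exit code 2)."""


_SIM_FIELDS = {f.name for f in dataclasses.fields(SimParams)}
_EXTRA_FIELDS = {"grid", "replicates", "out", "log_level", "record_events"}


@dataclass
class RunConfig:
    """Resolved configuration: simulation parameters plus driver options."""

    sim: SimParams
    grid: dict[str, list[float]] = field(default_factory=dict)
    replicates: int = 1
    out: str | None = None
    log_level: str = "INFO"
    record_events: bool = False

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self.sim)
        if self.grid:
            d["grid"] = {k: list(v) for k, v in self.grid.items()}
        d["replicates"] = self.replicates
        if self.out is not None:
            d["out"] = self.out
        d["log_level"] = self.log_level
        d["record_events"] = self.record_events
        return d

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _build_config(raw: dict[str, Any]) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(raw) - _SIM_FIELDS - _EXTRA_FIELDS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    sim_kwargs = {k: v for k, v in raw.items() if k in _SIM_FIELDS}
    try:
        sim = SimParams(**sim_kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    grid = raw.get("grid", {}) or {}
    if not isinstance(grid, dict):
        raise ConfigError("grid must map parameter names to value lists")
    for k, v in grid.items():
        if k not in _SIM_FIELDS:
            raise ConfigError(f"grid parameter {k!r} is not a SimParams field")
        if not isinstance(v, (list, tuple)) or not v:
            raise ConfigError(f"grid values for {k!r} must be a non-empty list")
    replicates = int(raw.get("replicates", 1))
    if replicates < 1:
        raise ConfigError("replicates must be >= 1")
    return RunConfig(
        sim=sim,
        grid={k: list(v) for k, v in grid.items()},
        replicates=replicates,
        out=raw.get("out"),
        log_level=str(raw.get("log_level", "INFO")),
        record_events=bool(raw.get("record_events", False)),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration, applying defaults."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
    return _build_config(raw or {})


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Serialize a configuration so that load(save(cfg)) == cfg."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def configure_logging(level: str = "INFO") -> None:
    """Send package logs to stderr (data streams stay clean)."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level.upper())


# ---------------------------------------------------------------------------
# Deterministic fixtures
# ---------------------------------------------------------------------------

def _empty_state(L: int, positions: list[tuple[int, int]]) -> LatticeState:
    grid = np.full((L, L), -1, dtype=np.int32)
    pos = np.empty((len(positions), 2), dtype=np.int64)
    for p, (r, c) in enumerate(positions):
        grid[r, c] = p
        pos[p] = (r, c)
    return LatticeState(L=L, grid=grid, positions=pos)


def _fixture_single(L: int = 9) -> LatticeState:
    return _empty_state(L, [(L // 2, L // 2)])


def _fixture_pair(L: int = 9) -> LatticeState:
    m = L // 2
    return _empty_state(L, [(m, m), (m, m + 1)])


def _fixture_bonded_dimer(L: int = 9) -> LatticeState:
    state = _fixture_pair(L)
    state.bonds[(0, 1)] = 1
    state.used_valency[:] = 1
    return state


def _fixture_block4(L: int = 9) -> LatticeState:
    m = L // 2
    return _empty_state(L, [(m, m), (m, m + 1), (m + 1, m), (m + 1, m + 1)])


def _fixture_plus5(L: int = 9) -> LatticeState:
    m = L // 2
    return _empty_state(
        L, [(m, m), (m - 1, m), (m + 1, m), (m, m - 1), (m, m + 1)]
    )


def _fixture_toy_chain() -> ChainConformation:
    # two adhesive domains joined by a 7-bead linker, at rest spacing
    return build_chain(n_domains=2, linker_length=7)


_FIXTURES = {
    "single_particle": _fixture_single,
    "adjacent_pair": _fixture_pair,
    "bonded_dimer": _fixture_bonded_dimer,
    "block4": _fixture_block4,
    "plus5": _fixture_plus5,
    "toy_chain": _fixture_toy_chain,
}

FIXTURE_NAMES = tuple(sorted(_FIXTURES))


def make_fixture(name: str, seed: int = 0):
    """Build a named deterministic scenario (lattice state or conformation).

    The geometry depends only on the name (and, for randomized fixtures,
    the seed), so fixtures are byte-identical across runs.
    """
    del seed  # current fixtures are fully deterministic by name
    try:
        builder = _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
    return builder()


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------

def _fmt(value: Any) -> str:
    if isinstance(value, (bool, np.bool_)):
        return str(bool(value))
    if isinstance(value, (float, np.floating)):
        return f"{value:.6g}"
    return str(value)


def write_table(rows, path: str | Path, columns: list[str] | None = None) -> None:
    """Write rows (DataFrame or list of dicts) as TSV, floats at 6 sig digits.

    The column order is fixed (explicit ``columns`` or first-row order), so
    identical inputs give byte-identical tables.  An empty table keeps its
    header line.
    """
    import pandas as pd

    if not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame(list(rows), columns=columns)
    elif columns is not None:
        rows = rows[columns]
    with open(path, "w") as fh:
        fh.write("\t".join(map(str, rows.columns)) + "\n")
        for _, row in rows.iterrows():
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def write_summary(
    results: dict[str, Any],
    path: str | Path,
    config: RunConfig | None = None,
    seeds: list[int] | None = None,
) -> None:
    """JSON summary embedding the resolved config, its hash, and the seeds."""
    from . import __version__

    payload: dict[str, Any] = {"version": __version__}
    if config is not None:
        payload["config"] = config.to_dict()
        payload["config_hash"] = config.config_hash
    if seeds is not None:
        payload["seeds"] = [int(s) for s in seeds]
    payload["results"] = results
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Chain conformation I/O (plain text)
# ---------------------------------------------------------------------------

def write_conformation(conf: ChainConformation, fh: TextIO) -> None:
    """Sections: ``#beads`` (id, type, x, y, z in Angstrom), ``#chain_bonds``
    and ``#specific_bonds`` (index pairs)."""
    fh.write("#beads\n")
    for i, t in enumerate(conf.topology.bead_types):
        x, y, z = (float(v) for v in conf.coords[i])
        fh.write(f"{i}\t{t}\t{x!r}\t{y!r}\t{z!r}\n")
    fh.write("#chain_bonds\n")
    for i, j in conf.topology.chain_bonds:
        fh.write(f"{i}\t{j}\n")
    fh.write("#specific_bonds\n")
    for i, j in sorted(conf.specific_bonds):
        fh.write(f"{i}\t{j}\n")


def read_conformation(fh: TextIO) -> ChainConformation:
    section = None
    types: list[str] = []
    coords: list[list[float]] = []
    chain_bonds: list[tuple[int, int]] = []
    specific: set[tuple[int, int]] = set()
    for line in fh:
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            section = line[1:]
            continue
        parts = line.split("\t")
        if section == "beads":
            types.append(parts[1])
            coords.append([float(x) for x in parts[2:5]])
        elif section == "chain_bonds":
            chain_bonds.append((int(parts[0]), int(parts[1])))
        elif section == "specific_bonds":
            specific.add((int(parts[0]), int(parts[1])))
        else:
            raise ValueError(f"line outside a known section: {line!r}")
    topo = ChainTopology(tuple(types), tuple(chain_bonds))
    return ChainConformation(topo, np.array(coords), specific)
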