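import numpy as np
import pytest

from stickerlattice import SimParams, init_lattice, place_bond


@pytest.fixture
def pair_params():
    """Two adjacent particles on a small lattice, valency 1."""
    return SimParams(L=9, lam=1, eps_sp=2.0, eps_ns=0.35, n_particles=2, seed=0)


def random_bonded_state(rng: np.random.Generator, L=None, n=None, lam=None):
    """Random small configuration with random feasible bonds, plus its params.

    Shared by the oracle-equivalence tests: states drawn here exercise
    monomers, clusters, saturated and unsaturated valencies.
    """
    L = L or int(rng.integers(4, 9))
    n = n or int(rng.integers(2, 11))
    lam = lam if lam is not None else int(rng.integers(0, 5))
    params = SimParams(
        L=L,
        lam=lam,
        eps_sp=float(rng.uniform(0.0, 3.0)),
        eps_ns=float(rng.uniform(0.0, 1.0)),
        n_particles=n,
        k_diff=float(rng.uniform(0.5, 2.0)),
        k_bond=float(rng.uniform(0.0, 2.0)),
        seed=int(rng.integers(2**31)),
    )
    state = init_lattice(params)
    for _ in range(3 * n):
        p = int(rng.integers(n))
        for _, q in state.neighbors_of(p):
            if (
                state.used_valency[p] < lam
                and state.used_valency[q] < lam
                and rng.random() < 0.5
            ):
                place_bond(state, params, p, q)
    return state, params
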