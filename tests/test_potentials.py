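import math

import numpy as np
import pytest

from stickerlattice.potentials import (
    KT_TO_KCAL,
    ChainConformation,
    ChainTopology,
    ForceFieldParams,
    bend_energy,
    build_chain,
    lj_energy,
    stretch_energy,
    total_energy,
    try_break_specific_bonds,
    try_form_specific_bonds,
)

FF = ForceFieldParams()


def chain(coords, types=None, bonds=None):
    coords = np.asarray(coords, dtype=float)
    m = len(coords)
    types = types or ("linker",) * m
    bonds = bonds if bonds is not None else tuple((i, i + 1) for i in range(m - 1))
    return ChainConformation(ChainTopology(tuple(types), tuple(bonds)), coords)


def random_conformation(rng, m=None):
    m = m or int(rng.integers(3, 21))
    types = tuple(rng.choice(["linker", "A", "B"]) for _ in range(m))
    coords = rng.uniform(0, 40, size=(m, 3))
    return ChainConformation(
        ChainTopology(types, tuple((i, i + 1) for i in range(m - 1))), coords
    )


class TestStretch:
    def test_equilibrium_chain_zero(self):
        conf = build_chain(n_domains=2, linker_length=5)
        assert stretch_energy(conf, FF) == pytest.approx(0.0)

    def test_single_stretched_bond(self):
        conf = chain([[0, 0, 0], [5.5, 0, 0]])
        # k_s = 5 kT/A^2, (5.5 - 4.5)^2 = 1 -> 5 kT
        assert stretch_energy(conf, FF, units="kT") == pytest.approx(5.0)

    def test_half_prefactor_convention_halves(self):
        conf = chain([[0, 0, 0], [6.0, 0, 0], [12.5, 0, 0]])
        full = stretch_energy(conf, FF)
        half = stretch_energy(conf, FF.with_(half_prefactor=True))
        assert half == pytest.approx(full / 2)

    def test_fewer_than_two_beads_zero(self):
        conf = chain([[0, 0, 0]], bonds=())
        assert stretch_energy(conf, FF) == 0.0


class TestBend:
    def test_collinear_chain_zero(self):
        conf = build_chain(n_domains=3, linker_length=4)
        assert bend_energy(conf, FF) == pytest.approx(0.0)

    def test_right_angle_kink(self):
        conf = chain([[0, 0, 0], [4.5, 0, 0], [4.5, 4.5, 0]])
        # kappa = 2 kcal/mol, 1 - cos 90 = 1
        assert bend_energy(conf, FF) == pytest.approx(2.0)

    def test_full_reversal_costs_two_kappa(self):
        conf = chain([[0, 0, 0], [4.5, 0, 0], [0, 0, 0.0001]])
        assert bend_energy(conf, FF) == pytest.approx(2 * FF.kappa_kcal, rel=1e-3)

    def test_zero_length_bond_rejected(self):
        conf = chain([[0, 0, 0], [0, 0, 0], [4.5, 0, 0]])
        with pytest.raises(ValueError):
            bend_energy(conf, FF)


class TestLennardJones:
    def test_zero_at_sigma(self):
        conf = chain([[0, 0, 0], [FF.sigma_linker, 0, 0]], bonds=())
        assert lj_energy(conf, FF) == pytest.approx(0.0, abs=1e-12)

    def test_minimum_at_two_to_the_sixth_sigma(self):
        r_min = 2 ** (1 / 6) * FF.sigma_linker
        conf = chain([[0, 0, 0], [r_min, 0, 0]], bonds=())
        assert lj_energy(conf, FF) == pytest.approx(-FF.eps_ns_kcal)

    def test_beyond_cutoff_contributes_nothing(self):
        conf = chain([[0, 0, 0], [2.6 * FF.sigma_linker, 0, 0]], bonds=())
        assert lj_energy(conf, FF) == 0.0

    def test_bonded_pairs_excluded(self):
        coords = [[0, 0, 0], [FF.sigma_linker * 1.1, 0, 0]]
        bonded = chain(coords)                 # consecutive pair is bonded
        free = chain(coords, bonds=())
        assert lj_energy(bonded, FF) == 0.0
        assert lj_energy(free, FF) != 0.0

    def test_mixed_pair_uses_mean_sigma(self):
        sigma_mix = 0.5 * (FF.sigma_linker + FF.sigma_domain)
        conf = chain([[0, 0, 0], [sigma_mix, 0, 0]], types=("linker", "A"), bonds=())
        assert lj_energy(conf, FF) == pytest.approx(0.0, abs=1e-12)

    def test_overlapping_beads_rejected(self):
        conf = chain([[0, 0, 0], [0, 0, 0]], bonds=())
        with pytest.raises(ValueError):
            lj_energy(conf, FF)


class TestInvariance:
    def test_rigid_transform_invariance(self):
        """Energies depend only on internal geometry: random rotation +
        translation changes nothing to 1e-8 relative."""
        rng = np.random.default_rng(41)
        for _ in range(10):
            conf = random_conformation(rng)
            ref = total_energy(conf, FF)
            # random rotation from QR decomposition, plus translation
            q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            if np.linalg.det(q) < 0:
                q[:, 0] *= -1
            moved = ChainConformation(
                conf.topology, conf.coords @ q.T + rng.uniform(-50, 50, 3)
            )
            new = total_energy(moved, FF)
            for key in ("stretch", "bend", "lj", "total"):
                assert new[key] == pytest.approx(ref[key], rel=1e-8, abs=1e-10)

    def test_terms_match_vectorized_oracle(self):
        """Loop implementations vs an independent vectorized recomputation."""
        rng = np.random.default_rng(43)
        for _ in range(20):
            conf = random_conformation(rng)
            x = conf.coords
            bonds = np.array(conf.topology.chain_bonds)
            d = np.linalg.norm(x[bonds[:, 0]] - x[bonds[:, 1]], axis=1)
            stretch = (FF.k_s_kt * KT_TO_KCAL * (d - FF.r0_linker) ** 2).sum()
            assert stretch_energy(conf, FF) == pytest.approx(stretch, rel=1e-10)

            v = np.diff(x, axis=0)
            cos = (v[:-1] * v[1:]).sum(1) / (
                np.linalg.norm(v[:-1], axis=1) * np.linalg.norm(v[1:], axis=1)
            )
            bend = (FF.kappa_kcal * (1 - cos)).sum()
            assert bend_energy(conf, FF) == pytest.approx(bend, rel=1e-8)

            types = conf.topology.bead_types
            lj = 0.0
            m = len(types)
            excl = set(conf.topology.chain_bonds)
            for i in range(m):
                for j in range(i + 1, m):
                    if (i, j) in excl:
                        continue
                    r = np.linalg.norm(x[i] - x[j])
                    s = FF.sigma(types[i], types[j])
                    if r < 2.5 * s:
                        lj += 4 * FF.eps_ns_kcal * ((s / r) ** 12 - (s / r) ** 6)
            assert lj_energy(conf, FF) == pytest.approx(lj, rel=1e-10, abs=1e-12)


class TestSpecificBonds:
    @staticmethod
    def _triplet():
        # A flanked by two B partners, all within capture range
        return chain(
            [[0, 0, 0], [15, 0, 0], [-15, 0, 0]],
            types=("A", "B", "B"),
            bonds=(),
        )

    def test_certain_formation(self):
        conf = chain([[0, 0, 0], [15, 0, 0]], types=("A", "B"), bonds=())
        out = try_form_specific_bonds(conf, FF, np.random.default_rng(0))
        assert out.specific_bonds == {(0, 1)}

    def test_zero_probability_never_forms(self):
        conf = self._triplet()
        out = try_form_specific_bonds(
            conf, FF.with_(p_form=0.0), np.random.default_rng(0)
        )
        assert out.specific_bonds == set()

    def test_valency_one_picks_exactly_one_partner_fairly(self):
        wins = {1: 0, 2: 0}
        for seed in range(400):
            out = try_form_specific_bonds(
                self._triplet(), FF, np.random.default_rng(seed)
            )
            assert len(out.specific_bonds) == 1  # A can hold only one bond
            (bond,) = out.specific_bonds
            wins[bond[1]] += 1
        # each partner chosen about half the time (3-sigma binomial band)
        assert abs(wins[1] - 200) < 3 * math.sqrt(400 * 0.25)

    def test_same_type_pairs_never_bond(self):
        conf = chain([[0, 0, 0], [15, 0, 0]], types=("B", "B"), bonds=())
        out = try_form_specific_bonds(conf, FF, np.random.default_rng(1))
        assert out.specific_bonds == set()

    def test_break_threshold(self):
        for stretch, broken in [(0.0, False), (2.3, True)]:
            conf = chain(
                [[0, 0, 0], [FF.r0_specific + stretch, 0, 0]],
                types=("A", "B"),
                bonds=(),
            )
            conf.specific_bonds.add((0, 1))
            out = try_break_specific_bonds(conf, FF)
            assert ((0, 1) not in out.specific_bonds) == broken

    def test_irreversible_bonds_never_break(self):
        conf = chain([[0, 0, 0], [80, 0, 0]], types=("A", "B"), bonds=())
        conf.specific_bonds.add((0, 1))
        out = try_break_specific_bonds(conf, FF.with_(irreversible=True))
        assert (0, 1) in out.specific_bonds

    def test_double_bond_on_one_domain_rejected(self):
        with pytest.raises(ValueError):
            ChainConformation(
                ChainTopology(("A", "B", "B"), ()),
                np.zeros((3, 3)) + np.arange(3)[:, None] * 30,
                specific_bonds={(0, 1), (0, 2)},
            )


class TestBuildChain:
    def test_default_architecture(self):
        conf = build_chain()
        topo = conf.topology
        assert topo.valency == 5
        assert topo.n_beads == 5 + 4 * 35
        assert stretch_energy(conf, FF) == pytest.approx(0.0)
        assert bend_energy(conf, FF) == pytest.approx(0.0)
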