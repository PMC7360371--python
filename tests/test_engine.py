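import math

import numpy as np
import pytest

from stickerlattice import (
    SimParams,
    apply_event,
    draw_event,
    enumerate_events,
    place_bond,
    run_trajectory,
    waiting_time,
)
from stickerlattice._kernel import kernel_enumerate
from stickerlattice.config import make_fixture
from stickerlattice.engine import Event, EventSet

from conftest import random_bonded_state


def by_kind(evset):
    out = {}
    for ev, rate in zip(evset.events, evset.rates):
        out.setdefault(ev.kind, []).append((ev, float(rate)))
    return out


class TestEnumerateEvents:
    def test_single_free_particle(self):
        state = make_fixture("single_particle")
        p = SimParams(L=state.L, lam=0, eps_sp=0.0, eps_ns=0.0, n_particles=1,
                      k_bond=0.0, k_diff=2.0)
        ev = enumerate_events(state, p)
        assert len(ev) == 4
        assert all(e.kind == "monomer_move" for e in ev.events)
        assert ev.r_total == pytest.approx(4 * 2.0)

    def test_adjacent_pair_full_event_set(self, pair_params):
        """Hand-enumerated two-particle configuration: six Boltzmann-
        suppressed hops, one bond formation, four dimer translations."""
        state = make_fixture("adjacent_pair")
        ev = by_kind(enumerate_events(state, pair_params))
        moves = ev["monomer_move"]
        assert len(moves) == 6
        for _, rate in moves:
            assert rate == pytest.approx(math.exp(-0.35))
        assert len(ev["bond_form"]) == 1
        assert ev["bond_form"][0][1] == pytest.approx(1.0)
        cmoves = ev["cluster_move"]
        assert len(cmoves) == 4
        for _, rate in cmoves:
            assert rate == pytest.approx(0.5)
        total = enumerate_events(state, pair_params).r_total
        assert total == pytest.approx(6 * math.exp(-0.35) + 1.0 + 2.0)

    def test_bonded_pair_break_rate_and_saturated_valency(self, pair_params):
        state = make_fixture("bonded_dimer")
        ev = by_kind(enumerate_events(state, pair_params))
        assert "bond_form" not in ev  # valency exhausted at lam=1
        (_, rate), = ev["bond_break"]
        assert rate == pytest.approx(math.exp(-2.0))

    def test_break_events_count_multiplicity(self):
        state = make_fixture("adjacent_pair")
        p = SimParams(L=state.L, lam=3, eps_sp=1.0, n_particles=2)
        for _ in range(3):
            place_bond(state, p, 0, 1)
        ev = by_kind(enumerate_events(state, p))
        assert len(ev["bond_break"]) == 3
        assert sum(r for _, r in ev["bond_break"]) == pytest.approx(3 * p.k_break)

    def test_kernel_enumeration_matches_reference(self):
        """Compiled and reference enumerations agree event-for-event on
        randomized small states."""
        rng = np.random.default_rng(17)
        for _ in range(200):
            state, params = random_bonded_state(rng)
            ref = {}
            for e, r in zip(*(lambda s: (s.events, s.rates))(
                    enumerate_events(state, params))):
                ref[(e.kind, e.a, e.b)] = ref.get((e.kind, e.a, e.b), 0.0) + float(r)
            ker, r_tot = kernel_enumerate(state, params)
            assert set(ref) == set(ker)
            for key in ref:
                assert ker[key] == pytest.approx(ref[key], rel=1e-9)
            assert r_tot == pytest.approx(sum(ref.values()), rel=1e-9)


class TestDrawEvent:
    def test_single_event_always_chosen(self):
        evset = EventSet([Event("bond_form", 0, 1)], np.array([2.0]), 2.0)
        for u in (0.0, 0.3, 0.999):
            assert draw_event(evset, u).kind == "bond_form"

    def test_cumulative_interval_selection(self):
        evset = EventSet(
            [Event("bond_form", 0, 1), Event("bond_break", 0, 1)],
            np.array([1.0, 3.0]),
            4.0,
        )
        assert draw_event(evset, 0.1).kind == "bond_form"   # 0.4 < 1.0
        assert draw_event(evset, 0.5).kind == "bond_break"  # 2.0 >= 1.0

    def test_empty_event_set_rejected(self):
        with pytest.raises(ValueError):
            draw_event(EventSet([], np.array([]), 0.0), 0.5)

    def test_empirical_frequencies_match_rates(self):
        rates = np.array([0.5, 1.5, 3.0])
        evset = EventSet(
            [Event("bond_form", 0, i) for i in range(3)], rates, float(rates.sum())
        )
        rng = np.random.default_rng(23)
        n = 100_000
        counts = np.zeros(3)
        for u in rng.random(n):
            counts[draw_event(evset, u).b] += 1
        p = rates / rates.sum()
        sigma = np.sqrt(n * p * (1 - p))
        assert (np.abs(counts - n * p) < 3 * sigma).all()


class TestWaitingTime:
    def test_closed_form_values(self):
        assert waiting_time(5.0, 1.0) == 0.0
        assert waiting_time(2.0, math.exp(-1.0)) == pytest.approx(0.5)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            waiting_time(0.0, 0.5)
        with pytest.raises(ValueError):
            waiting_time(1.0, 0.0)  # log divergence

    def test_sample_mean_is_inverse_rate(self):
        rng = np.random.default_rng(29)
        r = 3.0
        draws = np.array([waiting_time(r, 1 - rng.random()) for _ in range(100_000)])
        # exponential: mean 1/r, sd 1/r; 3-sigma band for the sample mean
        assert abs(draws.mean() - 1 / r) < 3 / (r * math.sqrt(len(draws)))


class TestApplyEvent:
    def test_form_then_break_restores_state(self, pair_params):
        state = make_fixture("adjacent_pair")
        before = state.copy()
        apply_event(state, pair_params, Event("bond_form", 0, 1))
        apply_event(state, pair_params, Event("bond_break", 0, 1))
        assert state.bonds == before.bonds
        assert np.array_equal(state.used_valency, before.used_valency)

    def test_cluster_move_preserves_bond(self, pair_params):
        state = make_fixture("bonded_dimer")
        r0 = state.positions.copy()
        apply_event(state, pair_params, Event("cluster_move", 0, 1, members=(0, 1)))
        assert np.array_equal(state.positions[:, 0], r0[:, 0] + 1)  # moved south
        assert state.bond_multiplicity(0, 1) == 1
        state.validate(lam=pair_params.lam)

    def test_monomer_move_severs_all_bonds(self):
        state = make_fixture("plus5")
        p = SimParams(L=state.L, lam=5, eps_sp=2.0, n_particles=5)
        place_bond(state, p, 0, 1)
        place_bond(state, p, 0, 2)
        # the N arm (particle 1) hops north, away from the center
        apply_event(state, p, Event("monomer_move", 1, 0))
        assert state.used_valency[1] == 0
        assert state.bond_multiplicity(0, 1) == 0
        assert state.bond_multiplicity(0, 2) == 1  # untouched bond remains
        state.validate(lam=p.lam)


class TestRunTrajectory:
    def test_zero_duration_keeps_initial_snapshot_only(self):
        p = SimParams(L=10, lam=1, eps_sp=1.0, n_particles=5, t_end=0.0)
        traj = run_trajectory(p, engine="python")
        assert traj.snapshot_times == [0.0]
        assert traj.n_events == 0

    @pytest.mark.parametrize("engine", ["python", "fast"])
    def test_state_valid_and_particles_conserved(self, engine):
        p = SimParams(
            L=12, lam=3, eps_sp=2.0, n_particles=20, t_end=20.0,
            snapshot_interval=5.0, seed=8,
        )
        traj = run_trajectory(p, engine=engine)
        assert traj.snapshot_times == [0.0, 5.0, 10.0, 15.0, 20.0]
        for snap in traj.snapshots:
            assert snap.n_particles == 20
            assert (snap.grid >= 0).sum() == 20
            snap.validate(lam=p.lam)

    @pytest.mark.parametrize("engine", ["python", "fast"])
    def test_identical_seed_identical_trajectory(self, engine):
        p = SimParams(L=10, lam=2, eps_sp=1.5, n_particles=12, t_end=15.0, seed=42)
        a = run_trajectory(p, engine=engine)
        b = run_trajectory(p, engine=engine)
        assert a.n_events == b.n_events
        assert np.array_equal(a.final_state.positions, b.final_state.positions)
        assert a.final_state.bonds == b.final_state.bonds

    def test_observers_receive_snapshot_ticks(self):
        p = SimParams(L=10, lam=1, eps_sp=1.0, n_particles=5, t_end=4.0,
                      snapshot_interval=2.0)
        seen = []
        run_trajectory(p, observers=[lambda t, s: seen.append(t)], engine="fast")
        assert seen == [0.0, 2.0, 4.0]

    def test_engines_agree_statistically_on_bond_counts(self):
        """Both engines should reach the same bonded steady state within
        Monte-Carlo error on a small dense system."""
        p = SimParams(L=6, lam=2, eps_sp=1.5, n_particles=14, t_end=40.0)
        means = {}
        for engine in ("python", "fast"):
            totals = []
            for seed in range(12):
                traj = run_trajectory(p.with_(seed=seed), engine=engine)
                totals.append(sum(traj.final_state.bonds.values()))
            means[engine] = np.mean(totals)
        assert means["python"] == pytest.approx(means["fast"], abs=3.0)
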