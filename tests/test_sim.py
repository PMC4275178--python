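"""Lattice simulator: initialization, reaction enumeration, Gillespie
sampling oracles, conservation and limiting behaviour."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given
from hypothesis import strategies as st

from sirswitch.sim import (
    A, Boundary, ConservationError, DEFAULT_RATES, E, InfeasibleStateError,
    Kernel, LatticeState, M, RateSet, S, SimConfig, U,
    apply_reaction, competitive_inhibition, core_propensities,
    enumerate_reactions, gillespie_step, init_lattice, simulate,
    sir_occupancy)


def decay_only_rates(**kw):
    return RateSet(k_basal_acetyl=0, k_sir_deacetyl=0, k_txn_feedback=0,
                   k_sir_bind=0, k_activation=0, k_sir_unbind=0, **kw)


class TestInitLattice:
    def test_all_active_full_free_pool(self):
        cfg = SimConfig(L=4, N_sir_total=2, locus_window=(1, 4),
                        t_record=1.0, t_burn=0.0)
        st_ = init_lattice(cfg, "all_active")
        assert st_.sites.tolist() == [E, E, E, E]
        assert st_.free_sir == 2

    def test_all_silenced_without_pinning(self):
        cfg = SimConfig(L=4, N_sir_total=4, locus_window=(1, 4),
                        t_record=1.0, t_burn=0.0,
                        boundary=Boundary(distal_pinned_active=False))
        st_ = init_lattice(cfg, "all_silenced")
        assert st_.sites.tolist() == [S, S, S, S]
        assert st_.free_sir == 0

    def test_all_silenced_infeasible_with_default_supply(self):
        cfg = SimConfig()  # L=200, N=100
        with pytest.raises(InfeasibleStateError):
            init_lattice(cfg, "all_silenced")

    def test_explicit_state_conservation_enforced(self):
        cfg = SimConfig(L=4, N_sir_total=2, locus_window=(1, 4),
                        t_record=1.0, t_burn=0.0)
        bad = LatticeState(np.array([S, S, S, E], np.uint8),
                           free_sir=2, N_sir_total=2)
        with pytest.raises(ConservationError):
            init_lattice(cfg, "explicit", explicit=bad)

    def test_telomere_block_and_random_satisfy_invariants(self):
        cfg = SimConfig(L=30, N_sir_total=10, locus_window=(1, 10),
                        t_record=1.0, t_burn=0.0)
        blk = init_lattice(cfg, "telomere_block", block_size=8)
        assert blk.sites[:8].tolist() == [S] * 8
        blk.check()
        rnd = init_lattice(cfg, "random")
        rnd.check()
        assert rnd.sites[-1] == E  # pinned


class TestEnumerateReactions:
    def small(self, sites, free, N, boundary=None):
        return LatticeState(np.array(sites, np.uint8), free, N)

    def test_no_sir_reactions_without_s_sites(self):
        # virtual nucleation off: no S anywhere -> no A->U boost, no U->S
        state = self.small([E, U, U], 3, 3)
        rx = enumerate_reactions(state, RateSet(), 0.0,
                                 Boundary(telomere_nucleation=False,
                                          distal_pinned_active=True))
        kinds = {(r.from_state, r.to_state) for r, _ in rx}
        assert (U, S) not in kinds

    def test_nucleation_boundary_feeds_first_site(self):
        state = self.small([U, U, U], 3, 3)
        rates = RateSet(kernel=Kernel.nearest_neighbor())
        for strength in (1.0, 0.05):
            rx = enumerate_reactions(
                state, rates, 0.0, Boundary(nucleation_strength=strength))
            u_to_s = [(r, p) for r, p in rx if r.to_state == S]
            assert len(u_to_s) == 1 and u_to_s[0][0].site == 0
            assert u_to_s[0][1] == pytest.approx(
                rates.k_sir_bind * strength)

    def test_deacetylation_counts_flanking_s_sites(self):
        for I in (0.0, 1.0, 3.0):
            state = self.small([S, A, S, E], 0, 2)
            rates = RateSet(kernel=Kernel.nearest_neighbor())
            rx = enumerate_reactions(state, rates, I,
                                     Boundary(telomere_nucleation=False))
            a_to_u = [p for r, p in rx
                      if r.site == 1 and r.to_state == U][0]
            f = competitive_inhibition(I)
            assert a_to_u == pytest.approx(
                rates.k_mark_loss + 2 * f * rates.k_sir_deacetyl)

    def test_empty_pool_blocks_binding(self):
        state = self.small([S, U, U, E], 0, 1)
        rx = enumerate_reactions(state, RateSet(), 0.0, Boundary())
        assert all(r.to_state != S for r, _ in rx)

    def test_pinned_site_never_reacts(self):
        state = self.small([U, U, E], 2, 2)
        rx = enumerate_reactions(state, RateSet(), 0.0, Boundary())
        assert all(r.site != 2 for r, _ in rx)

    def test_methylation_requires_active_neighbor(self):
        state = self.small([U, E, U, E], 2, 2)
        rx = enumerate_reactions(state, RateSet(), 0.0, Boundary())
        to_m = {r.site for r, p in rx if r.to_state == M}
        assert to_m == {0, 2}

    @given(seed=st.integers(0, 10_000), I=st.floats(0.0, 4.0))
    def test_compiled_core_matches_reference_enumeration(self, seed, I):
        """The numba propensity vector equals the pure-Python one on random
        states (dual-route check of the reaction graph)."""
        rng = np.random.default_rng(seed)
        L, N = 24, 10
        sites = rng.integers(0, 5, L).astype(np.uint8)
        sites[-1] = E
        n_s = int((sites == S).sum())
        if n_s > N:
            sites[np.flatnonzero(sites == S)[: n_s - N]] = U
        state = LatticeState(sites, N - int((sites == S).sum()), N)
        rates = RateSet(kernel=Kernel.exponential(2.0, 3))
        ref = enumerate_reactions(state, rates, I, Boundary())
        core = core_propensities(state, rates, I, Boundary())
        ref_map = {(r.site, r.to_state): p for r, p in ref}
        core_map = {(int(s), int(t)): p for s, t, p in core}
        assert set(ref_map) == set(core_map)
        for k in ref_map:
            assert ref_map[k] == pytest.approx(core_map[k], rel=1e-12)


class TestGillespieStep:
    def test_absorbing_state_signalled(self, rng):
        state = LatticeState(np.array([U, U, E], np.uint8), 2, 2)
        new, dt = gillespie_step(state, [], rng)
        assert dt is None and new is state

    def test_waiting_time_exponential_mean(self, rng):
        """Mean dt over 1e5 draws matches 1/rate within 2%."""
        state = LatticeState(np.array([U, E], np.uint8), 1, 1)
        from sirswitch.sim import Reaction
        a = 3.7
        rxs = [(Reaction(0, U, A), a)]
        dts = [gillespie_step(state, rxs, rng)[1] for _ in range(100_000)]
        assert np.mean(dts) == pytest.approx(1 / a, rel=0.02)

    def test_selection_frequency_proportional_to_propensity(self, rng):
        """Propensities [1, 3]: second reaction fires ~75% of the time."""
        state = LatticeState(np.array([U, E], np.uint8), 1, 1)
        from sirswitch.sim import Reaction
        rxs = [(Reaction(0, U, A), 1.0), (Reaction(0, U, M), 3.0)]
        picks = 0
        n = 100_000
        for _ in range(n):
            new, _ = gillespie_step(state, rxs, rng)
            picks += new.sites[0] == M
        assert picks / n == pytest.approx(0.75, abs=0.01)

    def test_apply_reaction_returns_sir_to_pool(self):
        from sirswitch.sim import Reaction
        state = LatticeState(np.array([S, U, E], np.uint8), 1, 2)
        new = apply_reaction(state, Reaction(0, S, U))
        assert new.free_sir == 2 and new.n_S == 0


class TestSimulate:
    def test_decay_limit_reaches_all_unmodified(self):
        """With only mark loss, every interior site ends unmodified and the
        non-U count never increases."""
        cfg = SimConfig(L=30, N_sir_total=10, rates=decay_only_rates(),
                        locus_window=(1, 20), t_record=30.0, t_burn=0.0)
        init = init_lattice(cfg, "telomere_block", block_size=10)
        traj = simulate(cfg, initial=init, seed=4)
        final = traj.final_state
        assert final.sites[:-1].tolist() == [U] * 29
        assert final.free_sir == 10
        non_u = (traj.snapshots[:, :-1] != U).sum(axis=1)
        assert np.all(np.diff(non_u) <= 0)
        assert traj.occupancy[-1] == 0.0

    def test_determinism_same_seed(self, small_sim_config):
        t1 = simulate(small_sim_config, init_mode="random", seed=7)
        t2 = simulate(small_sim_config, init_mode="random", seed=7)
        assert np.array_equal(t1.occupancy, t2.occupancy)
        assert np.array_equal(t1.final_state.sites, t2.final_state.sites)
        assert t1.n_events == t2.n_events
        t3 = simulate(small_sim_config, init_mode="random", seed=8)
        assert not np.array_equal(t1.occupancy, t3.occupancy)

    def test_conservation_over_1e5_events(self):
        """count(S) + free_sir stays exactly at the supply after every one
        of >= 1e5 events on the default lattice."""
        cfg = SimConfig(rates=DEFAULT_RATES)
        init = init_lattice(cfg, "telomere_block")
        traj = simulate(cfg, initial=init, seed=99, duration=5e3,
                        max_events=100_000, keep_snapshots=False)
        assert traj.n_events >= 100_000
        assert traj.conservation_ok
        assert traj.final_state.n_S + traj.final_state.free_sir == 100

    def test_pinned_boundary_never_changes(self, small_sim_config):
        traj = simulate(small_sim_config, init_mode="random", seed=3)
        assert np.all(traj.snapshots[:, -1] == E)

    def test_occupancy_bounds_and_burn_mask(self, small_sim_config):
        traj = simulate(small_sim_config, init_mode="random", seed=5)
        assert traj.occupancy.min() >= 0 and traj.occupancy.max() <= 1
        assert traj.burn_mask.sum() > 0
        occ = sir_occupancy(traj)
        assert 0 <= occ <= 1

    def test_rewindowed_occupancy_from_snapshots(self, small_sim_config):
        traj = simulate(small_sim_config, init_mode="telomere_block", seed=6)
        full = sir_occupancy(traj, window=(1, small_sim_config.L))
        sub = sir_occupancy(traj, window=(1, 5))
        assert 0 <= full <= 1 and 0 <= sub <= 1

    def test_monotone_inhibitor_response(self):
        """Ensemble-mean occupancy is non-increasing in I (within noise)."""
        cfg = SimConfig(L=60, N_sir_total=30, rates=DEFAULT_RATES,
                        locus_window=(2, 20), t_burn=2.0, t_record=12.0)
        means, ses = [], []
        for I in (0.0, 1.0, 4.0):
            occ = []
            for s in range(50):
                traj = simulate(replace(cfg, I=I),
                                init_mode="telomere_block",
                                seed=1000 + s, keep_snapshots=False)
                occ.append(sir_occupancy(traj))
            means.append(np.mean(occ))
            ses.append(np.std(occ, ddof=1) / np.sqrt(len(occ)))
        for a, b, sa, sb in zip(means, means[1:], ses, ses[1:]):
            assert b <= a + 2 * np.hypot(sa, sb)


class TestRateSetValidation:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            RateSet(k_sir_bind=-1.0)

    def test_kernel_must_be_non_increasing(self):
        with pytest.raises(ValueError):
            Kernel((0.5, 1.0))

    def test_inhibitor_response_contract(self):
        r = RateSet()
        assert r.f(0.0) == 1.0
        assert r.f(4.0) == pytest.approx(0.2)
        assert r.f(1.0) < r.f(0.5)
        with pytest.raises(ValueError):
            r.f(-1.0)


class TestRateSearch:
    def small_config(self):
        from sirswitch.sim import Boundary
        return SimConfig(L=40, N_sir_total=20, locus_window=(2, 14),
                         t_burn=2.0, t_record=8.0,
                         boundary=Boundary(nucleation_strength=0.05))

    def test_vacuous_criterion_accepts_first_sample(self):
        from sirswitch.sim import RateSearchConfig, find_bistable_rates
        search = RateSearchConfig(n_candidates=1, n_rep=1, min_gap=-1.0,
                                  t_pregrow=10.0, require_closure=False)
        rates, record = find_bistable_rates(search, seed=3,
                                            base_config=self.small_config())
        assert record["candidate_index"] == 0
        assert set(record["rates"]) >= set(search.bounds)

    def test_zero_binding_bounds_cannot_pass(self):
        """Without Sir binding the silenced branch cannot persist, so the
        search must fail loudly rather than return a rate set."""
        from sirswitch.sim import (RateSearchConfig, SearchFailureError,
                                   find_bistable_rates)
        bounds = dict(RateSearchConfig().bounds)
        bounds["k_sir_bind"] = (1e-9, 1e-9)
        search = RateSearchConfig(bounds=bounds, n_candidates=3, n_rep=2,
                                  min_gap=0.2, t_pregrow=15.0,
                                  require_closure=False)
        with pytest.raises(SearchFailureError):
            find_bistable_rates(search, seed=5,
                                base_config=self.small_config())

    def test_shipped_rates_replay_acceptance_criterion(self):
        """The shipped wild-type rate set passes the very criterion the
        search accepts on: history-conditioned gap at I=0 above threshold,
        gap closure at I=4."""
        from sirswitch.sim import RateSearchConfig, history_gap
        crit = RateSearchConfig()
        cfg = SimConfig(rates=DEFAULT_RATES)
        gap0, se0 = history_gap(cfg, probe_I=0.0, n_rep=crit.n_rep,
                                t_pregrow=crit.t_pregrow, seed=42)
        assert gap0 >= crit.min_gap - 2 * se0
        gap4, se4 = history_gap(cfg, probe_I=4.0, n_rep=crit.n_rep,
                                t_pregrow=crit.t_pregrow, seed=43)
        assert abs(gap4) <= crit.closure_tol + 2 * se4

    def test_shipped_rates_bistable_branch_ordering(self):
        """At I=0 the silenced-history branch keeps a distinctly higher
        locus occupancy than the active-history branch."""
        from sirswitch.sim import history_gap
        gap, se = history_gap(SimConfig(), probe_I=0.0, n_rep=10, seed=7)
        assert gap > 3 * se
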