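"""Attempt loop, replication, generations, trajectories and lineage trees."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import cpgsim as c
from cpgsim import _kernels
from cpgsim.engine import (
    SimulationConfig,
    all_h,
    all_m,
    all_u,
    attempt,
    choose_event,
    from_string,
    replicate,
    run_generation,
    state_counts,
    to_string,
)
from cpgsim.model_core import (
    CATALOGUE,
    MEDIATOR_CODES,
    PRODUCT_CODES,
    REACTION_IDS,
    TARGET_CODES,
    make_scheme,
)

states_strategy = st.lists(st.integers(0, 2), min_size=2, max_size=60).map(
    lambda xs: np.array(xs, np.int8)
)


class TestStateHelpers:
    def test_string_round_trip(self):
        s = "uhmmhu"
        assert to_string(from_string(s)) == s

    def test_counts(self):
        assert state_counts(from_string("uuhm")) == (2, 1, 1)


class TestChooseEvent:
    def test_all_zero_rates_always_noop(self, rng):
        scheme = c.make_scheme({})
        assert all(choose_event(scheme, rng) is None for _ in range(300))

    def test_single_rate_frequency(self, rng):
        scheme = c.make_scheme({"h+": 0.5})
        n = 100_000
        hits = sum(choose_event(scheme, rng) == "h+" for _ in range(n))
        se = np.sqrt(0.25 / n)
        assert abs(hits / n - 0.5) < 3 * se


class TestAttempt:
    def test_sure_reaction_on_all_u(self, rng):
        state = all_u(10)
        _, completed, rid = attempt(state, c.make_scheme({"u+": 1.0}), rng)
        assert completed and rid == "u+"
        assert state_counts(state) == (9, 1, 0)

    def test_collaborative_reaction_needs_existing_mediator(self, rng):
        state = all_u(10)
        scheme = c.make_scheme({"u+m": 1.0})
        for _ in range(50):
            _, completed, _ = attempt(state, scheme, rng)
            assert not completed  # no m site exists to mediate
        assert state_counts(state) == (10, 0, 0)

    def test_two_site_collaboration(self, rng):
        # [u, m] under u+m: only site 0 can change, mediated by site 1
        scheme = c.make_scheme({"u+m": 1.0})
        seen = set()
        for _ in range(200):
            state = from_string("um")
            _, completed, _ = attempt(state, scheme, rng)
            seen.add((to_string(state), completed))
        assert seen == {("hm", True), ("um", False)}


class TestReplicate:
    def test_all_m_becomes_all_h(self, rng):
        assert to_string(replicate(all_m(80), rng)) == "h" * 80

    def test_all_u_unchanged(self, rng):
        assert (replicate(all_u(80), rng) == 0).all()

    def test_h_resolves_half_half(self, rng):
        out = replicate(all_h(10_000), rng)
        n_u = int((out == 0).sum())
        assert abs(n_u - 5000) < 4 * np.sqrt(10_000 * 0.25)

    @given(states_strategy)
    def test_never_creates_m_never_destroys_u(self, state):
        rng = np.random.default_rng(7)
        out = replicate(state, rng)
        assert (out != 2).all()
        assert (out[state == 0] == 0).all()
        assert out.size == state.size


class TestRunGeneration:
    def test_zero_scheme_only_replicates(self, rng):
        cfg = SimulationConfig(L=40, generations=1)
        out, rec = run_generation(all_m(40), c.make_scheme({}), cfg, rng)
        assert rec.n_m == 0 and rec.n_h == 40
        assert rec.completions.sum() == 0
        assert rec.attempts == cfg.attempts_per_generation

    def test_maintenance_restores_m_after_replication(self, rng, standard_scheme):
        # replication zeroes m; strong h+ restores it within the generation
        cfg = SimulationConfig(L=80, generations=1)
        out, rec = run_generation(all_m(80), standard_scheme, cfg, rng)
        assert rec.n_m > 70

    def test_counts_conserved(self, rng, collab_scheme):
        cfg = SimulationConfig(L=80, generations=1)
        out, rec = run_generation(all_m(80), collab_scheme, cfg, rng)
        assert rec.n_u + rec.n_h + rec.n_m == 80


class TestTrajectory:
    def test_seed_determinism_bit_identical(self, collab_scheme):
        cfg = SimulationConfig(L=80, generations=40, seed=123,
                               record_full_states=True)
        a = c.run_trajectory(all_m(80), collab_scheme, cfg)
        b = c.run_trajectory(all_m(80), collab_scheme, cfg)
        assert np.array_equal(a.n_u, b.n_u)
        assert np.array_equal(a.completions, b.completions)
        assert np.array_equal(a.states, b.states)

    def test_counts_sum_to_L_every_generation(self, collab_scheme):
        cfg = SimulationConfig(L=60, generations=50, seed=5)
        traj = c.run_trajectory(all_u(60), collab_scheme, cfg)
        assert ((traj.n_u + traj.n_h + traj.n_m) == 60).all()

    def test_stop_rule_truncates(self, rng, standard_scheme):
        cfg = SimulationConfig(L=80, generations=100, seed=2)
        traj = c.run_trajectory(all_m(80), standard_scheme, cfg,
                                stop_rule=lambda g, u, h, m: g >= 7)
        assert traj.n_generations == 7
        assert traj.termination == "stopped"

    def test_poisson_attempt_counts_vary_around_mean(self, collab_scheme):
        cfg = SimulationConfig(L=80, generations=30, seed=8,
                               attempt_count_mode="poisson")
        traj = c.run_trajectory(all_m(80), collab_scheme, cfg)
        assert traj.attempts.std() > 0
        assert abs(traj.attempts.mean() - 8000) < 4 * np.sqrt(8000 / 30)

    def test_mismatched_init_length_rejected(self, collab_scheme):
        cfg = SimulationConfig(L=80, generations=5)
        with pytest.raises(ValueError):
            c.run_trajectory(all_m(40), collab_scheme, cfg)


def exact_one_attempt_matrix(scheme):
    """Brute-force one-attempt transition matrix for a 2-site island.

    Enumerates reaction x target (x the forced mediator, the other site) and
    accumulates probabilities over the 9 joint states.  Independent of the
    simulation code: uses only the catalogue's declared transitions.
    """
    idx = {(a, b): 3 * a + b for a in range(3) for b in range(3)}
    P = np.zeros((9, 9))
    rates = [scheme.rates[r] for r in REACTION_IDS]
    for (a, b), i in idx.items():
        stay = 1.0 - sum(rates)  # no-op draw
        for k, rid in enumerate(REACTION_IDS):
            spec = CATALOGUE[rid]
            for target in (0, 1):
                pr = rates[k] * 0.5
                s = [a, b]
                mediator_ok = (not spec.is_collaborative
                               or s[1 - target] == int(spec.mediator_state))
                if s[target] == int(spec.target_state) and mediator_ok:
                    s[target] = int(spec.product_state)
                    P[i, idx[(s[0], s[1])]] += pr
                else:
                    stay += pr
        P[i, i] += stay
    return P


class TestOneAttemptOracle:
    def test_kernel_matches_enumerated_transition_matrix(self):
        scheme = make_scheme({rid: 0.05 for rid in REACTION_IDS})
        P = exact_one_attempt_matrix(scheme)
        assert np.allclose(P.sum(axis=1), 1.0)
        cum = np.cumsum(scheme.rate_vector())
        rng = np.random.default_rng(31)
        n = 30_000
        comp = np.zeros(12, np.int64)
        for i in range(9):
            start = np.array([i // 3, i % 3], np.int8)
            counts = np.zeros(9)
            for _ in range(n):
                s = start.copy()
                _kernels.run_attempts(s, cum, TARGET_CODES, PRODUCT_CODES,
                                      MEDIATOR_CODES, 1, rng, comp)
                counts[3 * s[0] + s[1]] += 1
            emp = counts / n
            se = np.sqrt(np.maximum(P[i] * (1 - P[i]), 1e-12) / n)
            assert (np.abs(emp - P[i]) <= 4 * se + 1e-9).all(), (i, emp, P[i])
            # transitions the enumeration forbids must never occur
            assert (emp[P[i] == 0] == 0).all()

    def test_reference_attempt_matches_enumerated_matrix(self):
        scheme = make_scheme({rid: 0.05 for rid in REACTION_IDS})
        P = exact_one_attempt_matrix(scheme)
        rng = np.random.default_rng(17)
        n = 10_000
        for i in (0, 4, 5, 8):  # uu, hh, hm, mm
            start = np.array([i // 3, i % 3], np.int8)
            counts = np.zeros(9)
            for _ in range(n):
                s = start.copy()
                attempt(s, scheme, rng)
                counts[3 * s[0] + s[1]] += 1
            emp = counts / n
            se = np.sqrt(np.maximum(P[i] * (1 - P[i]), 1e-12) / n)
            assert (np.abs(emp - P[i]) <= 4 * se + 1e-9).all()


class TestPopulation:
    def test_leaf_count(self, rng, standard_scheme):
        cfg = SimulationConfig(L=20, generations=1)
        leaves = c.population_run(all_m(20), standard_scheme, cfg, divisions=5,
                                  rng=rng)
        assert leaves.shape == (32, 20)

    def test_divisions_cap(self, rng, standard_scheme):
        cfg = SimulationConfig(L=20, generations=1)
        with pytest.raises(ValueError):
            c.population_run(all_m(20), standard_scheme, cfg, divisions=40,
                             rng=rng)

    def test_standard_population_variance_grows_with_divisions(self, standard_scheme):
        # under the standard model descendant methylation densities drift
        # apart: leaf-level variance increases with the number of divisions
        variances = []
        for d in range(1, 9):
            rng = np.random.default_rng(100 + d)
            leaves = c.population_run(all_m(80), standard_scheme,
                                      SimulationConfig(L=80, generations=1),
                                      divisions=d, rng=rng)
            levels = [c.methylation_level(s) for s in leaves]
            variances.append(np.var(levels))
        rho, _ = stats.spearmanr(range(1, 9), variances)
        assert rho > 0.5

    def test_bistable_population_is_bimodal(self, collab_scheme):
        # descendant populations are mosaics of M and U cells; intermediate
        # methylation levels are avoided
        rng = np.random.default_rng(77)
        leaves = c.population_run(all_m(80), collab_scheme,
                                  SimulationConfig(L=80, generations=1),
                                  divisions=7, rng=rng)
        levels = [c.methylation_level(s) for s in leaves]
        frac_u, frac_int, frac_m = c.bimodality_summary(levels)
        assert frac_int < 0.05
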