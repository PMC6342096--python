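import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom, chisquare, poisson

import gridpop as gp
from gridpop.process import (dispersal_many, initial_state_logpseudodensity,
                             neighborhood_mean)


def make_state(N_r, year=0):
    return gp.PopulationState(year=year, N_r=np.asarray(N_r, dtype=np.int64))


class TestGrowth:
    def test_zero_field_absorbing(self, lattice3, rng):
        state = make_state(np.zeros(9))
        gp.growth_step(state, gp.GrowthParams(alpha0=2.0), lattice3, rng)
        assert state.N_h.sum() == 0

    def test_reference_growth_rate_at_zero_covariates(self, lattice3):
        # intercept 0.332 gives r ~= 1.39 where covariates vanish
        r = gp.GrowthParams(alpha0=0.332).rates(lattice3)
        np.testing.assert_allclose(r, 1.39, atol=0.005)
        assert gp.GrowthParams(alpha0=0.332).check_cap(lattice3)
        assert not gp.GrowthParams(alpha0=0.41).check_cap(lattice3)

    def test_poisson_moments(self, rng):
        land = gp.build_lattice(1, 1, 2.0)
        draws = np.empty(100_000)
        state = make_state([50])
        growth = gp.GrowthParams(alpha0=np.log(1.2))
        for i in range(draws.size):
            gp.growth_step(state, growth, land, rng)
            draws[i] = state.N_h[0]
        se = np.sqrt(60.0 / draws.size)
        assert abs(draws.mean() - 60.0) < 3 * se


class TestHunting:
    def test_no_hunting_identity(self):
        state = make_state([5, 3])
        state.N_h = np.array([7, 4])
        gp.hunting_step(state, np.zeros(2, dtype=int))
        np.testing.assert_array_equal(state.N_d, [7, 4])

    def test_exact_subtraction(self):
        state = make_state([5, 3])
        state.N_h = np.array([5, 3])
        gp.hunting_step(state, np.array([2, 3]))
        np.testing.assert_array_equal(state.N_d, [3, 0])

    def test_overharvest_raises(self):
        state = make_state([1, 0])
        state.N_h = np.array([1, 0])
        with pytest.raises(gp.InfeasibleStateError):
            gp.hunting_step(state, np.array([2, 0]))


class TestDispersal:
    def test_identity_kernel_preserves_field(self, lattice3, rng):
        state = make_state(np.arange(9))
        state.N_d = np.arange(9, dtype=np.int64)
        M = gp.short_term_kernel(lattice3, gp.MovementParams(-1e3))
        k = gp.MovementKernel(M, gp.annual_kernel(M, 16), 16)
        nxt = gp.dispersal_step(state, k, rng)
        np.testing.assert_array_equal(nxt.N_r, state.N_d)

    @given(st.lists(st.integers(0, 40), min_size=9, max_size=9),
           st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_total_conserved_exactly(self, counts, seed):
        land = gp.build_lattice(3, 3, 2.0)
        k = gp.build_kernel(land, gp.MovementParams(-0.8))
        state = make_state(counts)
        state.N_d = np.asarray(counts, dtype=np.int64)
        nxt = gp.dispersal_step(state, k, np.random.default_rng(seed))
        assert nxt.N_r.sum() == sum(counts)

    def test_two_cell_flow_matches_binomial_pmf(self, rng):
        """10 animals, 5% leave: flow to the other cell is Bin(10, 0.05)."""
        land = gp.build_lattice(1, 2, 2.0)
        M = np.array([[0.95, 0.05], [0.05, 0.95]])
        k = gp.MovementKernel(gp.short_term_kernel(land, gp.MovementParams(-1.0)),
                              M, 1)
        reps = 100_000
        N_d = np.zeros((reps, 2), dtype=np.int64)
        N_d[:, 0] = 10
        out = dispersal_many(N_d, M, rng)
        observed = np.bincount(out[:, 1], minlength=11)
        expected = binom.pmf(np.arange(11), 10, 0.05) * reps
        keep = expected > 5
        stat, p = chisquare(observed[keep], expected[keep] * observed[keep].sum()
                            / expected[keep].sum())
        assert p > 0.001

    def test_bad_kernel_rows_rejected(self, lattice3, rng):
        state = make_state(np.ones(9))
        state.N_d = np.ones(9, dtype=np.int64)
        bad = gp.MovementKernel(gp.short_term_kernel(lattice3, gp.MovementParams(-1.0)),
                                np.full((9, 9), 0.5), 16)
        with pytest.raises(ValueError):
            gp.dispersal_step(state, bad, rng)


class TestInitialState:
    def test_zero_seed_stays_zero(self, lattice3, rng):
        state = gp.initial_state_sample(lattice3, np.zeros(9, dtype=int), 5, rng)
        assert state.N_r.sum() == 0

    def test_mask_forces_zero_everywhere(self, lattice3, rng):
        lattice3.present2000 = np.zeros(9, dtype=int)
        state = gp.initial_state_sample(lattice3, np.full(9, 7), 2, rng)
        assert state.N_r.sum() == 0

    def test_conditional_mean_uniform_field(self, lattice3):
        # uniform areas and uniform counts c: every conditional mean equals c
        field = np.full(9, 6)
        for i in range(9):
            assert neighborhood_mean(field, lattice3, i) == pytest.approx(6.0)

    def test_pseudodensity_two_cell_hand_computation(self):
        land = gp.build_lattice(1, 2, 2.0)
        land.area[:] = 1.0
        expected = poisson.logpmf(2, 3) + poisson.logpmf(3, 2)
        got = initial_state_logpseudodensity(np.array([2, 3]), land)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_pseudodensity_conventions(self, lattice3):
        # all-zero field scores 0 under the 0·log0 = 0 convention
        assert initial_state_logpseudodensity(np.zeros(9, dtype=int), lattice3) == 0.0
        # occupied cell with empty neighborhood is impossible
        field = np.zeros(9, dtype=int)
        field[0] = 2
        assert initial_state_logpseudodensity(field, lattice3) == -np.inf

    def test_pseudodensity_mask_violation(self, lattice3):
        lattice3.present2000 = np.zeros(9, dtype=int)
        assert initial_state_logpseudodensity(np.ones(9, dtype=int),
                                              lattice3) == -np.inf

    def test_vectorized_pseudodensity_matches_scalar(self, small_landscape, rng):
        from gridpop.process import initial_pseudodensity_many
        fields = rng.poisson(2.0, size=(6, small_landscape.n)).astype(np.int64)
        fields[:, small_landscape.present2000 == 0] = 0
        batch = initial_pseudodensity_many(fields, small_landscape)
        single = [initial_state_logpseudodensity(f, small_landscape)
                  for f in fields]
        np.testing.assert_allclose(batch, single, atol=1e-9)


class TestTrajectory:
    def test_zero_years_returns_initial_only(self, lattice3, rng):
        init = make_state(np.ones(9))
        k = gp.build_kernel(lattice3, gp.MovementParams(-1.0))
        states = gp.simulate_trajectory(init, 0, gp.GrowthParams(0.1), k,
                                        lattice3, rng)
        assert states == [init]

    def test_branching_mean_growth(self, rng):
        """Without hunting, E[total at t] = r^t * total(0)."""
        land = gp.build_lattice(2, 2, 2.0)
        k = gp.build_kernel(land, gp.MovementParams(-1.0))
        growth = gp.GrowthParams(alpha0=np.log(1.3))
        reps, years, n0 = 600, 4, 40
        finals = np.empty(reps)
        for i in range(reps):
            states = gp.simulate_trajectory(make_state([10, 10, 10, 10]),
                                            years, growth, k, land, rng)
            finals[i] = states[-1].N_r.sum()
        expected = 1.3 ** years * n0
        se = finals.std(ddof=1) / np.sqrt(reps)
        assert abs(finals.mean() - expected) < 3 * se

    def test_total_hunting_causes_extinction(self, lattice3, rng):
        k = gp.build_kernel(lattice3, gp.MovementParams(-1.0))

        def cull_all(state, rng_):
            return state.N_h.copy()

        states = gp.simulate_trajectory(make_state(np.full(9, 3)), 3,
                                        gp.GrowthParams(0.2), k, lattice3, rng,
                                        hunting_policy=cull_all)
        assert states[1].N_r.sum() == 0
        assert states[-1].N_r.sum() == 0

    def test_dispersal_conserves_total_every_year(self, small_landscape, rng):
        k = gp.build_kernel(small_landscape, gp.MovementParams(-1.5))
        init = make_state(rng.poisson(3, small_landscape.n))
        states = gp.simulate_trajectory(init, 5, gp.GrowthParams(np.log(1.2)),
                                        k, small_landscape, rng)
        for prev, nxt in zip(states[:-1], states[1:]):
            assert nxt.N_r.sum() == prev.N_d.sum()

    def test_export_frame_shape(self, lattice3, rng):
        from gridpop.process import trajectory_to_frame
        k = gp.build_kernel(lattice3, gp.MovementParams(-1.0))
        states = gp.simulate_trajectory(make_state(np.ones(9)), 2,
                                        gp.GrowthParams(0.0), k, lattice3, rng)
        df = trajectory_to_frame(states)
        assert set(df.columns) == {"year", "cell_id", "N_r", "N_h", "N_d", "H"}
        assert len(df) == 27
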