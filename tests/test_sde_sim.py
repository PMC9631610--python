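"""Path simulation: Euler-Maruyama vs the exact linear-SDE solution."""

import math

import numpy as np
import pytest
from scipy import stats

from gcsde import (
    GridError,
    RateParameters,
    TimeGrid,
    brownian_increments,
    constant_schedule,
    deterministic_gc,
    simulate_em,
    simulate_exact,
    sqrt_schedule,
    stochastic_integral,
    variance_gc,
)

# c^2 (1 - e^{-6}) / 6 at c=0.5, a-b=-3, t=1 (Ito-isometry closed form)
VAR_CONST_C = 0.25 * (1.0 - math.exp(-6.0)) / 6.0


@pytest.mark.parametrize("simulate", [simulate_em, simulate_exact])
class TestNoiseFreeReduction:
    def test_zero_schedule_reduces_to_deterministic(self, params, simulate):
        grid = TimeGrid(1.0, 10_000 if simulate is simulate_em else 50)
        ens = simulate(params, constant_schedule(0.0), grid, 3, seed=7)
        ref = deterministic_gc(params, grid.times)
        tol = 1e-3 if simulate is simulate_em else 1e-12
        assert np.max(np.abs(ens.values - ref)) < tol
        assert np.all(ens.values[:, 0] == params.F0)

    def test_seed_determinism(self, params, simulate):
        grid = TimeGrid(1.0, 50)
        sched = sqrt_schedule(0.5)
        a = simulate(params, sched, grid, 20, seed=11)
        b = simulate(params, sched, grid, 20, seed=11)
        np.testing.assert_array_equal(a.values, b.values)

    def test_extending_paths_preserves_earlier_ones(self, params, simulate):
        grid = TimeGrid(1.0, 50)
        sched = sqrt_schedule(0.5)
        small = simulate(params, sched, grid, 5, seed=3)
        large = simulate(params, sched, grid, 9, seed=3)
        np.testing.assert_array_equal(large.values[:5], small.values)


class TestEulerMaruyama:
    def test_terminal_mean_matches_closed_form(self, params):
        ens = simulate_em(params, sqrt_schedule(0.5), TimeGrid(1.0, 400),
                          4000, seed=5)
        term = ens.terminal
        se = term.std(ddof=1) / math.sqrt(term.size)
        assert abs(term.mean() - deterministic_gc(params, 1.0)) < 4 * se

    def test_terminal_variance_matches_ito_isometry(self, params):
        ens = simulate_em(params, constant_schedule(0.5), TimeGrid(1.0, 1000),
                          10_000, seed=6)
        assert ens.terminal.var(ddof=1) == pytest.approx(VAR_CONST_C, rel=0.10)

    def test_zero_length_grid_rejected(self, params):
        with pytest.raises(Exception, match="n_steps"):
            TimeGrid(1.0, 0)

    def test_increments_are_stored_brownian(self, params):
        grid = TimeGrid(1.0, 64)
        ens = simulate_em(params, constant_schedule(0.5), grid, 50, seed=9)
        np.testing.assert_array_equal(
            ens.increments, brownian_increments(grid, 50, seed=9)
        )

    def test_clamp_keeps_paths_in_unit_interval(self):
        p = RateParameters(a=-2.0, b=1.0, F0=0.05)
        ens = simulate_em(p, constant_schedule(2.0), TimeGrid(1.0, 200),
                          50, seed=12, clamp=True)
        assert np.all(ens.values > 0) and np.all(ens.values < 1)

    def test_exit_flags_count_boundary_crossings(self):
        p = RateParameters(a=-2.0, b=1.0, F0=0.05)
        ens = simulate_em(p, constant_schedule(2.0), TimeGrid(1.0, 200),
                          200, seed=13)
        # huge noise from F0=0.05 must push some paths out of (0, 1)
        assert ens.n_exited > 0
        crossed = np.any((ens.values <= 0) | (ens.values >= 1), axis=1)
        np.testing.assert_array_equal(ens.exit_flags, crossed)


class TestStochasticIntegral:
    def test_zero_schedule_gives_zero(self, params):
        vals = stochastic_integral(params, constant_schedule(0.0),
                                   TimeGrid(1.0, 100), 10, seed=1)
        assert np.all(vals == 0.0)

    def test_variance_matches_ito_isometry(self, params):
        vals = stochastic_integral(params, constant_schedule(0.5),
                                   TimeGrid(1.0, 2000), 40_000, seed=2)
        assert vals.var(ddof=1) == pytest.approx(VAR_CONST_C, rel=0.02)
        assert abs(vals.mean()) < 4 * vals.std(ddof=1) / math.sqrt(vals.size)

    def test_degenerate_rates_reduce_to_scaled_brownian(self):
        """With a-b ~ 0 and c = 1 the integral is B_T: variance T."""
        p = RateParameters(a=1.0 - 1e-12, b=1.0, F0=0.5)
        vals = stochastic_integral(p, constant_schedule(1.0), TimeGrid(1.0, 1),
                                   50_000, seed=3)
        assert vals.var(ddof=1) == pytest.approx(1.0, rel=0.05)

    def test_gaussian_moments_at_terminal_time(self, params):
        vals = stochastic_integral(params, sqrt_schedule(0.5),
                                   TimeGrid(1.0, 400), 100_000, seed=4)
        assert abs(stats.skew(vals)) < 0.05
        assert abs(stats.kurtosis(vals)) < 0.1

    def test_literal_ds_reading_collapses_the_variance(self, params):
        """The debug flag reproduces the double-counted-step discretisation:
        its variance is smaller by ~ds and cannot match the Ito isometry."""
        grid = TimeGrid(1.0, 100)
        dB = brownian_increments(grid, 20_000, seed=5)
        good = stochastic_integral(params, constant_schedule(0.5), grid,
                                   20_000, seed=5, increments=dB)
        literal = stochastic_integral(params, constant_schedule(0.5), grid,
                                      20_000, seed=5, increments=dB,
                                      literal_ds_factor=True)
        ratio = literal.var(ddof=1) / good.var(ddof=1)
        assert ratio == pytest.approx(grid.dt**2, rel=0.2)

    def test_shape_mismatch_rejected(self, params):
        with pytest.raises(GridError, match="shape"):
            stochastic_integral(params, constant_schedule(0.5),
                                TimeGrid(1.0, 10), 5, seed=1,
                                increments=np.zeros((5, 9)))


class TestExactScheme:
    def test_marginal_moments_exact_at_any_step_count(self, params):
        """One step or a thousand: same closed-form mean and variance."""
        sched = constant_schedule(0.5)
        target_var = variance_gc(params, sched, 1.0)
        for n_steps in (1, 1000):
            ens = simulate_exact(params, sched, TimeGrid(1.0, n_steps),
                                 20_000, seed=21)
            term = ens.terminal
            se = term.std(ddof=1) / math.sqrt(term.size)
            assert abs(term.mean() - deterministic_gc(params, 1.0)) < 4 * se
            assert term.var(ddof=1) == pytest.approx(target_var, rel=0.05)

    def test_coarse_and_fine_terminal_distributions_indistinguishable(
        self, params
    ):
        sched = sqrt_schedule(0.5)
        coarse = simulate_exact(params, sched, TimeGrid(1.0, 1), 10_000, seed=22)
        fine = simulate_exact(params, sched, TimeGrid(1.0, 500), 10_000, seed=23)
        ks = stats.ks_2samp(coarse.terminal, fine.terminal)
        assert ks.pvalue > 0.01

    def test_scenario_variance_recovery(self, params, scenario_schedules):
        for sched in scenario_schedules:
            ens = simulate_exact(params, sched, TimeGrid(1.0, 100),
                                 10_000, seed=24)
            assert ens.terminal.var(ddof=1) == pytest.approx(
                variance_gc(params, sched, 1.0), rel=0.10
            )


class TestSchemeAgreement:
    def test_em_and_exact_agree_at_terminal_time(self, params,
                                                 scenario_schedules):
        """The two simulators are mutual oracles: terminal means and
        variances agree within Monte-Carlo error."""
        n = 10_000
        for sched in scenario_schedules:
            em = simulate_em(params, sched, TimeGrid(1.0, 2000), n, seed=31)
            ex = simulate_exact(params, sched, TimeGrid(1.0, 100), n, seed=32)
            se = math.hypot(em.terminal.std(ddof=1), ex.terminal.std(ddof=1))
            se /= math.sqrt(n)
            assert abs(em.terminal.mean() - ex.terminal.mean()) < 4 * se
            assert em.terminal.var(ddof=1) == pytest.approx(
                ex.terminal.var(ddof=1), rel=0.15
            )

    def test_strong_convergence_under_refinement(self, params):
        """EM on a common Brownian path approaches the exact solution as
        the step is halved; terminal RMS error decreases monotonically."""
        sched = sqrt_schedule(0.5)
        n_paths, n_fine = 400, 1024
        fine_grid = TimeGrid(1.0, n_fine)
        dB_fine = brownian_increments(fine_grid, n_paths, seed=41)
        # pathwise-exact terminal value from the same driving noise
        ref = deterministic_gc(params, 1.0) + stochastic_integral(
            params, sched, fine_grid, n_paths, seed=41, increments=dB_fine
        )
        rms = []
        for k in range(5):  # n_steps = 64, 128, 256, 512, 1024
            factor = 2 ** (4 - k)
            n_steps = n_fine // factor
            dB = dB_fine.reshape(n_paths, n_steps, factor).sum(axis=2)
            ens = simulate_em(params, sched, TimeGrid(1.0, n_steps),
                              n_paths, seed=41, increments=dB)
            rms.append(float(np.sqrt(np.mean((ens.terminal - ref) ** 2))))
        assert all(a > b for a, b in zip(rms, rms[1:]))
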