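"""Grid-search estimation: RMSE objective, grids, recovery, tie-breaks."""

import numpy as np
import pytest

from cellcompete import (
    CompetitionSystem,
    GridSpec,
    GrowthCurve,
    LogisticParams,
    count_grid_combinations,
    fit_competition_grid,
    fit_logistic_grid,
    logistic_solution,
    rmse,
    simulate_competition,
)


def make_logistic_curve(r, K, n0, days, line="DFT1", condition="monoculture"):
    t = np.asarray(days, dtype=float) - days[0]
    counts = np.atleast_1d(logistic_solution(LogisticParams(r, K), n0, t))
    return GrowthCurve(line, condition, "100:0", "rep1",
                       np.asarray(days, dtype=float), counts)


def make_coculture_pair(sysm, n0_1, n0_2, days, step=0.01):
    days = np.asarray(days, dtype=float)
    traj = simulate_competition(sysm, n0_1, n0_2, days - days[0], step=step)
    c1 = GrowthCurve("DFT1", "coculture", "x", "rep1", days, traj.values[0])
    c2 = GrowthCurve("DFT2", "coculture", "x", "rep1", days, traj.values[1])
    return c1, c2


class TestRmse:
    def test_identical_series_is_zero(self):
        assert rmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_constant_unit_residual(self):
        assert rmse([2, 3, 4], [1, 2, 3]) == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=10), rng.normal(size=10)
        expected = np.sqrt(np.sum((a - b) ** 2) / 10)
        assert rmse(a, b) == pytest.approx(expected, rel=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse([1, 2], [1, 2, 3])


class TestGridSpec:
    def test_default_logistic_grid_has_10000_combinations(self):
        assert count_grid_combinations(GridSpec(), "logistic") == 10_000

    def test_default_competition_grid_enumerates_stated_range(self):
        # -100..100 step 1 inclusive on each axis: 201 * 201
        assert count_grid_combinations(GridSpec(), "competition") == 40_401

    def test_single_value_axes(self):
        g = GridSpec(r_min=0.4, r_max=0.4, K_min=1e5, K_max=1e5)
        assert count_grid_combinations(g, "logistic") == 1

    def test_axis_endpoints_inclusive(self):
        g = GridSpec()
        assert g.r_values()[0] == pytest.approx(0.01)
        assert g.r_values()[-1] == pytest.approx(1.0)
        assert g.K_values()[-1] == pytest.approx(1e6)
        assert g.alpha_values()[0] == -100.0 and g.alpha_values()[-1] == 100.0

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(r_min=1.0, r_max=0.5)
        with pytest.raises(ValueError):
            GridSpec(K_step=0.0)


class TestLogisticGridFit:
    def test_exact_recovery_of_on_grid_truth(self, assay_days):
        curve = make_logistic_curve(0.40, 8.2e5, 1e5, assay_days)
        res = fit_logistic_grid(curve)
        assert res.params == LogisticParams(0.40, 8.2e5)
        assert res.rmse == pytest.approx(0.0, abs=1e-6)
        assert res.n_grid_evaluated == 10_000

    def test_off_grid_truth_within_one_step(self, assay_days):
        curve = make_logistic_curve(0.405, 8.25e5, 1e5, assay_days)
        res = fit_logistic_grid(curve)
        assert abs(res.params.r - 0.405) <= 0.01 + 1e-12
        assert abs(res.params.K - 8.25e5) <= 1e4 + 1e-6

    def test_constant_data_tie_breaks_to_smallest_r(self, assay_days):
        """At n0 = K every r fits perfectly; the smallest r is returned."""
        K = 5e5
        curve = GrowthCurve("DFT1", "monoculture", "100:0", "rep1",
                            assay_days, np.full(assay_days.size, K))
        res = fit_logistic_grid(curve)
        assert res.params.K == pytest.approx(K)
        assert res.params.r == pytest.approx(0.01)
        assert res.tie_count >= 100  # whole r axis ties

    def test_all_zero_curve_rejected(self, assay_days):
        curve = GrowthCurve("DFT1", "monoculture", "100:0", "rep1",
                            assay_days, np.zeros(assay_days.size))
        with pytest.raises(ValueError, match="zero"):
            fit_logistic_grid(curve)

    def test_too_few_observations_rejected(self):
        curve = GrowthCurve("DFT1", "monoculture", "100:0", "rep1",
                            [1.0, 2.0], [1e5, 1.2e5])
        with pytest.raises(ValueError):
            fit_logistic_grid(curve)

    def test_exhaustive_optimality_vs_brute_force(self, assay_days):
        """No grid point beats the returned minimum (coarse-grid check)."""
        grid = GridSpec(r_min=0.1, r_max=0.9, r_step=0.1,
                        K_min=1e5, K_max=9e5, K_step=1e5)
        rng = np.random.default_rng(3)
        truth = make_logistic_curve(0.37, 4.4e5, 1e5, assay_days)
        noisy = truth.counts * rng.lognormal(0, 0.1, truth.counts.shape)
        curve = GrowthCurve("DFT1", "monoculture", "100:0", "rep1",
                            assay_days, noisy)
        res = fit_logistic_grid(curve, grid)
        best = min(
            rmse(logistic_solution(LogisticParams(r, K), curve.n0,
                                   curve.rel_times), curve.counts)
            for r in grid.r_values() for K in grid.K_values()
        )
        assert res.rmse == pytest.approx(best, rel=1e-12)

    def test_determinism(self, assay_days):
        curve = make_logistic_curve(0.40, 8.2e5, 1e5, assay_days)
        assert fit_logistic_grid(curve) == fit_logistic_grid(curve)


class TestCompetitionGridFit:
    def test_exact_recovery_on_coarse_grid(self, assay_days, coarse_lv_grid):
        fixed = CompetitionSystem(0.40, 0.76, 8.2e5, 4.2e5, 0, 0)
        pair = make_coculture_pair(fixed.with_coefficients(78, 15),
                                   5e4, 5e4, assay_days)
        res = fit_competition_grid(pair, fixed, coarse_lv_grid)
        assert (res.alpha, res.beta) == (78.0, 15.0)
        assert res.rmse == pytest.approx(0.0, abs=1e-3)
        assert res.n_grid_evaluated == 34 * 34

    def test_decoupled_truth_recovers_zero_coefficients(self, assay_days,
                                                        coarse_lv_grid):
        fixed = CompetitionSystem(0.40, 0.76, 8.2e5, 4.2e5, 0, 0)
        pair = make_coculture_pair(fixed, 5e4, 5e4, assay_days)
        res = fit_competition_grid(pair, fixed, coarse_lv_grid)
        assert (res.alpha, res.beta) == (0.0, 0.0)
        # each line then follows its own logistic curve
        np.testing.assert_allclose(
            pair[0].counts,
            logistic_solution(LogisticParams(0.40, 8.2e5), 5e4,
                              pair[0].rel_times),
            rtol=1e-6)

    def test_absent_line_tie_breaks_toward_zero(self, assay_days):
        """With one line extinct both coefficients are unidentifiable and
        the (0, 0) grid point is selected by the tie-break."""
        fixed = CompetitionSystem(0.40, 0.76, 8.2e5, 4.2e5, 0, 0)
        days = np.asarray(assay_days, dtype=float)
        c1 = make_logistic_curve(0.40, 8.2e5, 1e5, days, condition="coculture")
        c2 = GrowthCurve("DFT2", "coculture", "x", "rep1", days,
                         np.zeros(days.size))
        grid = GridSpec(alpha_min=-10, alpha_max=10, alpha_step=1,
                        beta_min=-10, beta_max=10, beta_step=1)
        res = fit_competition_grid((c1, c2), fixed, grid)
        assert (res.alpha, res.beta) == (0.0, 0.0)
        assert res.tie_count == 21 * 21

    def test_mismatched_days_rejected(self, assay_days):
        fixed = CompetitionSystem(0.40, 0.76, 8.2e5, 4.2e5, 0, 0)
        c1, c2 = make_coculture_pair(fixed, 5e4, 5e4, assay_days)
        c2_short = GrowthCurve("DFT2", "coculture", "x", "rep1",
                               c2.days[:-1], c2.counts[:-1])
        with pytest.raises(ValueError, match="days"):
            fit_competition_grid((c1, c2_short), fixed)

    def test_divergent_grid_points_scored_infinite(self, assay_days):
        """Strongly mutualistic grid points blow up and never win."""
        fixed = CompetitionSystem(1.0, 1.0, 1e5, 1e5, 0, 0)
        pair = make_coculture_pair(fixed.with_coefficients(2, 2), 5e4, 5e4,
                                   assay_days)
        grid = GridSpec(alpha_min=-100, alpha_max=2, alpha_step=2,
                        beta_min=-100, beta_max=2, beta_step=2)
        res = fit_competition_grid(pair, fixed, grid)
        assert res.n_divergent > 0
        assert np.isfinite(res.rmse)
        assert (res.alpha, res.beta) == (2.0, 2.0)

    def test_exhaustive_optimality_vs_brute_force(self, assay_days):
        fixed = CompetitionSystem(0.5, 0.7, 5e5, 4e5, 0, 0)
        rng = np.random.default_rng(11)
        c1, c2 = make_coculture_pair(fixed.with_coefficients(3, 1),
                                     5e4, 5e4, assay_days)
        noisy1 = c1.counts * rng.lognormal(0, 0.05, c1.counts.shape)
        noisy2 = c2.counts * rng.lognormal(0, 0.05, c2.counts.shape)
        c1 = GrowthCurve("DFT1", "coculture", "x", "rep1", c1.days, noisy1)
        c2 = GrowthCurve("DFT2", "coculture", "x", "rep1", c2.days, noisy2)
        grid = GridSpec(alpha_min=0, alpha_max=6, alpha_step=1,
                        beta_min=0, beta_max=6, beta_step=1)
        res = fit_competition_grid((c1, c2), fixed, grid)
        best = np.inf
        for a in grid.alpha_values():
            for b in grid.beta_values():
                traj = simulate_competition(fixed.with_coefficients(a, b),
                                            c1.n0, c2.n0, c1.rel_times)
                err = rmse(np.concatenate([traj.values[0], traj.values[1]]),
                           np.concatenate([c1.counts, c2.counts]))
                best = min(best, err)
        assert res.rmse == pytest.approx(best, rel=1e-9)
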