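"""Forward-model correctness: closed-form logistic and RK4 LV dynamics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import solve_ivp

from cellcompete import (
    CompetitionSystem,
    LogisticParams,
    logistic_solution,
    simulate_competition,
    simulate_logistic,
)
from cellcompete.growth import integrate_lv_batch, integrate_lv_scalar


class TestLogisticSolution:
    @pytest.mark.parametrize("r,K,n0", [
        (0.40, 8.2e5, 1.0e5),
        (0.76, 4.2e5, 1.0e5),
        (0.01, 1e4, 5e3),
        (1.0, 1e6, 9.9e5),
    ])
    def test_matches_numerical_integration(self, r, K, n0):
        """Closed form agrees with an independent ODE solver to 1e-6 rel."""
        params = LogisticParams(r, K)
        ts = np.linspace(0, 13, 14)
        sol = solve_ivp(lambda t, y: r * y * (1 - y / K), [0, 13], [n0],
                        t_eval=ts, rtol=1e-10, atol=1e-8)
        ours = logistic_solution(params, n0, ts)
        np.testing.assert_allclose(ours, sol.y[0], rtol=1e-6)

    def test_carrying_capacity_is_fixed_point(self):
        assert logistic_solution(LogisticParams(0.76, 4.2e5), 4.2e5, 7) == \
            pytest.approx(4.2e5)

    def test_extinction_is_absorbing(self):
        assert logistic_solution(LogisticParams(0.5, 1e5), 0.0, 5) == 0.0

    def test_rejects_nonfinite_inputs(self):
        with pytest.raises(ValueError):
            logistic_solution(LogisticParams(0.5, 1e5), float("nan"), 1.0)
        with pytest.raises(ValueError):
            logistic_solution(LogisticParams(0.5, 1e5), 1e4, float("inf"))

    @given(r=st.floats(0.01, 1.0), K=st.floats(1e4, 1e6),
           frac=st.floats(0.01, 1.0), t=st.floats(0, 50))
    def test_bounded_between_n0_and_K(self, r, K, frac, t):
        """N(t) always lies in [min(n0, K), max(n0, K)]."""
        n0 = frac * K
        v = logistic_solution(LogisticParams(r, K), n0, t)
        assert min(n0, K) - 1e-6 <= v <= max(n0, K) + 1e-6

    @given(r=st.floats(0.01, 1.0), K=st.floats(1e4, 1e6),
           frac=st.floats(0.01, 2.0))
    def test_monotone_in_time(self, r, K, frac):
        n0 = frac * K
        ts = np.linspace(0, 20, 41)
        vals = logistic_solution(LogisticParams(r, K), n0, ts)
        diffs = np.diff(vals)
        if n0 <= K:
            assert np.all(diffs >= -1e-9 * K)
        else:
            assert np.all(diffs <= 1e-9 * K)


class TestSimulateLogistic:
    def test_single_time_point_returns_n0(self):
        traj = simulate_logistic(LogisticParams(0.4, 8.2e5), 1e5, [0.0])
        assert traj.values.shape == (1, 1)
        assert traj.values[0, 0] == pytest.approx(1e5)

    def test_monotone_approach_to_K(self):
        traj = simulate_logistic(LogisticParams(0.4, 8.2e5), 1e5,
                                 np.arange(14.0))
        vals = traj.values[0]
        assert np.all(np.diff(vals) >= 0)
        assert vals[-1] <= 8.2e5

    def test_constant_at_carrying_capacity(self):
        traj = simulate_logistic(LogisticParams(0.9, 3e5), 3e5, np.arange(10.0))
        np.testing.assert_allclose(traj.values[0], 3e5, rtol=1e-12)

    def test_rejects_empty_and_unsorted_times(self):
        p = LogisticParams(0.4, 8.2e5)
        with pytest.raises(ValueError):
            simulate_logistic(p, 1e5, [])
        with pytest.raises(ValueError):
            simulate_logistic(p, 1e5, [0.0, 2.0, 1.0])
        with pytest.raises(ValueError):
            simulate_logistic(p, 1e5, [1.0, 2.0])  # must start at 0


class TestSimulateCompetition:
    def test_decoupled_limit_matches_logistic(self):
        """alpha = beta = 0 gives two independent logistic curves."""
        sysm = CompetitionSystem(0.4, 0.76, 8.2e5, 4.2e5, 0.0, 0.0)
        ts = np.arange(14.0)
        traj = simulate_competition(sysm, 9e4, 1e4, ts)
        np.testing.assert_allclose(
            traj.values[0], logistic_solution(LogisticParams(0.4, 8.2e5), 9e4, ts),
            rtol=1e-6)
        np.testing.assert_allclose(
            traj.values[1], logistic_solution(LogisticParams(0.76, 4.2e5), 1e4, ts),
            rtol=1e-6)

    def test_absent_species_stays_absent(self):
        sysm = CompetitionSystem(0.4, 0.76, 8.2e5, 4.2e5, 2.0, 3.0)
        ts = np.arange(14.0)
        traj = simulate_competition(sysm, 0.0, 1e5, ts)
        assert np.all(traj.values[0] == 0.0)
        np.testing.assert_allclose(
            traj.values[1], logistic_solution(LogisticParams(0.76, 4.2e5), 1e5, ts),
            rtol=1e-6)

    def test_step_halving_convergence(self, paper_system):
        """Halving the RK4 step changes samples by <= 1e-6 relative."""
        ts = np.arange(14.0)
        a = simulate_competition(paper_system, 9e4, 1e4, ts, step=0.01)
        b = simulate_competition(paper_system, 9e4, 1e4, ts, step=0.005)
        scale = np.max(np.abs(b.values))
        assert np.max(np.abs(a.values - b.values)) <= 1e-6 * scale

    def test_matches_independent_ode_solver(self, paper_system):
        s = paper_system
        ts = np.arange(14.0)

        def rhs(t, y):
            n1, n2 = y
            return [s.r1 * n1 * (1 - (n1 + s.alpha * n2) / s.K1),
                    s.r2 * n2 * (1 - (n2 + s.beta * n1) / s.K2)]

        ref = solve_ivp(rhs, [0, 13], [8e4, 2e4], t_eval=ts,
                        rtol=1e-10, atol=1e-8)
        ours = simulate_competition(s, 8e4, 2e4, ts, step=0.01)
        np.testing.assert_allclose(ours.values, ref.y, rtol=1e-5, atol=1e-3)

    def test_dominant_start_excludes_other_line(self, paper_system):
        """From a 90:10 start line 1 approaches K1 while line 2 dies out."""
        ts = np.arange(0.0, 61.0)
        traj = simulate_competition(paper_system, 0.9e5, 0.1e5, ts)
        assert traj.values[1, -1] < 1.0
        assert traj.values[0, -1] == pytest.approx(paper_system.K1, rel=1e-3)

    def test_nonnegative_everywhere(self, paper_system):
        ts = np.arange(0.0, 101.0)
        for f in (0.1, 0.5, 0.9):
            traj = simulate_competition(paper_system, f * 1e5, (1 - f) * 1e5, ts)
            assert np.all(traj.values >= 0.0)

    def test_mutualistic_blowup_flagged_divergent(self):
        sysm = CompetitionSystem(1.0, 1.0, 1e5, 1e5, -100.0, -100.0)
        traj = simulate_competition(sysm, 5e4, 5e4, np.arange(30.0),
                                    ceiling=1e9)
        assert traj.divergent

    def test_step_larger_than_spacing_rejected(self, paper_system):
        with pytest.raises(ValueError):
            simulate_competition(paper_system, 1e4, 1e4, [0.0, 0.5, 1.0],
                                 step=0.6)


class TestIntegratorPaths:
    def test_scalar_and_batch_paths_agree(self, paper_system):
        """The pure-Python scalar RK4 and the vectorized batch RK4 are the
        same scheme and must produce identical trajectories."""
        s = paper_system
        horizon, step = 20.0, 0.01
        n1b, n2b, div = integrate_lv_batch(
            s.r1, s.r2, s.K1, s.K2, s.alpha, s.beta,
            8e4, 2e4, [0.0, horizon], step)
        n1s, n2s, t, divs = integrate_lv_scalar(s, 8e4, 2e4, horizon, step)
        assert not div.any() and not divs
        assert n1b[0, -1] == pytest.approx(n1s, rel=1e-9, abs=1e-9)
        assert n2b[0, -1] == pytest.approx(n2s, rel=1e-9, abs=1e-9)

    def test_batch_broadcasts_over_parameters(self):
        alphas = np.array([0.0, 1.0, 10.0])
        n1, n2, div = integrate_lv_batch(
            0.4, 0.76, 8.2e5, 4.2e5, alphas, 1.0,
            5e4, 5e4, np.arange(5.0), 0.01)
        assert n1.shape == (3, 5)
        # stronger competition on line 1 -> lower line-1 trajectory
        assert n1[0, -1] > n1[1, -1] > n1[2, -1]
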