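"""Mean-field rate equations: derivatives, fixed points, integration."""

import numpy as np
import pytest

from hetsnn.meanfield import (FixedPointError, MeanFieldState,
                              find_fixed_point, integrate_mf, mf_derivative,
                              single_population_graph, two_population_graph)


class TestDerivative:
    def test_quiescent_state_is_exact_fixed_point(self, rs):
        d = mf_derivative(MeanFieldState(0.0, rs.vr, 0.0, 0.0), rs, 0.5, 0.0)
        assert np.all(d == 0.0)

    def test_heterogeneity_term_vanishes_at_zero_width(self, rs):
        st = MeanFieldState(0.0, -50.0, 0.0, 0.0)
        d = mf_derivative(st, rs, 0.0, 0.0)
        assert d[0] == 0.0  # dr/dt has no source without disorder or rate

    def test_extra_conductance_currents_add_up(self, rs):
        st = MeanFieldState(0.02, -50.0, 1.0, 0.5)
        base = mf_derivative(st, rs, 0.5, 10.0)
        extra = mf_derivative(st, rs, 0.5, 10.0,
                              extra_currents=[(2.0, 0.3, -65.0)])
        # dv gains g*s*(E - v)/C; dr loses g*s*r/C
        assert extra[1] - base[1] == pytest.approx(2.0 * 0.3 * (-65.0 + 50.0) / rs.C)
        assert extra[0] - base[0] == pytest.approx(-2.0 * 0.3 * st.r / rs.C)

    def test_rate_equation_dimensional_scaling(self, rs):
        """Doubling C, k, b, g, kappa, J at fixed (r*C, ...) structure:
        the quiescent fixed point stays a fixed point."""
        from dataclasses import replace
        scaled = replace(rs, C=2 * rs.C, k=2 * rs.k, b=2 * rs.b, g=2 * rs.g,
                         kappa=2 * rs.kappa)
        d = mf_derivative(MeanFieldState(0.0, scaled.vr, 0.0, 0.0), scaled,
                          0.5, 0.0)
        assert np.all(d == 0.0)


class TestFixedPoints:
    def test_quiescent_root_found_exactly(self, rs):
        fp = find_fixed_point(rs, 0.5, 0.0, MeanFieldState(0.0, rs.vr, 0.0, 0.0))
        assert fp.state.v == pytest.approx(-60.0, abs=1e-9)
        assert fp.stable

    def test_r0_nullcline_roots_match_quadratic(self, rs):
        """With r = s = 0 and u = b(v - vr), stationarity of v solves
        0.7 (v+60)(v+40) + 2 (v+60) = 0: roots -60 and -40 - 2/0.7.
        The r = 0 plane is invariant only without disorder, so the high
        root is located at delta_v = 0."""
        expected = -40.0 - 2.0 / 0.7
        u_star = rs.b * (expected - rs.vr)
        d = mf_derivative(MeanFieldState(0.0, expected, u_star, 0.0), rs, 0.0, 0.0)
        assert abs(d[1]) < 1e-9
        fp_high = find_fixed_point(rs, 0.0, 0.0,
                                   MeanFieldState(0.0, -43.0, u_star, 0.0))
        assert fp_high.state.v == pytest.approx(expected, abs=1e-9)
        assert fp_high.state.r == pytest.approx(0.0, abs=1e-12)

    def test_active_fixed_point_is_stable_focus_or_node(self, rs):
        fp = find_fixed_point(rs, 0.5, 60.0,
                              MeanFieldState(0.03, -48.0, -13.0, 2.8))
        assert fp.state.r > 0.01
        assert fp.stable
        assert np.all(fp.eigenvalues.real < 0)

    def test_unreachable_guess_raises(self, rs):
        with pytest.raises(FixedPointError):
            find_fixed_point(rs, 0.5, 60.0,
                             MeanFieldState(5.0, 100.0, 1e4, 100.0),
                             max_iter=5)

    def test_fixed_point_is_stationary_under_integration(self, rs):
        fp = find_fixed_point(rs, 0.5, 60.0,
                              MeanFieldState(0.03, -48.0, -13.0, 2.8))
        traj = integrate_mf(single_population_graph(rs, 0.5), 60.0, 100.0,
                            init=[fp.state])
        drift = abs(traj[traj.population == 0]["r"].iloc[-1] - fp.state.r)
        assert drift < 1e-8


class TestIntegration:
    def test_quiescent_trajectory_constant(self, rs):
        traj = integrate_mf(single_population_graph(rs, 0.5), 0.0, 200.0)
        tr = traj[traj.population == 0]
        assert np.allclose(tr["r"], 0.0, atol=1e-14)
        assert np.allclose(tr["v"], rs.vr, atol=1e-12)

    def test_euler_step_refinement(self, rs):
        """r trajectory at dt=0.01 within 0.5% of dt=0.001 after 1 s."""
        g = single_population_graph(rs, 0.5)
        r_end = {}
        for dt in (0.01, 0.001):
            traj = integrate_mf(g, 60.0, 1000.0, dt=dt)
            r_end[dt] = traj[traj.population == 0]["r"].iloc[-1]
        assert r_end[0.01] == pytest.approx(r_end[0.001], rel=0.005)

    def test_zero_disorder_keeps_quiescence_invariant(self, rs):
        traj = integrate_mf(single_population_graph(rs, 0.0), 0.0, 200.0)
        assert np.allclose(traj[traj.population == 0]["r"], 0.0, atol=1e-14)

    def test_bistable_switching_persists_after_step(self, rs):
        """A 30->60->40 pA input excursion leaves the population on the
        high branch: inputs inside the bistable band retain state."""
        g = single_population_graph(rs, 0.5)
        n = int(3000.0 / 0.01)
        I = np.full((1, n), 30.0)
        I[0, int(1000 / 0.01):int(2000 / 0.01)] = 60.0
        I[0, int(2000 / 0.01):] = 40.0
        traj = integrate_mf(g, I, 3000.0)
        tr = traj[traj.population == 0]
        early = tr[tr.time_ms < 900]["r"].mean() * 1e3
        late = tr[tr.time_ms > 2800]["r"].mean() * 1e3
        assert early < 10.0 < late

    def test_two_population_gating_by_fs_heterogeneity(self, rs, fs):
        """Homogeneous FS inhibition entrains RS into oscillation;
        heterogeneous FS leaves RS stationary (same drive)."""
        spans = {}
        for dfs in (0.1, 2.0):
            g = two_population_graph(rs, 0.5, fs, dfs, 16.0, 16.0, 4.0, 4.0)
            traj = integrate_mf(g, np.array([60.0, 35.0]), 3000.0,
                                record_dt=1.0)
            r = traj[traj.population == 0]
            r = r[r.time_ms > 2000]["r"].to_numpy() * 1e3
            spans[dfs] = np.ptp(r)
        assert spans[0.1] > 10.0
        assert spans[2.0] < 1.0
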