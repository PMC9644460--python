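"""Stock-and-flow simulation: drivers, mortality identity, integrator accuracy."""

import numpy as np
import pytest

from distressdyn import (
    ModelParameters,
    background_mortality_rate,
    exogenous_drivers,
    simulate_trajectory,
)
from distressdyn.dynamics import distress_stock_at


def make_params(**overrides):
    base = dict(
        prev0=0.1464, P0=16_167_328.0, g=308_538.0, D0=136_840.0, h=2228.7,
        gamma=1.37, i0=0.06, delta_i=0.01, s=0.31, C0=305_315.0, u=43_696.0,
        r0=0.1845, delta_r=0.0,
        beta={"distress": 400.0, "population": 1e5, "mortality": 1e5,
              "services": 1e5},
    )
    base.update(overrides)
    return ModelParameters(**base)


class TestExogenousDrivers:
    def test_constant_case(self):
        p = make_params(g=0.0, h=0.0, u=0.0, delta_i=0.0, delta_r=0.0)
        for t in (0.0, 3.7, 12.0):
            P, D, C, i, r = exogenous_drivers(p, t)
            assert (P, D, C, i, r) == (p.P0, p.D0, p.C0, p.i0, p.r0)

    def test_linear_population(self):
        P, *_ = exogenous_drivers(make_params(), 1.0)
        assert P == pytest.approx(16_475_866.0)

    def test_exponential_incidence(self):
        p = make_params(i0=0.05, delta_i=0.02)
        _, _, _, i, _ = exogenous_drivers(p, 11.0)
        assert i == pytest.approx(0.05 * np.exp(0.22), rel=1e-12)
        assert i == pytest.approx(0.0623, abs=1e-4)

    def test_effectiveness_clipped_with_warning(self):
        p = make_params(r0=0.9, delta_r=0.2)
        with pytest.warns(UserWarning, match="clipped"):
            *_, r = exogenous_drivers(p, 5.0)
        assert r == 1.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            exogenous_drivers(make_params(), -0.1)

    def test_driver_leaving_physical_range_raises(self):
        p = make_params(g=-2e6)
        with pytest.raises(ValueError, match="P"):
            exogenous_drivers(p, 12.0)


class TestBackgroundMortality:
    def test_no_distressed_population(self):
        assert background_mortality_rate(1000.0, 0.0, 10.0, 1.37) == pytest.approx(0.01)

    def test_prior_mean_configuration(self):
        P = 16_167_328.0
        M = 0.1464 * P
        k = background_mortality_rate(P, M, 136_840.0, 1.37)
        assert k == pytest.approx(136_840.0 / 17_043_080.0, rel=1e-6)
        assert k == pytest.approx(0.0080291, rel=1e-4)
        # substituting back reproduces D exactly
        assert k * (P - M) + 1.37 * k * M == pytest.approx(136_840.0, rel=1e-12)

    def test_unit_hazard_ratio_removes_m_dependence(self):
        for M in (0.0, 100.0, 900.0):
            assert background_mortality_rate(1000.0, M, 10.0, 1.0) == pytest.approx(0.01)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            background_mortality_rate(1000.0, 1500.0, 10.0, 1.37)
        with pytest.raises(ValueError):
            background_mortality_rate(1000.0, 0.0, -1.0, 1.37)


class TestSimulateTrajectory:
    def test_empty_stock_fixed_point(self):
        p = make_params(prev0=0.0, i0=0.0, C0=0.0, u=0.0)
        traj = simulate_trajectory(p, 10.0)
        assert np.all(traj.M == 0.0)
        assert np.all(traj.prevalence == 0.0)

    def test_constant_coefficient_closed_form(self):
        # gamma = 1 and constant drivers make the ODE linear with constant
        # coefficients: dM/dt = i P - (i + k + s) M
        P, i, s, k = 1e6, 0.05, 0.31, 0.01
        p = make_params(prev0=0.2, P0=P, g=0.0, D0=k * P, h=0.0, gamma=1.0,
                        i0=i, delta_i=0.0, s=s, C0=0.0, u=0.0, r0=0.5,
                        delta_r=0.0)
        traj = simulate_trajectory(p, 30.0, dt_store=0.5)
        rate = i + k + s
        m_star = i * P / rate
        assert m_star == pytest.approx(135_135.135, rel=1e-6)
        expected = m_star + (p.M0 - m_star) * np.exp(-rate * traj.times)
        np.testing.assert_allclose(traj.M, expected, rtol=1e-6)
        assert traj.M[-1] == pytest.approx(m_star, rel=1e-4)

    def test_matches_fine_euler_oracle(self):
        p = make_params(delta_r=0.0)
        traj = simulate_trajectory(p, 12.0, dt_store=1.0)
        # independent brute-force Euler integration at dt = 1e-4 yr
        dt = 1e-4
        n = int(round(12.0 / dt))
        M = p.prev0 * p.P0
        stored = [M]
        next_store = 1.0
        for step in range(n):
            t = step * dt
            P = p.P0 + p.g * t
            D = p.D0 + p.h * t
            C = p.C0 + p.u * t
            i = p.i0 * np.exp(p.delta_i * t)
            r = min(p.r0 * np.exp(p.delta_r * t), 1.0)
            k = D / (P - M + p.gamma * M)
            M = M + dt * (i * (P - M) - p.gamma * k * M - p.s * M - r * C)
            if (step + 1) * dt >= next_store - 1e-12:
                stored.append(M)
                next_store += 1.0
        np.testing.assert_allclose(traj.M, np.array(stored), rtol=1e-4)

    def test_adaptive_and_fixed_step_agree(self):
        p = make_params()
        a = simulate_trajectory(p, 12.0, dt_store=1.0, method="adaptive")
        b = simulate_trajectory(p, 12.0, dt_store=1.0, method="rk4")
        np.testing.assert_allclose(a.M, b.M, rtol=1e-7)

    def test_step_halving_converged(self):
        p = make_params()
        t = np.array([12.0])
        m1, _ = distress_stock_at(p, t, dt=1 / 365)
        m2, _ = distress_stock_at(p, t, dt=1 / 730)
        assert abs(m2[0] / m1[0] - 1.0) < 1e-10

    def test_mortality_identity_on_grid(self):
        traj = simulate_trajectory(make_params(), 12.0)
        lhs = traj.k * (traj.P - traj.M) + 1.37 * traj.k * traj.M
        np.testing.assert_allclose(lhs, traj.D, rtol=1e-8)

    def test_bounds_and_prevalence_definition(self):
        traj = simulate_trajectory(make_params(), 12.0)
        assert np.all(traj.M >= 0.0)
        assert np.all(traj.M <= traj.P)
        np.testing.assert_array_equal(traj.prevalence, traj.M / traj.P)

    @pytest.mark.parametrize("name,direction", [("r0", -1.0), ("i0", 1.0)])
    def test_monotone_response(self, name, direction):
        # raising treatment effectiveness never increases the stock;
        # raising incidence never decreases it
        lo = simulate_trajectory(make_params(**{name: 0.05}), 12.0)
        hi = simulate_trajectory(make_params(**{name: 0.15}), 12.0)
        diff = direction * (hi.M[1:] - lo.M[1:])
        assert np.all(diff >= 0.0)

    def test_negative_stock_guard_flags(self):
        # overwhelming treatment flow relative to a tiny stock
        p = make_params(prev0=1e-6, P0=1e6, i0=1e-6, C0=8e5, u=0.0, r0=0.9)
        traj = simulate_trajectory(p, 5.0, method="rk4")
        assert traj.negative_stock_guard
        assert np.all(traj.M >= 0.0)

    def test_trajectory_csv_roundtrip(self, tmp_path):
        traj = simulate_trajectory(make_params(), 3.0)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert list(df.columns) == ["time", "M", "P", "D", "C", "i", "r", "k",
                                    "prevalence"]
        np.testing.assert_allclose(df["M"], traj.M)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            simulate_trajectory(make_params(), -1.0)
        with pytest.raises(ValueError):
            simulate_trajectory(make_params(), 5.0, dt_store=6.0)


class TestModelParameters:
    def test_vector_roundtrip(self):
        p = make_params()
        q = ModelParameters.from_vector(p.to_vector())
        assert q == p

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            make_params(prev0=1.5)
        with pytest.raises(ValueError):
            make_params(gamma=0.9)
        with pytest.raises(ValueError):
            make_params(s=-0.1)
        with pytest.raises(ValueError):
            make_params(beta={"distress": -1.0})

    def test_initial_stock(self):
        assert make_params().M0 == pytest.approx(0.1464 * 16_167_328.0)
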