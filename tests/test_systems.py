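"""ODE testbed tests: RK4 order, right-hand sides against symbolic
oracles, printed-parameter fidelity, and batch simulation semantics."""

import numpy as np
import pytest

from tippingrc.systems import (
    FoodChainParams,
    PowerSystemParams,
    food_chain,
    food_chain_rhs,
    power_system,
    power_system_rhs,
    rk4_step,
    simulate,
    simulate_batch,
)


def power_rhs_oracle(state, q1, p=None):
    """Independent scalar transcription of the power-system equations."""
    import math

    p = p or PowerSystemParams()
    dm, w, d, v = state
    root = math.sqrt(
        1 + p.c_cap**2 / p.y0**2 - 2 * p.c_cap / p.y0 * math.cos(p.theta0)
    )
    e0p, y0p = p.e0 / root, p.y0 * root
    P = -e0p * y0p * v * math.sin(d) + p.em * p.ym * v * math.sin(dm - d)
    Q = (
        e0p * y0p * v * math.cos(d)
        - (y0p + p.ym) * v**2
        + p.em * p.ym * v * math.cos(dm - d)
    )
    return [
        w,
        (-p.dm * w + p.pm - p.em * p.ym * math.sin(dm - d) * v) / p.m_inertia,
        (-p.k_qv2 * v**2 - p.k_qv * v + Q - p.q0 - q1) / p.k_qw,
        (
            p.k_pw * p.k_qv2 * v**2
            + (p.k_pw * p.k_qv - p.k_qw * p.k_pv) * v
            + p.k_qw * (P - p.p0 - p.p1)
            - p.k_pw * (Q - p.q0 - q1)
        )
        / (p.t_load * p.k_qw * p.k_pv),
    ]


def food_rhs_oracle(state, k_cap, p=None):
    p = p or FoodChainParams()
    r, c, pr = state
    return [
        r * (1 - r / k_cap) - p.x_c * p.y_c * c * r / (r + p.r0),
        p.x_c * c * (p.y_c * r / (r + p.r0) - 1) - p.x_p * p.y_p * pr * c / (c + p.c0),
        p.x_p * pr * (p.y_p * c / (c + p.c0) - 1),
    ]


class TestRK4:
    def test_zero_rhs_keeps_state(self):
        rhs = lambda s, th: np.zeros_like(s)
        s = np.array([1.0, -2.0])
        np.testing.assert_array_equal(rk4_step(rhs, s, 0.0, 0.1), s)

    def test_exponential_decay_polynomial(self):
        # one RK4 step of xdot=-x equals 1 - h + h^2/2 - h^3/6 + h^4/24
        rhs = lambda s, th: -s
        h = 0.1
        got = rk4_step(rhs, np.array([1.0]), 0.0, h)[0]
        expected = 1 - h + h**2 / 2 - h**3 / 6 + h**4 / 24
        np.testing.assert_allclose(got, expected, rtol=1e-15)
        np.testing.assert_allclose(got, 0.90483750, rtol=1e-8)

    def test_fourth_order_convergence(self):
        rhs = lambda s, th: -s
        errs = []
        for n in (10, 20, 40):
            h = 1.0 / n
            x = np.array([1.0])
            for _ in range(n):
                x = rk4_step(rhs, x, 0.0, h)
            errs.append(abs(x[0] - np.exp(-1.0)))
        # halving dt cuts global error ~16x
        assert 12 < errs[0] / errs[1] < 20
        assert 12 < errs[1] / errs[2] < 20


class TestPowerSystem:
    def test_first_component_is_omega(self, rng):
        s = rng.normal(size=(5, 4))
        d = power_system_rhs(s, 2.9)
        np.testing.assert_array_equal(d[:, 0], s[:, 1])

    def test_load_terms_vanish_at_zero_voltage(self, rng):
        s = rng.normal(size=4)
        s[3] = 0.0
        p = PowerSystemParams()
        d = power_system_rhs(s, 2.9)
        # with V=0, P=Q=0: remaining terms are independent of angles
        expected_ddelta = (0.0 - p.q0 - 2.9) / p.k_qw
        np.testing.assert_allclose(d[2], expected_ddelta, rtol=1e-12)

    def test_rhs_matches_symbolic_oracle(self):
        x0 = np.array([0.17, 0.05, 0.05, 0.83])
        got = power_system_rhs(x0, 2.98953)
        np.testing.assert_allclose(got, power_rhs_oracle(x0, 2.98953), rtol=1e-12)

    def test_derived_constants_recomputed(self):
        p = PowerSystemParams()
        ratio = p.c_cap / p.y0
        root = np.sqrt(1 + ratio**2 - 2 * ratio)
        # the radicand nearly cancels (C/Y0 ~ 1.05), so allow for round-off
        np.testing.assert_allclose(p.e0_eff, p.e0 / root, rtol=1e-9)
        np.testing.assert_allclose(p.y0_eff, p.y0 * root, rtol=1e-9)
        # effective source angle is pi here because C/Y0 > 1
        np.testing.assert_allclose(p.theta0_eff, np.pi, rtol=1e-14)

    def test_printed_defaults(self):
        p = PowerSystemParams()
        assert (p.k_pw, p.k_pv, p.k_qw, p.k_qv, p.k_qv2) == (0.4, 0.3, -0.03, -2.8, 2.1)
        assert (p.t_load, p.p0, p.p1, p.y0, p.ym) == (8.5, 0.6, 0.0, 3.33, 5.0)
        assert (p.pm, p.dm, p.theta0, p.em) == (1.0, 0.05, 0.0, 1.05)
        assert (p.m_inertia, p.c_cap, p.e0, p.q0) == (0.01464, 3.5, 1.0, 1.3)

    def test_q0_override(self):
        assert PowerSystemParams(q0=0.3).q0 == 0.3

    def test_spec_defaults(self):
        spec = power_system()
        np.testing.assert_array_equal(spec.x0, [0.17, 0.05, 0.05, 0.83])
        assert spec.dt == 0.05 and spec.n_steps == 10000


class TestFoodChain:
    def test_extinct_predator_stays_extinct(self, rng):
        s = np.abs(rng.normal(size=3))
        s[2] = 0.0
        assert food_chain_rhs(s, 0.95)[2] == 0.0

    def test_zero_resource_stays_zero(self, rng):
        s = np.abs(rng.normal(size=3))
        s[0] = 0.0
        assert food_chain_rhs(s, 0.95)[0] == 0.0

    def test_rhs_matches_symbolic_oracle(self):
        x0 = np.array([0.6, 0.35, 0.9])
        np.testing.assert_allclose(
            food_chain_rhs(x0, 0.95), food_rhs_oracle(x0, 0.95), rtol=1e-12
        )

    def test_printed_defaults(self):
        p = FoodChainParams()
        assert (p.x_c, p.y_c, p.x_p, p.y_p, p.r0, p.c0) == (
            0.4, 2.009, 0.08, 2.876, 0.16129, 0.5,
        )
        spec = food_chain()
        np.testing.assert_array_equal(spec.x0, [0.6, 0.35, 0.9])
        assert spec.dt == 0.1 and spec.n_steps == 25000

    def test_nonpositive_params_rejected(self):
        with pytest.raises(ValueError):
            FoodChainParams(r0=-1.0)


class TestSimulate:
    def test_zero_steps_returns_x0(self):
        spec = food_chain()
        traj, collapsed = simulate(spec, 0.95, n_steps=0)
        assert len(traj) == 1 and not collapsed
        np.testing.assert_array_equal(traj.states[0], spec.x0)

    def test_training_parameter_bounded(self):
        # shortened run: well inside the oscillatory regime
        traj, collapsed = simulate(food_chain(), 0.92, n_steps=5000)
        assert not collapsed
        assert np.isfinite(traj.states).all()
        assert traj.states.max() < 2.0

    def test_power_past_collapse_flagged(self):
        _, collapsed = simulate(power_system(), 2.9899, n_steps=10000)
        assert collapsed

    def test_bit_reproducible(self):
        a, _ = simulate(food_chain(), 0.93, n_steps=500)
        b, _ = simulate(food_chain(), 0.93, n_steps=500)
        assert np.array_equal(a.states, b.states)

    def test_batch_matches_scalar(self):
        spec = food_chain()
        batch = simulate_batch(spec, np.array([0.92, 0.95]), n_steps=300)
        for i, th in enumerate([0.92, 0.95]):
            traj, _ = simulate(spec, th, n_steps=300)
            np.testing.assert_allclose(batch.states[i], traj.states, rtol=1e-12)

    def test_collapsed_rows_are_nan_after_stop(self):
        spec = power_system()
        batch = simulate_batch(spec, np.array([2.9899]), n_steps=10000)
        assert batch.collapsed[0]
        stop = batch.stop_index[0]
        assert np.isfinite(batch.states[0, : stop + 1]).all()
        assert np.isnan(batch.states[0, stop + 1 :]).all()
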