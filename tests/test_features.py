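"""Feature-pipeline unit and property tests.

The brute-force oracle enumerates monomials as deduplicated sorted
exponent tuples, independently of the library's combinatorics.
"""

from itertools import product
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tippingrc.features import (
    FeatureConfig,
    InsufficientHistoryError,
    Trajectory,
    build_manifest,
    delay_embed,
    feature_dimension,
    feature_matrix,
    feature_vector,
    get_plan,
    poly_features,
    postprocess,
)


def brute_force_monomials(values, orders):
    """All unique monomials as {sorted index tuple: product}, per order."""
    out = []
    for o in orders:
        seen = set()
        for combo in product(range(len(values)), repeat=o):
            key = tuple(sorted(combo))
            if key not in seen:
                seen.add(key)
                out.append(np.prod([values[i] for i in key]))
    return out


class TestDelayEmbed:
    def test_paper_layout_d2_k2_s1(self):
        traj = Trajectory(np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]), dt=1.0)
        v = delay_embed(traj, k=2, s=1, i=2)
        # current point first, then the point s steps back
        np.testing.assert_array_equal(v, [5.0, 6.0, 3.0, 4.0])

    def test_k1_returns_point_itself(self, random_traj):
        v = delay_embed(random_traj, k=1, s=5, i=10)
        np.testing.assert_array_equal(v, random_traj.states[10])

    def test_scalar_ramp(self):
        traj = Trajectory(np.arange(20.0), dt=1.0)
        v = delay_embed(traj, k=3, s=2, i=10)
        np.testing.assert_array_equal(v, [10.0, 8.0, 6.0])

    def test_below_warmup_raises_with_delta_t(self, random_traj):
        with pytest.raises(InsufficientHistoryError, match="6"):
            delay_embed(random_traj, k=3, s=2, i=5)


class TestPolyFeatures:
    def test_order_1_2_pair(self):
        got = poly_features(np.array([2.0, 3.0]), [1, 2])
        # unique monomials of orders 1 and 2 of (a, b)
        assert sorted(got) == sorted([2.0, 3.0, 4.0, 9.0, 6.0])
        assert len(got) == 5

    def test_order1_is_identity(self, rng):
        v = rng.normal(size=7)
        np.testing.assert_array_equal(poly_features(v, [1]), v)

    def test_matches_brute_force_enumeration(self, rng):
        v = rng.normal(size=2)
        got = poly_features(v, [1, 2, 3])
        expected = brute_force_monomials(v, [1, 2, 3])
        assert len(got) == 9
        np.testing.assert_allclose(np.sort(got), np.sort(expected), rtol=1e-12)

    def test_empty_orders_rejected(self):
        with pytest.raises(ValueError):
            poly_features(np.array([1.0]), [])


class TestFeatureDimension:
    def test_power_architecture_493(self):
        cfg = FeatureConfig(2, 2, (1, 2, 3), (0, 1, 2, 3))
        assert feature_dimension(4, cfg) == (164, 493)

    def test_foodchain_architecture_271(self):
        cfg = FeatureConfig(4, 4, (1, 2), (0, 1, 2, 3))
        assert feature_dimension(3, cfg) == (90, 271)

    def test_2n_plus_1_layout(self):
        cfg = FeatureConfig(2, 1, (1, 2), (0, 1, 2))
        n, n_tilde = feature_dimension(2, cfg)
        assert n == 14
        assert n_tilde == 2 * n + 1

    @pytest.mark.parametrize("d,k", [(1, 1), (1, 3), (2, 2), (3, 2), (2, 3)])
    @pytest.mark.parametrize("orders", [(1,), (1, 2), (2, 4), (1, 2, 3, 4)])
    def test_dimension_law_against_brute_force(self, d, k, orders, rng):
        cfg = FeatureConfig(k, 1, orders, (0, 1, 3))
        D = d * k
        v = rng.normal(size=D)
        n_brute = len(brute_force_monomials(v, orders))
        n, n_tilde = feature_dimension(d, cfg)
        assert n == n_brute
        assert n == sum(comb(D + o - 1, o) for o in orders)
        assert n_tilde == 2 * n + 1
        manifest = build_manifest(d, cfg)
        assert len(manifest) == n_tilde


class TestPostprocess:
    def test_powers_and_bias(self):
        got = postprocess(np.array([2.0, 3.0]), [0, 1, 2, 3])
        np.testing.assert_array_equal(got, [1.0, 2.0, 3.0, 4.0, 9.0, 8.0, 27.0])

    def test_identity_for_order_1(self, rng):
        r = rng.normal(size=9)
        np.testing.assert_array_equal(postprocess(r, [1]), r)

    def test_output_dimension_2n_plus_1(self, rng):
        r = rng.normal(size=11)
        assert postprocess(r, [0, 1, 2]).shape == (23,)


class TestFeatureVector:
    def test_gamma_zero_matches_parameter_free(self, rng):
        cfg = FeatureConfig(2, 1, (1, 2), (0, 1, 2), gamma=0.0)
        hist = rng.normal(size=(5, 2))
        np.testing.assert_array_equal(
            feature_vector(hist, cfg, theta=7.3), feature_vector(hist, cfg, theta=0.0)
        )

    def test_shift_before_powers_bias_unshifted(self):
        # scalar monomial 2 with shift 0.5: q_[0,1,2] -> (1, 2.5, 6.25)
        cfg = FeatureConfig(1, 1, (1,), (0, 1, 2), gamma=0.5)
        hist = np.array([[0.0], [2.0]])
        np.testing.assert_allclose(
            feature_vector(hist, cfg, theta=1.0), [1.0, 2.5, 6.25]
        )

    def test_matches_direct_evaluation(self, rng):
        # independent scalar-path oracle: q(P(L(x)) + gamma*theta)
        cfg = FeatureConfig(2, 1, (1, 2), (0, 1, 2, 3), gamma=0.4)
        theta = 0.92
        hist = rng.normal(size=(4, 2))
        stacked = np.concatenate([hist[-1], hist[-2]])
        plan = get_plan(2, cfg)
        mono = np.array(
            [np.prod(stacked[list(m)]) for m in plan.manifest.monomials]
        )
        shifted = mono + cfg.gamma * theta
        expected = np.concatenate([[1.0], shifted, shifted**2, shifted**3])
        np.testing.assert_allclose(feature_vector(hist, cfg, theta), expected, rtol=1e-12)

    @given(
        gamma=st.floats(0.1, 10.0),
        scale=st.sampled_from([0.25, 0.5, 2.0, 4.0, 8.0]),
    )
    @settings(max_examples=25, deadline=None)
    def test_gamma_theta_product_invariance(self, gamma, scale):
        # power-of-two rescaling keeps the product gamma*theta bit-exact
        cfg1 = FeatureConfig(1, 1, (1, 2), (0, 1, 2), gamma=gamma)
        cfg2 = FeatureConfig(1, 1, (1, 2), (0, 1, 2), gamma=gamma * scale)
        hist = np.array([[0.3], [0.7]])
        theta = 1.7
        np.testing.assert_array_equal(
            feature_vector(hist, cfg1, theta), feature_vector(hist, cfg2, theta / scale)
        )

    def test_nonfinite_theta_rejected(self, rng):
        cfg = FeatureConfig(1, 1, (1,), (1,))
        with pytest.raises(ValueError):
            feature_vector(rng.normal(size=(2, 1)), cfg, theta=np.nan)


class TestFeatureMatrix:
    def test_column_count(self, rng):
        cfg = FeatureConfig(2, 2, (1,), (1,))
        m = 9
        traj = Trajectory(rng.normal(size=(cfg.delta_t + 1 + m, 2)), dt=0.1)
        assert feature_matrix(traj, cfg).shape[1] == m

    def test_constant_trajectory_constant_columns(self):
        cfg = FeatureConfig(2, 1, (1, 2), (0, 1, 2))
        traj = Trajectory(np.tile([1.5, -0.5], (10, 1)), dt=0.1)
        R = feature_matrix(traj, cfg, theta=0.3)
        assert np.all(R == R[:, :1])

    def test_columns_match_scalar_path(self, rng):
        # column-by-column reconstruction via feature_vector
        cfg = FeatureConfig(4, 4, (1, 2), (0, 1, 2, 3), gamma=0.4)
        traj = Trajectory(rng.normal(size=(40, 3)), dt=0.1)
        R = feature_matrix(traj, cfg, theta=0.93)
        for j in range(R.shape[1]):
            i = cfg.delta_t + j
            col = feature_vector(traj.states[: i + 1], cfg, theta=0.93)
            np.testing.assert_array_equal(R[:, j], col)

    def test_too_short_raises(self, rng):
        cfg = FeatureConfig(2, 2, (1,), (1,))
        with pytest.raises(ValueError, match="6"):
            feature_matrix(Trajectory(rng.normal(size=(5, 2)), dt=0.1), cfg)

    def test_bit_identical_determinism(self, rng):
        cfg = FeatureConfig(2, 1, (1, 2, 3), (0, 1, 2), gamma=0.7)
        traj = Trajectory(rng.normal(size=(30, 2)), dt=0.1)
        a = feature_matrix(traj, cfg, theta=1.23)
        b = feature_matrix(traj, cfg, theta=1.23)
        assert np.array_equal(a, b)


class TestManifest:
    def test_roundtrip(self):
        cfg = FeatureConfig(2, 2, (1, 2), (0, 1, 2))
        m = build_manifest(3, cfg)
        from tippingrc.features import FeatureOrderingManifest

        assert FeatureOrderingManifest.from_dict(m.to_dict()) == m

    def test_duplicate_monomials_kept(self):
        # squares of order-1 monomials duplicate order-2 entries; both stay
        cfg = FeatureConfig(1, 1, (1, 2), (1, 2))
        n, n_tilde = feature_dimension(2, cfg)
        assert n == 5 and n_tilde == 10


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(k=0, s=1, poly_orders=(1,), post_orders=(1,)),
            dict(k=1, s=0, poly_orders=(1,), post_orders=(1,)),
            dict(k=1, s=1, poly_orders=(), post_orders=(1,)),
            dict(k=1, s=1, poly_orders=(2, 1), post_orders=(1,)),
            dict(k=1, s=1, poly_orders=(0, 1), post_orders=(1,)),
            dict(k=1, s=1, poly_orders=(1,), post_orders=(2, 1)),
            dict(k=1, s=1, poly_orders=(1,), post_orders=(1,), beta=-1.0),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            FeatureConfig(**kwargs)

    def test_delta_t(self):
        assert FeatureConfig(4, 4, (1,), (1,)).delta_t == 16
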