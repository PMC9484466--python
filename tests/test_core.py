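"""Delta-gamma moments, sampling, closed-form MLEs, and the cube-root maps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from deltagamma import (
    DeltaGammaParams,
    GammaParams,
    ZeroInflatedSample,
    cube_root_moments,
    dg_mean,
    dg_sample,
    dg_variance,
    gamma_mean_from_moments,
    gamma_variance_from_moments,
    mle_fit,
    scale_from_moments,
    shape_from_moments,
)
from deltagamma.errors import DegenerateSampleError, InsufficientPositivesError


def dg(delta, shape, scale):
    return DeltaGammaParams(delta, GammaParams(shape, scale))


class TestMoments:
    @pytest.mark.parametrize(
        "delta, shape, scale, mean",
        [(0.2, 7, 1, 5.6), (0.0, 3, 2, 6.0), (0.5, 2, 1, 1.0)],
    )
    def test_mean(self, delta, shape, scale, mean):
        assert dg_mean(dg(delta, shape, scale)) == pytest.approx(mean)

    @pytest.mark.parametrize(
        "delta, shape, scale, var",
        [(0.5, 2, 1, 2.0), (0.0, 3, 2, 12.0), (0.8, 1.25, 1, 0.5)],
    )
    def test_variance(self, delta, shape, scale, var):
        assert dg_variance(dg(delta, shape, scale)) == pytest.approx(var)

    def test_zero_inflation_vanishes_at_delta_zero(self):
        g = GammaParams(3.7, 0.4)
        p = DeltaGammaParams(0.0, g)
        assert dg_mean(p) == g.mean
        assert dg_variance(p) == g.variance

    def test_rainfall_summary_plugin(self):
        # shape 0.7297 with gamma mean 18.6461 and zero probability 0.5517
        g = GammaParams(0.7297, 18.6461 / 0.7297)
        p = DeltaGammaParams(0.5517, g)
        assert dg_mean(p) == pytest.approx(8.359, abs=5e-3)
        assert dg_variance(p) == pytest.approx(299.5542, abs=0.5)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            GammaParams(-1, 1)
        with pytest.raises(ValueError):
            GammaParams(1, 0)
        with pytest.raises(ValueError):
            DeltaGammaParams(1.0, GammaParams(1, 1))


class TestSampling:
    def test_no_zeros_when_delta_zero(self):
        s = dg_sample(dg(0.0, 2, 1), 100, seed=1)
        assert s.n0 == 0 and s.n == 100

    def test_zero_fraction_law_of_large_numbers(self):
        s = dg_sample(dg(0.5, 2, 1), 10**5, seed=2)
        assert abs(s.n0 / s.n - 0.5) < 0.01

    def test_same_seed_same_sample(self):
        a = dg_sample(dg(0.3, 2, 1), 50, seed=42)
        b = dg_sample(dg(0.3, 2, 1), 50, seed=42)
        np.testing.assert_array_equal(a.values, b.values)

    def test_sample_moments_match_model(self):
        p = dg(0.5, 2.0, 1.0)
        n = 10**6
        x = dg_sample(p, n, seed=3).values
        se_mean = x.std() / np.sqrt(n)
        assert abs(x.mean() - p.mean) < 3 * se_mean
        dev = (x - x.mean()) ** 2
        se_var = dev.std() / np.sqrt(n)
        assert abs(x.var() - p.variance) < 3 * se_var


class TestSampleContainer:
    def test_counts_partition(self):
        s = ZeroInflatedSample([0.0, 1.5, 0.0, 2.5, 3.0])
        assert (s.n, s.n0, s.n1) == (5, 2, 3)
        assert np.all(s.positives > 0)

    def test_rejects_negatives(self):
        with pytest.raises(ValueError):
            ZeroInflatedSample([1.0, -0.1])

    def test_cube_root_summary_needs_two_positives(self):
        with pytest.raises(InsufficientPositivesError):
            ZeroInflatedSample([0.0, 0.0, 4.0]).cube_root_summary()


class TestMleFit:
    def test_hand_worked_two_point_sample(self):
        # positives {1, e^2}: mean log = 1, so alpha = 0.5/(log xbar - 1)
        s = ZeroInflatedSample([1.0, np.exp(2.0)])
        est = mle_fit(s)
        assert est.delta_hat == 0.0
        assert est.alpha_hat == pytest.approx(1.15266, abs=1e-4)
        assert est.rate_hat == pytest.approx(0.27480, abs=1e-4)

    def test_delta_hat_is_exact_zero_fraction(self, synthetic_rainfall):
        est = mle_fit(synthetic_rainfall)
        assert est.delta_hat == synthetic_rainfall.n0 / synthetic_rainfall.n

    def test_gamma_mean_identity(self, synthetic_rainfall):
        # alpha/rate equals the positive-part sample mean by construction
        est = mle_fit(synthetic_rainfall)
        assert est.gamma_mean_hat == pytest.approx(
            synthetic_rainfall.positives.mean()
        )

    def test_all_equal_positives_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            mle_fit(ZeroInflatedSample([5.0, 5.0, 5.0, 0.0]))

    def test_insufficient_positives(self):
        with pytest.raises(InsufficientPositivesError):
            mle_fit(ZeroInflatedSample([0.0, 0.0, 4.0]))

    def test_consistency_on_simulated_data(self):
        p = dg(0.5, 2.0, 1.0)
        s = dg_sample(p, 10**5, seed=11)
        est = mle_fit(s)
        assert est.delta_hat == pytest.approx(0.5, rel=0.02)
        assert est.gamma_mean_hat == pytest.approx(2.0, rel=0.02)
        assert est.tau_hat == pytest.approx(2.0, rel=0.05)


class TestCubeRootMaps:
    def test_unit_gamma_moments(self):
        mu, s2 = cube_root_moments(GammaParams(1, 1))
        assert mu == pytest.approx(8 / 9)
        assert s2 == pytest.approx(1 / 9)

    def test_shape_nine_moments(self):
        mu, s2 = cube_root_moments(GammaParams(9, 1))
        assert mu == pytest.approx(2.05441, abs=1e-5)
        assert s2 == pytest.approx(0.0534166, abs=1e-6)

    def test_inverse_maps_at_unit_point(self):
        assert shape_from_moments(8 / 9, 1 / 9) == pytest.approx(1.0)
        assert scale_from_moments(1.0, 1 / 9) == pytest.approx(1.0)
        assert gamma_mean_from_moments(8 / 9, 1 / 9) == pytest.approx(1.0)
        assert gamma_variance_from_moments(8 / 9, 1 / 9) == pytest.approx(1.0)

    def test_shape_exceeds_one_ninth(self, rng):
        mus = rng.uniform(0.05, 5.0, 200)
        s2s = rng.uniform(1e-3, 2.0, 200)
        assert np.all(shape_from_moments(mus, s2s) > 1 / 9)

    def test_scale_power_law_in_sigma(self):
        assert scale_from_moments(4.0, 0.4) == pytest.approx(
            8 * scale_from_moments(4.0, 0.1)
        )

    def test_domain_errors(self):
        for f in (shape_from_moments, gamma_mean_from_moments,
                  gamma_variance_from_moments):
            with pytest.raises(ValueError):
                f(1.0, 0.0)
        with pytest.raises(ValueError):
            scale_from_moments(1.0, -1.0)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        a=st.floats(0.2, 50.0),
        b=st.floats(0.05, 20.0),
    )
    def test_round_trip_recovers_parameters(self, a, b):
        mu, s2 = cube_root_moments(GammaParams(a, b))
        assert shape_from_moments(mu, s2) == pytest.approx(a, rel=1e-8)
        assert scale_from_moments(a, s2) == pytest.approx(b, rel=1e-8)
        assert gamma_mean_from_moments(mu, s2) == pytest.approx(a * b, rel=1e-8)
        assert gamma_variance_from_moments(mu, s2) == pytest.approx(
            a * b * b, rel=1e-8
        )
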