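import numpy as np
import pytest

from tempsf.errors import (
    DegenerateSignalError,
    InsufficientDataError,
    ParameterError,
    ScaleRangeError,
    ValidationError,
)
from tempsf.sfcore import (
    OrderRange,
    ScaleRange,
    fit_scaling_exponent,
    normalize_sf,
    structure_function,
    structure_function_multi,
)
from tempsf.toysignals import gen_random_normal, gen_sinusoid


def sf_reference(values, taus, q):
    """Independent double-loop oracle for S_q(tau)."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    out = []
    for tau in taus:
        acc = 0.0
        for i in range(n - tau):
            acc += abs(values[i] - values[i + tau]) ** q
        out.append(acc / (n - tau))
    return np.array(out)


class TestStructureFunction:
    @pytest.mark.parametrize("q, expected", [
        (1, [5 / 3, 1.0, 3.0]),
        (2, [3.0, 1.0, 9.0]),
    ])
    def test_four_point_hand_example(self, q, expected):
        sf = structure_function([1, 3, 2, 4], ScaleRange(1, 3), order=q)
        np.testing.assert_allclose(sf.values, expected)

    def test_constant_series_is_identically_zero(self):
        sf = structure_function([5, 5, 5, 5], ScaleRange(1, 3))
        np.testing.assert_array_equal(sf.values, 0.0)

    def test_linear_ramp_gives_s_equal_tau(self):
        sf = structure_function(np.arange(100, dtype=float), ScaleRange(1, 30))
        np.testing.assert_allclose(sf.values, sf.taus)

    def test_number_of_differences_is_n_minus_tau(self):
        n = 50
        sf = structure_function(np.random.default_rng(0).normal(size=n),
                                ScaleRange(1, 20))
        np.testing.assert_array_equal(sf.n_diffs, n - sf.taus)

    def test_scale_range_must_fit_series(self):
        with pytest.raises(ScaleRangeError):
            structure_function([1.0, 2.0, 3.0], ScaleRange(1, 3))

    def test_empty_or_tiny_series_rejected(self):
        with pytest.raises(InsufficientDataError):
            structure_function([], ScaleRange(1, 1))

    def test_order_must_be_positive(self):
        with pytest.raises(ParameterError):
            structure_function([1.0, 2.0, 3.0], ScaleRange(1, 1), order=0)

    def test_matches_double_loop_oracle(self):
        """Production vectorized SF equals the brute-force definition."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = int(rng.integers(10, 200))
            values = rng.normal(size=n) * rng.uniform(0.1, 10)
            tau_max = int(rng.integers(3, n - 1))
            q = float(rng.choice([0.5, 1.0, 2.0, 3.0]))
            sf = structure_function(values, ScaleRange(1, tau_max), order=q)
            ref = sf_reference(values, sf.taus, q)
            np.testing.assert_allclose(sf.values, ref, rtol=1e-12)

    def test_iid_normal_closed_form(self):
        """For i.i.d. N(mu, sigma), E S_1(tau) = 2 sigma / sqrt(pi) at every tau."""
        sd = 0.1
        series = gen_random_normal(10_000, mean=1.0, sd=sd, seed=11)
        sf = structure_function(series, ScaleRange(1, 1000))
        expected = 2 * sd / np.sqrt(np.pi)
        se = np.sqrt(2 * sd ** 2 * (1 - 2 / np.pi)) / np.sqrt(sf.n_diffs)
        assert np.all(np.abs(sf.values - expected) < 4 * se)

    def test_sinusoid_closed_form(self):
        """S_1(tau) of sin(2 pi f t / samp) tends to (4/pi)|sin(pi f tau / samp)|."""
        series = gen_sinusoid(100_000, freq=1.0, samp=100.0)
        sf = structure_function(series, ScaleRange(1, 300))
        expected = (4 / np.pi) * np.abs(np.sin(np.pi * sf.taus / 100.0))
        assert np.max(np.abs(sf.values - expected)) < 0.02 * (4 / np.pi)

    @pytest.mark.parametrize("q", [0.5, 1.0, 2.0])
    def test_homogeneity_and_shift_invariance(self, q):
        """Scaling by c multiplies S_q by c^q; adding a constant changes nothing."""
        rng = np.random.default_rng(5)
        values = rng.normal(size=300)
        scales = ScaleRange(1, 40)
        base = structure_function(values, scales, order=q)
        c = 3.7
        scaled = structure_function(c * values, scales, order=q)
        shifted = structure_function(values + 11.3, scales, order=q)
        np.testing.assert_allclose(scaled.values, c ** q * base.values, rtol=1e-12)
        np.testing.assert_allclose(shifted.values, base.values, rtol=1e-9)
        # normalized SF is invariant under the affine map combined
        both = structure_function(c * values + 11.3, scales, order=q)
        np.testing.assert_allclose(normalize_sf(both).values,
                                   normalize_sf(base).values, rtol=1e-9)


class TestStructureFunctionMulti:
    def test_singleton_orders_match_single_call(self):
        values = np.random.default_rng(1).normal(size=60)
        single = structure_function(values, ScaleRange(1, 10))
        multi = structure_function_multi(values, ScaleRange(1, 10),
                                         OrderRange(1.0, 1.0))
        assert len(multi) == 1
        np.testing.assert_array_equal(multi[0].values, single.values)

    def test_four_point_example_both_orders(self):
        sfs = structure_function_multi([1, 3, 2, 4], ScaleRange(1, 3),
                                       OrderRange(1.0, 2.0, 1.0))
        np.testing.assert_allclose(sfs[0].values, [5 / 3, 1.0, 3.0])
        np.testing.assert_allclose(sfs[1].values, [3.0, 1.0, 9.0])

    def test_ramp_scaling_exponents_are_q(self):
        """A linear ramp has S_q(tau) = tau^q, so zeta(q) = q exactly."""
        ramp = np.arange(500, dtype=float)
        for q, sf in zip([1.0, 2.0],
                         structure_function_multi(ramp, ScaleRange(1, 50),
                                                  OrderRange(1.0, 2.0, 1.0))):
            fit = fit_scaling_exponent(sf)
            assert fit.zeta == pytest.approx(q, abs=1e-10)
            assert fit.r_squared == pytest.approx(1.0)


class TestNormalize:
    def test_divides_by_initial_value(self, make_sf):
        sf = make_sf([2.0, 4.0, 6.0], normalized=False)
        out = normalize_sf(sf)
        np.testing.assert_allclose(out.values, [1.0, 2.0, 3.0])
        assert out.normalized

    def test_normalized_starts_at_exactly_one(self):
        series = gen_random_normal(500, seed=3)
        sf = normalize_sf(structure_function(series, ScaleRange(1, 40)))
        assert sf.values[0] == 1.0

    def test_double_normalization_is_an_error(self, make_sf):
        with pytest.raises(ValidationError):
            normalize_sf(make_sf([1.0, 2.0], normalized=True))

    def test_constant_series_cannot_be_normalized(self, make_sf):
        with pytest.raises(DegenerateSignalError):
            normalize_sf(make_sf([0.0, 0.0], normalized=False))


class TestFitScalingExponent:
    def test_exact_power_law(self, make_sf):
        taus = np.arange(1, 101)
        fit = fit_scaling_exponent(make_sf(taus.astype(float)))
        assert fit.zeta == pytest.approx(1.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_flat_function_has_zero_slope(self, make_sf):
        fit = fit_scaling_exponent(make_sf(np.full(50, 2.5)))
        assert fit.zeta == pytest.approx(0.0, abs=1e-12)

    def test_zero_values_raise_unless_dropped(self, make_sf):
        sf = make_sf(np.array([0.0, 1.0, 2.0, 3.0, 4.0]), normalized=False)
        with pytest.raises(DegenerateSignalError):
            fit_scaling_exponent(sf)
        fit = fit_scaling_exponent(sf, drop_zeros=True)
        assert np.isfinite(fit.zeta)

    def test_too_few_points_rejected(self, make_sf):
        with pytest.raises(InsufficientDataError):
            fit_scaling_exponent(make_sf([1.0, 2.0]))

    def test_linear_space_option(self, make_sf):
        taus = np.arange(1, 51).astype(float)
        fit = fit_scaling_exponent(make_sf(3.0 * taus + 1), space="linear")
        assert fit.zeta == pytest.approx(3.0)
        assert fit.space == "linear"

    def test_subrange_restriction(self, make_sf):
        # slope 1 below tau=50, flat above: fitting each side recovers each slope
        taus = np.arange(1, 101)
        values = np.minimum(taus, 50).astype(float)
        sf = make_sf(values)
        low = fit_scaling_exponent(sf, fit_range=ScaleRange(1, 50))
        high = fit_scaling_exponent(sf, fit_range=ScaleRange(51, 100))
        assert low.zeta == pytest.approx(1.0, abs=1e-12)
        assert high.zeta == pytest.approx(0.0, abs=1e-12)


class TestScaleAndOrderRanges:
    def test_scale_range_validation(self):
        with pytest.raises(ParameterError):
            ScaleRange(0, 5)
        with pytest.raises(ParameterError):
            ScaleRange(6, 5)

    def test_order_range_grid(self):
        np.testing.assert_allclose(OrderRange(1.0, 3.0, 0.5).orders(),
                                   [1.0, 1.5, 2.0, 2.5, 3.0])
        with pytest.raises(ParameterError):
            OrderRange(0.0, 1.0)
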