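"""Single-cosinor fitting, normalization, and group acrophase summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circakit import (
    Cosinor,
    CosinorFit,
    cosinor_fit,
    group_acrophase,
    percent_of_mean,
)
from circakit.errors import InvalidArgumentError, SingularFitError

from _oracles import circular_mean_oracle, cosinor_acrophase_grid_oracle

ZT_SAMPLES = np.array([9.0, 13.0, 17.0, 21.0, 1.0, 5.0])  # 17:00 start, 4-h steps


def cosine(t, mesor, amp, acro, period=24.0):
    return mesor + amp * np.cos(2 * np.pi * (np.asarray(t) - acro) / period)


class TestNormalization:
    def test_mean_already_100_left_unchanged(self):
        x = [50, 80, 120, 150, 100, 100]
        out = percent_of_mean(x)
        assert np.allclose(out, x)
        assert out.mean() == pytest.approx(100.0)

    def test_constant_rates_all_100(self):
        assert np.allclose(percent_of_mean([7.0] * 6), 100.0)

    def test_linear_ramp_values(self):
        out = percent_of_mean([2, 4, 6, 8, 10, 12])
        want = 100 * np.array([2, 4, 6, 8, 10, 12]) / 7.0
        assert np.allclose(out, want)

    def test_nonpositive_rejected(self):
        with pytest.raises(InvalidArgumentError):
            percent_of_mean([1.0, 0.0, 2.0])

    @settings(deadline=None, max_examples=200)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1e6), min_size=2,
                    max_size=24))
    def test_mean_is_always_100(self, values):
        assert percent_of_mean(values).mean() == pytest.approx(100.0, abs=1e-9)


class TestCosinorFit:
    def test_exact_recovery_of_known_cosine(self):
        y = cosine(ZT_SAMPLES, 100, 20, 18.8)
        fit = cosinor_fit(ZT_SAMPLES, y)
        assert fit.mesor == pytest.approx(100.0, abs=1e-8)
        assert fit.amplitude == pytest.approx(20.0, abs=1e-8)
        assert fit.acrophase_zt == pytest.approx(18.8, abs=1e-6)
        assert fit.p_zero_amplitude < 1e-6

    def test_constant_series_is_arrhythmic(self):
        fit = cosinor_fit(ZT_SAMPLES, np.full(6, 42.0))
        assert fit.amplitude == pytest.approx(0.0, abs=1e-9)
        assert fit.p_zero_amplitude == pytest.approx(1.0)

    def test_acrophase_matches_grid_search_oracle(self):
        rng = np.random.default_rng(11)
        y = cosine(ZT_SAMPLES, 100, 15, 3.0) + rng.normal(0, 2, 6)
        fit = cosinor_fit(ZT_SAMPLES, y)
        oracle = cosinor_acrophase_grid_oracle(ZT_SAMPLES, y)
        assert fit.acrophase_zt == pytest.approx(oracle, abs=0.002)

    def test_time_shift_equivariance(self):
        y = cosine(ZT_SAMPLES, 100, 20, 6.0)
        base = cosinor_fit(ZT_SAMPLES, y)
        shifted = cosinor_fit(ZT_SAMPLES + 5.0, y)
        assert shifted.acrophase_zt == pytest.approx((base.acrophase_zt + 5) % 24,
                                                     abs=1e-6)
        assert shifted.amplitude == pytest.approx(base.amplitude, abs=1e-8)

    def test_value_scaling(self):
        y = cosine(ZT_SAMPLES, 100, 20, 18.0)
        a, b = cosinor_fit(ZT_SAMPLES, y), cosinor_fit(ZT_SAMPLES, 3.5 * y)
        assert b.mesor == pytest.approx(3.5 * a.mesor)
        assert b.amplitude == pytest.approx(3.5 * a.amplitude)
        assert b.acrophase_zt == pytest.approx(a.acrophase_zt, abs=1e-9)
        assert b.p_zero_amplitude == pytest.approx(a.p_zero_amplitude, abs=1e-9)

    def test_normalized_input_gives_mesor_100(self):
        y = percent_of_mean(cosine(ZT_SAMPLES, 5e5, 1e5, 19.0))
        fit = cosinor_fit(ZT_SAMPLES, y)
        assert fit.mesor == pytest.approx(100.0, abs=1e-6)

    def test_rank_deficient_design_rejected(self):
        with pytest.raises((SingularFitError, InvalidArgumentError)):
            cosinor_fit([0.0, 12.0, 0.0, 12.0], [1, 2, 3, 4])

    def test_too_few_distinct_times_rejected(self):
        with pytest.raises(InvalidArgumentError):
            cosinor_fit([0, 8, 16], [1, 2, 3])

    def test_estimator_api(self):
        est = Cosinor(period=24.0)
        y = cosine(ZT_SAMPLES, 100, 20, 18.8)
        est.fit(ZT_SAMPLES, y)
        assert est.get_params() == {"period": 24.0}
        assert np.allclose(est.predict(ZT_SAMPLES), y, atol=1e-8)

    def test_parameter_recovery_sparse_noisy_design(self):
        # six-point design, A/M = 0.2, 5% multiplicative noise
        rng = np.random.default_rng(2024)
        errs = []
        for _ in range(500):
            acro = rng.uniform(0, 24)
            y = cosine(ZT_SAMPLES, 100, 20, acro) * rng.lognormal(
                0, 0.05, 6
            )
            fit = cosinor_fit(ZT_SAMPLES, y)
            d = (fit.acrophase_zt - acro + 12) % 24 - 12
            errs.append(abs(d))
        assert np.median(errs) < 0.5


class TestGroupAcrophase:
    def _fit(self, acro, p=0.01):
        return CosinorFit(period=24, mesor=100, amplitude=20,
                          acrophase_zt=acro, p_zero_amplitude=p,
                          residual_ss=0.0)

    def test_identical_acrophases(self):
        ga = group_acrophase([self._fit(18.8)] * 3)
        assert ga.mean_zt == pytest.approx(18.8)
        assert ga.sem == pytest.approx(0.0)

    def test_wraps_midnight(self):
        # mean of ZT23.5 and ZT0.5 is ZT0 (circular), not ZT12
        ga = group_acrophase([self._fit(23.5), self._fit(0.5)])
        dist_to_zero = min(ga.mean_zt, 24.0 - ga.mean_zt)
        assert dist_to_zero == pytest.approx(0.0, abs=1e-9)

    def test_matches_circular_mean_oracle(self):
        rng = np.random.default_rng(3)
        acros = rng.uniform(0, 24, 8)
        ga = group_acrophase([self._fit(a) for a in acros])
        assert ga.mean_zt == pytest.approx(circular_mean_oracle(acros), abs=1e-9)

    def test_arrhythmic_fits_flagged_and_excludable(self):
        fits = [self._fit(18.0), self._fit(18.4), self._fit(6.0, p=0.9)]
        ga = group_acrophase(fits)
        assert ga.n_arrhythmic == 1 and ga.n_used == 3
        ga_ex = group_acrophase(fits, include_arrhythmic=False)
        assert ga_ex.n_used == 2
        assert ga_ex.mean_zt == pytest.approx(18.2, abs=1e-9)

    def test_single_fit_rejected(self):
        with pytest.raises(InvalidArgumentError):
            group_acrophase([self._fit(18.0)])
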