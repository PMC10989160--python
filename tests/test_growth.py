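"""Interval growth rates, the top-five statistic, and the zero-growth gate."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from monodplate.exceptions import InsufficientDataError, SingularFitError
from monodplate.growth import (
    classify_growth,
    estimate_growth,
    min_growth_concentration,
    pointwise_rates,
    top_k_rate,
)
from monodplate.plate import WellSeries


def _series(times, f, **kw):
    base = dict(well_id="w", strain="S", state="axenic", nutrient="P",
                concentration=9.6, replicate=1, is_control=False)
    base.update(kw)
    return WellSeries(times=np.asarray(times, float),
                      fluorescence=np.asarray(f, float), **base)


class TestPointwiseRates:
    def test_doubling_in_one_day_gives_ln2(self):
        rs = pointwise_rates(_series([0.0, 1.0], [100.0, 200.0]))
        assert rs.rates[0] == pytest.approx(np.log(2.0), abs=1e-12)
        assert rs.interval_midpoints[0] == 0.5

    def test_constant_signal_gives_zero_rates(self):
        rs = pointwise_rates(_series([0, 1, 2], [50.0, 50.0, 50.0]))
        np.testing.assert_allclose(rs.rates, [0.0, 0.0])

    def test_declining_signal_gives_negative_rate(self):
        rs = pointwise_rates(_series([0.0, 0.5], [100.0, 90.0]))
        assert rs.rates[0] == pytest.approx(np.log(0.9) / 0.5, rel=1e-12)
        assert rs.rates[0] == pytest.approx(-0.2107, abs=5e-5)

    def test_noiseless_exponential_rates_all_equal_mu(self):
        t = np.arange(10.0)
        mu = 0.37
        rs = pointwise_rates(_series(t, 20.0 * np.exp(mu * t)))
        np.testing.assert_allclose(rs.rates, mu, rtol=1e-12)


class TestTopKRate:
    def test_mean_of_five_largest(self):
        mu, se, k_used = top_k_rate(np.array([0.1, 0.5, 0.4, 0.3, 0.2, 0.05]))
        assert mu == pytest.approx(np.mean([0.5, 0.4, 0.3, 0.2, 0.1]))
        assert k_used == 5

    def test_zero_variance_gives_zero_se(self):
        mu, se, k_used = top_k_rate(np.full(7, 0.2))
        assert (mu, se) == (pytest.approx(0.2), 0.0)

    def test_fewer_than_k_uses_all(self):
        mu, se, k_used = top_k_rate(np.array([0.1, 0.2, 0.3]), k=5)
        assert k_used == 3
        assert mu == pytest.approx(0.2)

    def test_se_is_sd_over_sqrt_k(self):
        vals = np.array([0.5, 0.4, 0.3, 0.2, 0.1, -1.0])
        _, se, _ = top_k_rate(vals)
        top = vals[:5]
        assert se == pytest.approx(np.std(top, ddof=1) / np.sqrt(5))

    def test_empty_raises(self):
        with pytest.raises(InsufficientDataError):
            top_k_rate(np.array([]))

    @given(st.lists(st.floats(-2, 2), min_size=1, max_size=40))
    @settings(max_examples=60, deadline=None)
    def test_permutation_invariant_and_monotone(self, rates):
        rates = np.asarray(rates)
        mu, _, k = top_k_rate(rates)
        mu_perm, _, _ = top_k_rate(rates[::-1].copy())
        assert mu == pytest.approx(mu_perm, abs=1e-12)
        # appending a rate above the current max cannot decrease the estimate
        mu_plus, _, _ = top_k_rate(np.append(rates, rates.max() + 1.0))
        assert mu_plus >= mu - 1e-12


class TestClassifyGrowth:
    def _flat_controls(self, rng, n=3, sigma=0.01, days=10):
        t = np.arange(float(days))
        return [
            _series(t, 100.0 * np.exp(rng.normal(0, sigma, days)),
                    well_id=f"c{i}", is_control=True, strain="media",
                    state="control", concentration=0.0, replicate=i + 1)
            for i in range(n)
        ]

    def test_identical_sides_give_p_one_flag_false(self):
        wells = [_series(np.arange(5.0), [10, 20, 40, 80, 160])]
        res = classify_growth(wells, wells)
        assert res.p_slope == pytest.approx(1.0)
        assert not res.growth_flag
        assert res.t_stat == pytest.approx(0.0)

    def test_exponential_vs_flat_control_flags_growth(self, rng):
        t = np.arange(10.0)
        treat = [_series(t, 10.0 * np.exp(0.5 * t), well_id=f"t{i}",
                         replicate=i + 1) for i in range(3)]
        res = classify_growth(treat, self._flat_controls(rng))
        assert res.growth_flag
        assert res.p_slope < 1e-6

    def test_declining_treatment_never_flags_growth(self, rng):
        t = np.arange(10.0)
        treat = [_series(t, 100.0 * np.exp(-0.2 * t), well_id=f"t{i}",
                         replicate=i + 1) for i in range(3)]
        res = classify_growth(treat, self._flat_controls(rng))
        assert res.p_slope < 0.01  # clearly different slope...
        assert res.slope_treatment < res.slope_control
        assert not res.growth_flag  # ...but in the wrong direction

    def test_p_value_matches_statsmodels_interaction(self, rng):
        """Pooled-error slope-difference t-test == OLS interaction term."""
        import statsmodels.api as sm

        t = np.arange(8.0)
        treat = [_series(t, 10.0 * np.exp(0.3 * t + rng.normal(0, 0.05, 8)),
                         well_id=f"t{i}", replicate=i + 1) for i in range(2)]
        ctrl = self._flat_controls(rng, n=2, sigma=0.05, days=8)
        res = classify_growth(treat, ctrl)

        tt = np.concatenate([w.times for w in treat + ctrl])
        yy = np.log(np.concatenate([w.fluorescence for w in treat + ctrl]))
        side = np.concatenate([np.ones(16), np.zeros(16)])
        X = sm.add_constant(np.column_stack([tt, side, tt * side]))
        fit = sm.OLS(yy, X).fit()
        assert res.p_slope == pytest.approx(fit.pvalues[3], abs=1e-8)
        assert res.t_stat == pytest.approx(fit.tvalues[3], rel=1e-8)

    def test_degenerate_times_raise(self):
        w = [_series([0.0, 0.0 + 1e-9], [10.0, 10.0])]
        bad = [_series([1.0, 1.0 + 1e-12], [5.0, 5.0], well_id="b")]
        # collapse controls onto a single effective time point
        with pytest.raises((SingularFitError, InsufficientDataError)):
            classify_growth(w, [_series([2.0, 2.0000000001], [5.0, 5.0001],
                                        well_id="c")])


class TestEstimateGrowth:
    def test_table_shape_and_gate_broadcast(self, p_plate):
        out = estimate_growth(p_plate)
        # 9 P levels x 3 replicates
        assert len(out) == 27
        assert set(out.columns) >= {"strain", "state", "nutrient",
                                    "concentration", "replicate", "mu_hat",
                                    "se", "k_used", "p_slope", "growth_flag"}
        # gate verdict identical within a treatment
        assert (out.groupby("concentration")["p_slope"].nunique() == 1).all()

    def test_per_treatment_aggregation_pools_replicates(self, p_plate):
        out = estimate_growth(p_plate, aggregate="per_treatment")
        assert len(out) == 9
        assert (out["replicate"] == 0).all()


class TestMinGrowthConcentration:
    def _frame(self, flags):
        import pandas as pd

        return pd.DataFrame(
            [dict(strain="S", state="axenic", nutrient="N", concentration=c,
                  replicate=1, growth_flag=f) for c, f in flags.items()]
        )

    def test_threshold_matches_observed_n_limitation(self):
        est = self._frame({8.0: False, 40.5: False, 87.0: True, 425.0: True})
        assert min_growth_concentration(est) == 87.0

    def test_no_growth_anywhere_returns_none(self):
        assert min_growth_concentration(
            self._frame({8.0: False, 40.5: False})) is None

    def test_growth_everywhere_returns_gradient_minimum(self):
        est = self._frame({8.0: True, 40.5: True, 87.0: True})
        assert min_growth_concentration(est) == 8.0
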