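"""Monod fitting, derived competition traits, and FDR contrasts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from monodplate.exceptions import (
    DomainError,
    InsufficientDataError,
    UndefinedRStarError,
)
from monodplate.kinetics import (
    MOLAR_MASS,
    contrast_parameters,
    fit_monod,
    initial_slope,
    monod_mu,
    r_star,
    summary_table,
)
from monodplate.simulate import P_GRADIENT

S_GRID = np.repeat(np.array(P_GRADIENT), 3)  # triplicate at each P level


class TestMonodMu:
    def test_half_saturation_definition(self):
        assert monod_mu(3.58, 0.55, 3.58) == pytest.approx(0.55 / 2)

    def test_zero_substrate_zero_growth(self):
        assert monod_mu(0.0, 0.55, 3.58) == 0.0

    def test_published_parameter_evaluation(self):
        # mu at the top of the P gradient for mu_max=0.55, K_s=3.58
        assert monod_mu(3030.0, 0.55, 3.58) == pytest.approx(0.5494, abs=5e-5)

    def test_negative_substrate_rejected(self):
        with pytest.raises(DomainError):
            monod_mu(-1.0, 0.5, 1.0)

    @given(st.floats(0.01, 1e5), st.floats(0.05, 2.0), st.floats(0.01, 1e4))
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_bounded(self, s, mu_max, k_s):
        v = monod_mu(s, mu_max, k_s)
        assert 0 < v < mu_max
        assert monod_mu(s * 1.5, mu_max, k_s) > v


class TestFitMonod:
    def test_exact_recovery_on_noiseless_data(self):
        mu = monod_mu(S_GRID, 0.55, 3.58)
        fit = fit_monod(S_GRID, mu)
        assert fit.converged
        assert fit.mu_max == pytest.approx(0.55, rel=1e-6)
        assert fit.k_s == pytest.approx(3.58, rel=1e-6)
        assert fit.rss == pytest.approx(0.0, abs=1e-16)

    def test_covariance_symmetric_psd(self):
        rng = np.random.default_rng(0)
        mu = monod_mu(S_GRID, 0.55, 3.58) + rng.normal(0, 0.02, S_GRID.size)
        fit = fit_monod(S_GRID, mu)
        cov = fit.covariance
        np.testing.assert_allclose(cov, cov.T)
        assert np.all(np.linalg.eigvalsh(cov) >= -1e-15)
        assert fit.mu_max_se > 0 and fit.k_s_se > 0

    def test_flat_response_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            fit = fit_monod([1.0, 10.0, 100.0], [0.3, 0.3, 0.3])
        assert "flat_response" in fit.flags

    def test_too_few_points_raise(self):
        with pytest.raises(InsufficientDataError):
            fit_monod([1.0, 10.0], [0.1, 0.2])
        with pytest.raises(InsufficientDataError):
            fit_monod([1.0, 1.0, 1.0], [0.1, 0.2, 0.3])

    def test_monte_carlo_recovery_and_coverage(self):
        """Gaussian rate noise sigma=0.02: parameter recovery and CI
        calibration of the nonlinear fit itself (no growth-curve stage)."""
        rng = np.random.default_rng(42)
        true_mu, true_ks = 0.55, 3.58
        clean = monod_mu(S_GRID, true_mu, true_ks)
        mus, kss, cover = [], [], 0
        n_sims = 500
        for _ in range(n_sims):
            fit = fit_monod(S_GRID, clean + rng.normal(0, 0.02, S_GRID.size))
            mus.append(fit.mu_max)
            kss.append(fit.k_s)
            cover += abs(fit.mu_max - true_mu) <= 1.96 * fit.mu_max_se
        assert np.mean(mus) == pytest.approx(true_mu, rel=0.05)
        assert np.mean(kss) == pytest.approx(true_ks, rel=0.25)
        assert 0.90 <= cover / n_sims <= 0.99


class TestInitialSlope:
    def test_published_p_row(self):
        assert initial_slope(0.48, 0.92, MOLAR_MASS["P"]) == pytest.approx(
            16.16, abs=0.005)

    def test_unit_identity(self):
        # K_s numerically equal to the molar mass is exactly 1 uM
        assert initial_slope(1.0, 30.974, 30.974) == pytest.approx(1.0)

    def test_published_n_row(self):
        assert initial_slope(0.60, 290.57, MOLAR_MASS["N"]) == pytest.approx(
            0.029, abs=5e-4)

    def test_equals_derivative_at_zero_substrate(self):
        mu_max, k_s, mm = 0.51, 4.2, MOLAR_MASS["P"]
        h = 1e-7
        numeric = monod_mu(h, mu_max, k_s) / h * mm  # per uM
        assert initial_slope(mu_max, k_s, mm) == pytest.approx(numeric, rel=1e-6)

    def test_nonpositive_molar_mass_rejected(self):
        with pytest.raises(DomainError):
            initial_slope(0.5, 1.0, 0.0)


class TestRStar:
    def test_published_p_row(self):
        assert r_star(0.55, 3.58, 0.2) == pytest.approx(2.0457, abs=5e-4)

    def test_published_n_row(self):
        assert r_star(0.54, 371.77, 0.2) == pytest.approx(218.7, abs=0.05)

    def test_vanishes_as_dilution_goes_to_zero(self):
        assert r_star(0.55, 3.58, 1e-9) < 1e-8

    def test_washout_raises(self):
        with pytest.raises(UndefinedRStarError):
            r_star(0.15, 3.58, 0.2)

    @given(st.floats(0.25, 1.5), st.floats(0.1, 500.0), st.floats(0.01, 0.2))
    @settings(max_examples=100, deadline=None)
    def test_closed_form_solves_monod_equation(self, mu_max, k_s, D):
        s = r_star(mu_max, k_s, D)
        assert monod_mu(s, mu_max, k_s) == pytest.approx(D, rel=1e-10)


def _fit_stub(strain, state, nutrient, mu, mu_se, ks, ks_se, n=27):
    from monodplate.kinetics import MonodFit

    return MonodFit(strain=strain, state=state, nutrient=nutrient,
                    mu_max=mu, mu_max_se=mu_se, k_s=ks, k_s_se=ks_se,
                    covariance=np.diag([mu_se**2, ks_se**2]), rss=0.0,
                    n_points=n, converged=True)


class TestContrasts:
    def test_identical_groups_give_p_one(self):
        fits = [_fit_stub("A", "axenic", "P", 0.5, 0.01, 3.0, 0.5),
                _fit_stub("B", "axenic", "P", 0.5, 0.01, 3.0, 0.5)]
        out = contrast_parameters(fits)
        assert (out["estimate_diff"] == 0).all()
        assert (out["p"] == 1.0).all()
        assert (out["p_adjusted"] == 1.0).all()

    def test_t_and_df_conventions(self):
        fits = [_fit_stub("A", "axenic", "P", 0.55, 0.01, 3.58, 0.75, n=27),
                _fit_stub("A", "xenic", "P", 0.49, 0.01, 1.72, 0.42, n=27)]
        out = contrast_parameters(fits)
        row = out[out.parameter == "mu_max"].iloc[0]
        assert row["se_diff"] == pytest.approx(np.hypot(0.01, 0.01))
        assert row["t"] == pytest.approx(0.06 / np.hypot(0.01, 0.01), rel=1e-6)
        assert row["df"] == 27 + 27 - 4

    def test_zero_se_nonzero_diff_warns_p_zero(self):
        fits = [_fit_stub("A", "axenic", "P", 0.5, 0.0, 3.0, 0.0),
                _fit_stub("B", "axenic", "P", 0.6, 0.0, 4.0, 0.0)]
        with pytest.warns(UserWarning, match="infinite"):
            out = contrast_parameters(fits)
        assert (out["p"] == 0.0).all()

    def test_bh_fixed_point_and_stepup_example(self):
        from statsmodels.stats.multitest import multipletests

        # all p equal to alpha stay at alpha
        adj = multipletests(np.full(6, 0.05), method="fdr_bh")[1]
        np.testing.assert_allclose(adj, 0.05)
        # classic step-up example
        adj = multipletests(np.array([0.01, 0.02, 0.03, 0.04]),
                            method="fdr_bh")[1]
        np.testing.assert_allclose(adj, 0.04)

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    @settings(max_examples=60, deadline=None)
    def test_bh_never_decreases_and_preserves_order(self, ps):
        from statsmodels.stats.multitest import multipletests

        ps = np.asarray(ps)
        adj = multipletests(ps, method="fdr_bh")[1]
        assert np.all(adj >= ps - 1e-15)
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_families_are_per_parameter_and_nutrient(self):
        fits = [_fit_stub("A", "axenic", "P", 0.5, 0.01, 3.0, 0.5),
                _fit_stub("B", "axenic", "P", 0.6, 0.01, 4.0, 0.5),
                _fit_stub("A", "axenic", "N", 0.5, 0.02, 300.0, 50.0),
                _fit_stub("B", "axenic", "N", 0.55, 0.02, 200.0, 50.0)]
        out = contrast_parameters(fits)
        assert set(out["family"]) == {"mu_max:P", "k_s:P", "mu_max:N", "k_s:N"}


class TestSummaryTable:
    def test_r_star_nan_when_washout(self):
        fits = [_fit_stub("A", "axenic", "P", 0.15, 0.01, 3.0, 0.5)]
        out = summary_table(fits, dilution_rate=0.2)
        assert np.isnan(out["r_star"].iloc[0])

    def test_one_row_per_group_with_derived_traits(self):
        fits = [_fit_stub("A", "axenic", "P", 0.55, 0.01, 3.58, 0.75),
                _fit_stub("A", "xenic", "P", 0.49, 0.01, 1.72, 0.42)]
        out = summary_table(fits)
        assert len(out) == 2
        assert out["initial_slope"].iloc[0] == pytest.approx(
            0.55 / (3.58 / MOLAR_MASS["P"]))
        assert out["r_star"].iloc[0] == pytest.approx(2.0457, abs=5e-4)
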