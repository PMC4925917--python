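import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import optimize
from scipy.special import expit, logit

from rxits.its import (
    EffectEstimate,
    SegmentedBinomialITS,
    SeparationError,
    negative_control,
)
from rxits.series import MonthlySeries
from rxits.simulate import SeriesSimConfig, generate_series, seasonal_harmonic


def _sim(seed=0, **kw):
    kw.setdefault("denominators", 20_000)
    return generate_series(SeriesSimConfig(seed=seed, **kw))


# ----------------------------------------------------------------------
# design construction
# ----------------------------------------------------------------------


def test_step_only_design_has_fifteen_columns():
    m = SegmentedBinomialITS(_sim(), 33, 38, "step_only")
    assert m.design.shape == (51, 15)
    assert list(m.design.columns[:2]) == ["intercept", "t"]
    assert "step" in m.design.columns and "during" in m.design.columns


def test_model_form_switches_post_terms():
    trend = SegmentedBinomialITS(_sim(), 33, 38, "trend_only")
    assert "post_slope" in trend.design.columns and "step" not in trend.design.columns
    both = SegmentedBinomialITS(_sim(), 33, 38, "step_plus_trend")
    assert {"step", "post_slope"} <= set(both.design.columns)


def test_post_split_indicators_cover_six_then_rest():
    m = SegmentedBinomialITS(_sim(), 33, 38, "post_split_6m")
    X = m.design
    assert X["step_first6m"].to_numpy().nonzero()[0].tolist() == list(range(39, 45))
    assert X["step_after6m"].to_numpy().nonzero()[0].tolist() == list(range(45, 51))


def test_exposure_at_series_edge_rejected():
    with pytest.raises(ValueError, match="post-exposure"):
        SegmentedBinomialITS(_sim(), 45, 50, "step_only")


def test_separation_raises_named_segment():
    s = MonthlySeries.from_arrays([0] * 33 + [3] * 18, [10] * 51)
    with pytest.raises(SeparationError, match="before"):
        SegmentedBinomialITS(s, 33, 38, "step_only")


# ----------------------------------------------------------------------
# likelihood oracle
# ----------------------------------------------------------------------


def _brute_force_mle(num, den, X):
    """Maximise the binomial log-likelihood directly (independent of IRLS)."""

    def nll(beta):
        eta = X @ beta
        return -(num * eta - den * np.logaddexp(0, eta)).sum()

    res = optimize.minimize(nll, np.zeros(X.shape[1]), method="BFGS",
                            options={"gtol": 1e-12, "maxiter": 500})
    # polish with Newton steps
    beta = res.x
    for _ in range(50):
        p = expit(X @ beta)
        grad = X.T @ (num - den * p)
        H = -(X * (den * p * (1 - p))[:, None]).T @ X
        step = np.linalg.solve(H, grad)
        beta = beta - step
        if np.abs(step).max() < 1e-12:
            break
    return beta


def test_stage_one_matches_brute_force_likelihood_maximisation():
    """IRLS coefficients equal direct likelihood maximisation to 1e-6 on a
    short series."""
    rng = np.random.default_rng(12)
    den = np.full(12, 40)
    num = rng.binomial(den, expit(-1 + 0.05 * np.arange(12)))
    num = np.clip(num, 1, den - 1)
    s = MonthlySeries.from_arrays(num, den)
    m = SegmentedBinomialITS(s, 8, 9, "step_only", seasonal=False)
    fit = m.fit(lagged_residual=False)
    X = m.design.to_numpy()
    beta_bf = _brute_force_mle(num.astype(float), den.astype(float), X)
    assert np.abs(fit.params.to_numpy() - beta_bf).max() < 1e-6


def test_fixed_tiny_series_intercept_trend_oracle():
    """6 months, denominators 10, numerators alternating 1,2: the
    intercept+trend fit matches brute-force maximisation."""
    num = np.array([1, 2, 1, 2, 1, 2], dtype=float)
    den = np.full(6, 10.0)
    X = np.column_stack([np.ones(6), np.arange(6.0)])
    beta_bf = _brute_force_mle(num, den, X)
    res = sm.GLM(np.column_stack([num, den - num]), X,
                 family=sm.families.Binomial()).fit(tol=1e-10)
    assert np.abs(res.params - beta_bf).max() < 1e-6


def test_binomial_sufficiency_under_row_splitting():
    """Splitting each month's counts into two half-rows with the same
    covariates leaves the coefficients unchanged."""
    s = _sim(seed=3, step_log_or=0.1)
    m = SegmentedBinomialITS(s, 33, 38, "step_only")
    fit = m.fit(lagged_residual=False)
    num = s.data["numerator"].to_numpy()
    den = s.data["denominator"].to_numpy()
    X = m.design.to_numpy()
    num_split = np.concatenate([num // 2, num - num // 2]).astype(float)
    den_split = np.concatenate([den // 2, den - den // 2]).astype(float)
    X_split = np.vstack([X, X])
    res = sm.GLM(
        np.column_stack([num_split, den_split - num_split]),
        X_split,
        family=sm.families.Binomial(),
    ).fit(tol=1e-10)
    assert np.abs(res.params - fit.params.to_numpy()).max() < 1e-8


# ----------------------------------------------------------------------
# inference
# ----------------------------------------------------------------------


def test_null_series_recovers_zero_step_and_unit_dispersion():
    fits = [
        SegmentedBinomialITS(_sim(seed=i), 33, 38).fit() for i in range(30)
    ]
    z = np.array([f.params["step"] / f.bse["step"] for f in fits])
    assert abs(z.mean()) < 3 / np.sqrt(len(z))
    phi = np.array([f.dispersion for f in fits])
    assert 0.8 < phi.mean() < 1.2


def test_dispersion_scaling_changes_se_not_estimates():
    fit = SegmentedBinomialITS(_sim(seed=4, dispersion=4.0), 33, 38).fit()
    assert np.allclose(fit.cov_params.to_numpy(),
                       fit.cov_unscaled.to_numpy() * fit.dispersion)
    assert np.allclose(fit.bse.to_numpy(),
                       fit.bse_unscaled.to_numpy() * np.sqrt(fit.dispersion))


def test_injected_dispersion_recovered_and_doubles_se():
    phis, ratios = [], []
    for i in range(40):
        fit = SegmentedBinomialITS(_sim(seed=100 + i, dispersion=4.0), 33, 38).fit()
        phis.append(fit.dispersion)
        ratios.append(fit.bse["step"] / fit.bse_unscaled["step"])
    assert abs(np.mean(phis) - 4.0) < 0.5
    assert abs(np.mean(ratios) - 2.0) < 0.15


def test_step_or_wald_interval_closed_form():
    est = EffectEstimate("step_or", 1.0, np.exp(-1.96 * 0.1), np.exp(1.96 * 0.1), 1.0)
    assert est.ci_low == pytest.approx(0.822, abs=1e-3)
    assert est.ci_high == pytest.approx(1.216, abs=1e-3)
    fit = SegmentedBinomialITS(_sim(seed=5, step_log_or=np.log(1.11)), 33, 38).fit()
    e = fit.step_odds_ratio()
    assert e.odds_ratio == pytest.approx(np.exp(fit.params["step"]))
    assert e.ci_low < e.odds_ratio < e.ci_high


def test_trend_change_reported_per_month():
    fit = SegmentedBinomialITS(
        _sim(seed=6, trend_change_per_month=np.log(0.98)), 33, 38, "trend_only"
    ).fit()
    e = fit.trend_change_test()
    assert e.name == "post_slope_or_per_month"
    assert e.odds_ratio == pytest.approx(np.exp(fit.params["post_slope"]))
    with pytest.raises(ValueError, match="post_slope"):
        SegmentedBinomialITS(_sim(seed=6), 33, 38, "step_only").fit().trend_change_test()


def test_trend_change_power_exceeds_null_rate():
    reject_null, reject_alt = 0, 0
    for i in range(60):
        f0 = SegmentedBinomialITS(_sim(seed=300 + i), 33, 38, "trend_only").fit()
        f1 = SegmentedBinomialITS(
            _sim(seed=300 + i, trend_change_per_month=np.log(1.02)), 33, 38, "trend_only"
        ).fit()
        reject_null += f0.trend_change_test().p_value < 0.05
        reject_alt += f1.trend_change_test().p_value < 0.05
    assert reject_alt > reject_null


# ----------------------------------------------------------------------
# curves and counterfactual
# ----------------------------------------------------------------------


def test_constant_series_fits_flat_pooled_proportion():
    s = MonthlySeries.from_arrays([20] * 51, [100] * 51)
    fit = SegmentedBinomialITS(s, 33, 38).fit(lagged_residual=False)
    curve = fit.predict_curve()
    assert np.allclose(curve["fitted"], 0.2, atol=1e-6)


def test_confidence_band_matches_hand_linear_algebra():
    s = _sim(seed=7, step_log_or=0.2)
    fit = SegmentedBinomialITS(s, 33, 38).fit()
    curve = fit.predict_curve()
    beta = fit.params.drop("lag_resid")
    X = fit.model.design[beta.index].to_numpy()
    eta = X @ beta.to_numpy()
    C = fit.cov_params.loc[beta.index, beta.index].to_numpy()
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, C, X))
    assert np.allclose(curve["lower"], expit(eta - 1.959963984540054 * se))
    assert np.allclose(curve["upper"], expit(eta + 1.959963984540054 * se))
    assert ((curve["fitted"] > 0) & (curve["fitted"] < 1)).all()


def test_counterfactual_equals_fitted_before_exposure():
    fit = SegmentedBinomialITS(_sim(seed=8, step_log_or=0.3), 33, 38).fit()
    curve = fit.predict_curve()
    pre = curve["segment"] == "before"
    assert np.array_equal(curve.loc[pre, "fitted"], curve.loc[pre, "counterfactual"])


def test_injected_step_lifts_fitted_above_counterfactual_post_exposure():
    gaps = []
    for i in range(20):
        fit = SegmentedBinomialITS(_sim(seed=400 + i, step_log_or=np.log(1.2)), 33, 38).fit()
        curve = fit.predict_curve()
        post = curve["segment"] == "after"
        gaps.append((curve.loc[post, "fitted"] - curve.loc[post, "counterfactual"]).to_numpy())
    assert (np.mean(gaps, axis=0) > 0).all()


def test_drop_during_removes_exposure_months_from_likelihood():
    m = SegmentedBinomialITS(_sim(seed=9), 33, 38, drop_during=True)
    assert len(m.design) == 45
    assert "during" not in m.design.columns
    fit = m.fit()
    assert len(fit.predict_curve()) == 45


# ----------------------------------------------------------------------
# negative controls
# ----------------------------------------------------------------------


def test_negative_controls_are_null_when_no_effect_exists():
    alt = _sim(seed=10)
    outcome = _sim(seed=11)
    a, b = negative_control(alt, outcome, 33, 38)
    for e in (a, b):
        assert e.ci_low < 1.0 < e.ci_high


def test_shifted_window_attenuates_a_real_step():
    """A true step at the real window is estimated at full size there but
    is attenuated when the analysis window is shifted 12 months earlier
    (the misplaced step indicator then also covers unaffected months)."""
    hits_true, log_true, log_shift = 0, [], []
    for i in range(20):
        s = _sim(seed=500 + i, step_log_or=np.log(1.3))
        true_fit = SegmentedBinomialITS(s, 33, 38).fit()
        _, shifted = negative_control(s, s, 33, 38)
        hits_true += true_fit.step_odds_ratio().p_value < 0.05
        log_true.append(true_fit.step_odds_ratio().log_odds)
        log_shift.append(shifted.log_odds)
    assert hits_true > 15
    assert np.mean(log_true) == pytest.approx(np.log(1.3), abs=0.05)
    assert np.mean(log_shift) < 0.7 * np.mean(log_true)


def test_warns_when_shifted_window_overlaps_true_window():
    s = _sim(seed=12)
    with pytest.warns(UserWarning, match="overlaps"):
        negative_control(s, s, 33, 38, window_shift_months=-3)
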