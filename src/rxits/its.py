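"""Segmented binomial regression for interrupted time series.

The model is a binomial-logit GLM on monthly (numerator, denominator)
pairs.  Time is divided into three segments — before, during and after an
exposure window — and the linear predictor carries

* an intercept and a linear month-on-month trend,
* eleven calendar-month indicators (January is the reference) for
  seasonality,
* a level indicator for the exposure months themselves,
* post-exposure terms depending on the model form: a step indicator
  (``step_only``), a post-exposure slope term (``trend_only``), both
  (``step_plus_trend``), or two step indicators splitting the
  post-exposure period at six months (``post_split_6m``).

Fitting is two-stage: an ordinary IRLS fit, then a refit with the lag-1
Pearson residuals of the first stage appended as a covariate to absorb
first-order autocorrelation.  Standard errors are scaled by the Pearson
dispersion (chi-square over residual degrees of freedom) of the final
fit, so confidence intervals and Wald tests are quasi-binomial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from .series import MonthlySeries

__all__ = [
    "MODEL_FORMS",
    "EffectEstimate",
    "SegmentedBinomialITS",
    "SegmentedITSResults",
    "SeparationError",
    "negative_control",
]

MODEL_FORMS = ("step_only", "trend_only", "step_plus_trend", "post_split_6m")

_MONTH_ABBR = [
    "jan", "feb", "mar", "apr", "may", "jun",
    "jul", "aug", "sep", "oct", "nov", "dec",
]


class SeparationError(ValueError):
    """A time segment has all-zero or all-saturated outcomes."""


@dataclass
class EffectEstimate:
    """An odds ratio with its confidence interval for a named contrast."""

    name: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    test: str = "Wald"

    def __post_init__(self) -> None:
        if not self.ci_low <= self.odds_ratio <= self.ci_high:
            raise ValueError("confidence interval does not bracket the estimate")

    @property
    def log_odds(self) -> float:
        return float(np.log(self.odds_ratio))

    def __str__(self) -> str:
        return (
            f"{self.name}: OR {self.odds_ratio:.3f} "
            f"(95% CI {self.ci_low:.3f} to {self.ci_high:.3f}; "
            f"P={self.p_value:.3g}, {self.test})"
        )


def _wald_effect(name: str, coef: float, se: float, z: float = 1.959963984540054) -> EffectEstimate:
    or_ = float(np.exp(coef))
    lo = float(np.exp(coef - z * se))
    hi = float(np.exp(coef + z * se))
    p = float(2 * stats.norm.sf(abs(coef) / se)) if se > 0 else (1.0 if coef == 0 else 0.0)
    return EffectEstimate(name, or_, lo, hi, p)


class SegmentedBinomialITS:
    """Segmented binomial GLM for a monthly outcome series.

    Parameters
    ----------
    series : MonthlySeries
        Contiguous, unstratified monthly counts.
    exposure_start, exposure_end : int
        Closed interval of 0-based month indices covered by the exposure
        window.  Months strictly after ``exposure_end`` form the
        post-exposure segment.
    model_form : str
        One of ``step_only``, ``trend_only``, ``step_plus_trend``,
        ``post_split_6m``.
    seasonal : bool
        Include the eleven calendar-month indicators (default True).
    drop_during : bool
        Drop the exposure months from the likelihood instead of giving
        them their own level indicator.
    """

    def __init__(
        self,
        series: MonthlySeries,
        exposure_start: int,
        exposure_end: int,
        model_form: str = "step_only",
        seasonal: bool = True,
        drop_during: bool = False,
        post_split_months: int = 6,
    ) -> None:
        if series.stratified:
            raise ValueError("series must be unstratified; see rxits.strata for joint fits")
        if model_form not in MODEL_FORMS:
            raise ValueError(f"model_form must be one of {MODEL_FORMS}")
        n = series.n_months
        if not 0 <= exposure_start <= exposure_end < n:
            raise ValueError("exposure window must lie inside the series")
        if exposure_end >= n - 1:
            raise ValueError("exposure window leaves no post-exposure months")
        self.series = series
        self.exposure_start = int(exposure_start)
        self.exposure_end = int(exposure_end)
        self.model_form = model_form
        self.seasonal = seasonal
        self.drop_during = drop_during
        self.post_split_months = int(post_split_months)
        if (series.data["denominator"] == 0).any() and not self._rows_used().any():
            raise ValueError("no months with a positive denominator")
        self.design = self._build_design()
        self._check_rank()
        self._check_separation()

    # ------------------------------------------------------------------
    @classmethod
    def from_series(cls, series: MonthlySeries, exposure_window, **kw) -> "SegmentedBinomialITS":
        """Build from a (start_year, start_month, end_year, end_month) window."""
        sy, sm_, ey, em = exposure_window
        return cls(series, series.month_of(sy, sm_), series.month_of(ey, em), **kw)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, exposure_start: int, exposure_end: int, **kw):
        return cls(MonthlySeries(df), exposure_start, exposure_end, **kw)

    # ------------------------------------------------------------------
    def segment_labels(self) -> np.ndarray:
        t = np.arange(self.series.n_months)
        lab = np.where(
            t < self.exposure_start, "before", np.where(t <= self.exposure_end, "during", "after")
        )
        return lab

    def _build_design(self) -> pd.DataFrame:
        s = self.series
        t = s.month_index().astype(float)
        cal = s.data["month"].to_numpy()
        after = t > self.exposure_end
        during = (t >= self.exposure_start) & (t <= self.exposure_end)
        cols: dict[str, np.ndarray] = {"intercept": np.ones_like(t), "t": t}
        if self.seasonal:
            for m in range(2, 13):
                cols[f"month_{_MONTH_ABBR[m - 1]}"] = (cal == m).astype(float)
        if not self.drop_during:
            cols["during"] = during.astype(float)
        if self.model_form == "step_only":
            cols["step"] = after.astype(float)
        elif self.model_form == "trend_only":
            cols["post_slope"] = (t - self.exposure_end) * after
        elif self.model_form == "step_plus_trend":
            cols["step"] = after.astype(float)
            cols["post_slope"] = (t - self.exposure_end) * after
        elif self.model_form == "post_split_6m":
            k = self.post_split_months
            early = after & (t <= self.exposure_end + k)
            late = after & (t > self.exposure_end + k)
            cols["step_first6m"] = early.astype(float)
            cols["step_after6m"] = late.astype(float)
        X = pd.DataFrame(cols)
        return X.loc[self._rows_used()].reset_index(drop=True)

    def _rows_used(self) -> np.ndarray:
        """Months entering the likelihood: positive denominator and, when
        ``drop_during`` is set, outside the exposure window."""
        t = np.arange(self.series.n_months)
        used = self.series.data["denominator"].to_numpy() > 0
        if self.drop_during:
            used &= (t < self.exposure_start) | (t > self.exposure_end)
        return used

    def _check_rank(self) -> None:
        X = self.design.to_numpy()
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is rank deficient for this series")

    def _check_separation(self) -> None:
        num = self.series.data["numerator"].to_numpy()[self._rows_used()]
        den = self.series.data["denominator"].to_numpy()[self._rows_used()]
        lab = self.segment_labels()[self._rows_used()]
        for seg in ("before", "during", "after"):
            m = lab == seg
            if not m.any():
                continue
            if (num[m] == 0).all() or (num[m] == den[m]).all():
                raise SeparationError(f"complete separation in the '{seg}' segment")

    # ------------------------------------------------------------------
    def fit(
        self,
        lagged_residual: bool = True,
        maxiter: int = 100,
        tol: float = 1e-8,
    ) -> "SegmentedITSResults":
        """Fit by IRLS, optionally with the lag-1 Pearson-residual refit."""
        used = self._rows_used()
        num = self.series.data["numerator"].to_numpy()[used].astype(float)
        den = self.series.data["denominator"].to_numpy()[used].astype(float)
        endog = np.column_stack([num, den - num])
        X = self.design.copy()

        res1 = self._glm_fit(endog, X, maxiter, tol)
        lag = None
        if lagged_residual:
            pearson = res1.resid_pearson
            lag = np.concatenate([[0.0], pearson[:-1]])
            X = X.assign(lag_resid=lag)
            res = self._glm_fit(endog, X, maxiter, tol)
        else:
            res = res1
        phi = float(res.pearson_chi2 / res.df_resid)
        return SegmentedITSResults(self, res, stage1=res1, dispersion=phi, lag_values=lag)

    @staticmethod
    def _glm_fit(endog, X, maxiter, tol):
        model = sm.GLM(endog, X, family=sm.families.Binomial())
        res = model.fit(maxiter=maxiter, tol=tol, scale=1.0)
        if not res.converged:
            raise RuntimeError(
                f"IRLS failed to converge after {maxiter} iterations "
                f"(deviance {res.deviance:.6g})"
            )
        return res

    def exposure_slice(self) -> slice:
        """Post-exposure month indices of the series."""
        return slice(self.exposure_end + 1, self.series.n_months)


class SegmentedITSResults:
    """Fitted segmented binomial ITS.

    Coefficients are on the log-odds scale.  ``cov_params`` is the
    dispersion-scaled covariance; the unscaled matrix is kept alongside.
    """

    def __init__(self, model: SegmentedBinomialITS, glm_results, stage1, dispersion, lag_values):
        self.model = model
        self._res = glm_results
        self._stage1 = stage1
        self.dispersion = dispersion
        self.lag_values = lag_values
        self.params = glm_results.params
        self.cov_unscaled = pd.DataFrame(
            np.asarray(glm_results.cov_params()),
            index=self.params.index,
            columns=self.params.index,
        )
        self.cov_params = self.cov_unscaled * dispersion
        self.bse_unscaled = pd.Series(np.sqrt(np.diag(self.cov_unscaled)), index=self.params.index)
        self.bse = self.bse_unscaled * np.sqrt(dispersion)
        self.llf = float(glm_results.llf)
        self.deviance = float(glm_results.deviance)
        self.df_resid = int(glm_results.df_resid)
        self.converged = bool(glm_results.converged)
        self.n_iter = int(getattr(glm_results, "fit_history", {}).get("iteration", 0) or 0)

    # ------------------------------------------------------------------
    def _linear_predictor(self, counterfactual: bool = False):
        """Linear predictor with the lagged-residual covariate at zero.

        With ``counterfactual=True`` the during/step/post-slope
        coefficients are zeroed so only pre-exposure structure (level,
        trend, seasonality) is extrapolated forward.
        """
        X = self.model.design
        beta = self.params.drop(labels=["lag_resid"], errors="ignore")
        if counterfactual:
            beta = beta.copy()
            for name in ("during", "step", "post_slope", "step_first6m", "step_after6m"):
                if name in beta.index:
                    beta[name] = 0.0
        Xb = X[beta.index]
        eta = Xb.to_numpy() @ beta.to_numpy()
        C = self.cov_params.loc[beta.index, beta.index].to_numpy()
        if counterfactual:
            keep = [
                n
                for n in beta.index
                if n not in ("during", "step", "post_slope", "step_first6m", "step_after6m")
            ]
            Xv = X[keep].to_numpy()
            Cv = self.cov_params.loc[keep, keep].to_numpy()
            var = np.einsum("ij,jk,ik->i", Xv, Cv, Xv)
        else:
            var = np.einsum("ij,jk,ik->i", Xb.to_numpy(), C, Xb.to_numpy())
        return eta, np.sqrt(np.maximum(var, 0.0))

    def predict_curve(self, alpha: float = 0.05) -> pd.DataFrame:
        """Fitted probabilities with pointwise confidence band, plus the
        counterfactual projection of the pre-exposure trend."""
        z = stats.norm.ppf(1 - alpha / 2)
        eta, se = self._linear_predictor()
        eta_cf, _ = self._linear_predictor(counterfactual=True)
        s = self.model.series
        used = self.model._rows_used()
        df = s.data.loc[used, ["year", "month", "denominator", "numerator"]].reset_index(drop=True)
        df["observed"] = df["numerator"] / df["denominator"]
        df["fitted"] = expit(eta)
        df["lower"] = expit(eta - z * se)
        df["upper"] = expit(eta + z * se)
        df["counterfactual"] = expit(eta_cf)
        df["segment"] = self.model.segment_labels()[used]
        return df

    def counterfactual(self) -> np.ndarray:
        eta_cf, _ = self._linear_predictor(counterfactual=True)
        return expit(eta_cf)

    # ------------------------------------------------------------------
    def _named_effect(self, coef_name: str, label: str) -> EffectEstimate:
        if coef_name not in self.params.index:
            raise ValueError(
                f"model form {self.model.model_form!r} has no {coef_name!r} term"
            )
        return _wald_effect(label, float(self.params[coef_name]), float(self.bse[coef_name]))

    def step_odds_ratio(self) -> EffectEstimate:
        """Post-exposure level change as an odds ratio (Wald, scaled SE)."""
        return self._named_effect("step", "step_or")

    def during_odds_ratio(self) -> EffectEstimate:
        return self._named_effect("during", "during_or")

    def trend_change_test(self) -> EffectEstimate:
        """Wald test of the pre- vs post-exposure slope difference,
        reported as a per-month odds ratio."""
        return self._named_effect("post_slope", "post_slope_or_per_month")

    def post_period_odds_ratios(self) -> tuple[EffectEstimate, EffectEstimate]:
        """Step ORs for the first six and the later post-exposure months."""
        return (
            self._named_effect("step_first6m", "step_or_first6m"),
            self._named_effect("step_after6m", "step_or_after6m"),
        )

    def effects(self) -> list[EffectEstimate]:
        out = []
        for name, label in (
            ("during", "during_or"),
            ("step", "step_or"),
            ("post_slope", "post_slope_or_per_month"),
            ("step_first6m", "step_or_first6m"),
            ("step_after6m", "step_or_after6m"),
        ):
            if name in self.params.index:
                out.append(self._named_effect(name, label))
        return out

    # ------------------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Segmented binomial ITS (logit link)",
            f"  model form: {self.model.model_form}   months: {self.model.series.n_months}"
            f"   exposure: [{self.model.exposure_start}, {self.model.exposure_end}]",
            f"  dispersion (Pearson chi2/df): {self.dispersion:.4f}"
            f"   deviance: {self.deviance:.2f}   df_resid: {self.df_resid}",
            "",
            f"  {'term':<16}{'coef':>10}{'se(scaled)':>12}{'OR':>9}{'p':>10}",
        ]
        for name in self.params.index:
            b = self.params[name]
            se = self.bse[name]
            p = 2 * stats.norm.sf(abs(b) / se) if se > 0 else float("nan")
            lines.append(
                f"  {name:<16}{b:>10.4f}{se:>12.4f}{np.exp(b):>9.3f}{p:>10.3g}"
            )
        lines.append("")
        for eff in self.effects():
            lines.append("  " + str(eff))
        return "\n".join(lines)

    def to_report(self) -> dict:
        """JSON-serialisable fit report."""
        return {
            "model_form": self.model.model_form,
            "exposure": [self.model.exposure_start, self.model.exposure_end],
            "n_months": int(self.model.series.n_months),
            "dispersion": self.dispersion,
            "deviance": self.deviance,
            "llf": self.llf,
            "converged": self.converged,
            "coefficients": {k: float(v) for k, v in self.params.items()},
            "se_scaled": {k: float(v) for k, v in self.bse.items()},
            "effects": [
                {
                    "name": e.name,
                    "odds_ratio": e.odds_ratio,
                    "ci": [e.ci_low, e.ci_high],
                    "p": e.p_value,
                    "test": e.test,
                }
                for e in self.effects()
            ],
        }

    def plot(self, ax=None):
        """Observed proportions, fitted curve with band, dotted counterfactual."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        df = self.predict_curve()
        x = np.arange(len(df))
        ax.scatter(x, df["observed"], s=12, color="black", zorder=3, label="observed")
        ax.plot(x, df["fitted"], color="tab:blue", label="fitted")
        ax.fill_between(x, df["lower"], df["upper"], color="tab:blue", alpha=0.25, lw=0)
        post = df["segment"] == "after"
        ax.plot(x[post], df.loc[post, "counterfactual"], "k:", label="counterfactual")
        ax.axvspan(
            self.model.exposure_start - 0.5, self.model.exposure_end + 0.5,
            color="grey", alpha=0.15,
        )
        ax.set_xlabel("month")
        ax.set_ylabel("proportion")
        ax.legend(frameon=False)
        return ax


def negative_control(
    series_alt_drug: MonthlySeries,
    series_shifted_window: MonthlySeries,
    exposure_start: int,
    exposure_end: int,
    window_shift_months: int = -12,
) -> tuple[EffectEstimate, EffectEstimate]:
    """Run the step-only analysis on the two negative controls.

    The first control applies the true exposure window to a series built
    from an unrelated drug class; the second applies a shifted window
    (default 12 months earlier) to the outcome series itself.
    """
    import warnings

    alt = SegmentedBinomialITS(
        series_alt_drug, exposure_start, exposure_end, model_form="step_only"
    ).fit()
    s, e = exposure_start + window_shift_months, exposure_end + window_shift_months
    if not (e < exposure_start or s > exposure_end):
        warnings.warn("shifted window overlaps the true exposure window", stacklevel=2)
    shifted = SegmentedBinomialITS(
        series_shifted_window, s, e, model_form="step_only"
    ).fit()
    a = alt.step_odds_ratio()
    b = shifted.step_odds_ratio()
    a.name, b.name = "alt_drug_step_or", "shifted_window_step_or"
    return a, b
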