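"""Effect-modification analysis for the segmented binomial ITS.

A single joint binomial model is fitted to a stratified monthly series:
seasonal and trend terms are shared across strata, each stratum gets its
own level (main effect), and the post-exposure step is allowed to differ
by stratum through step x stratum interaction terms.  A likelihood-ratio
test against the common-step model tests effect modification; for
ordinal modifiers a scored linear-trend contrast replaces the free
interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .its import EffectEstimate, SegmentedBinomialITS, _wald_effect
from .series import MonthlySeries

__all__ = [
    "InteractionResults",
    "fit_interaction",
    "ordinal_trend_test",
    "binary_duration_contrast",
    "aggregate_strata",
]

_POST_TERMS = ("during", "step", "post_slope", "step_first6m", "step_after6m")


def _joint_design(
    series: MonthlySeries,
    exposure_start: int,
    exposure_end: int,
    stratum_order=None,
    interactions: str = "step",
):
    """Long-format design over (stratum, month) rows.

    ``interactions``: ``"none"`` (common step), ``"step"`` (step x stratum)
    or ``"full"`` (every covariate x stratum; reproduces separate fits).
    """
    if not series.stratified:
        raise ValueError("series must be stratified")
    labels = stratum_order or series.strata()
    if len(labels) < 2:
        raise ValueError("need at least 2 strata for an interaction model")
    frames = []
    base_cols = None
    for k, lab in enumerate(labels):
        sub = series.select_stratum(lab)
        m = SegmentedBinomialITS(sub, exposure_start, exposure_end, model_form="step_only")
        X = m.design.copy()
        base_cols = list(X.columns)
        X["__stratum"] = lab
        X["__num"] = sub.data["numerator"].to_numpy()
        X["__den"] = sub.data["denominator"].to_numpy()
        frames.append(X)
    long = pd.concat(frames, ignore_index=True)
    zero_den = long["__den"] == 0
    if zero_den.any():
        import warnings

        empty = long.loc[zero_den, "__stratum"].unique()
        warnings.warn(f"dropping {int(zero_den.sum())} zero-denominator rows", stacklevel=2)
    long = long[~zero_den].reset_index(drop=True)

    for lab in labels[1:]:
        long[f"stratum[{lab}]"] = (long["__stratum"] == lab).astype(float)
    if interactions == "step":
        for lab in labels[1:]:
            long[f"step:stratum[{lab}]"] = long["step"] * (long["__stratum"] == lab)
    elif interactions == "full":
        for col in base_cols:
            if col == "intercept":
                continue
            for lab in labels[1:]:
                long[f"{col}:stratum[{lab}]"] = long[col] * (long["__stratum"] == lab)
    elif interactions != "none":
        raise ValueError("interactions must be 'none', 'step' or 'full'")
    return long, labels


def _fit_long(long: pd.DataFrame, lagged_residual: bool):
    cols = [c for c in long.columns if not c.startswith("__")]
    endog = np.column_stack([long["__num"], long["__den"] - long["__num"]])
    X = long[cols]
    model = sm.GLM(endog, X, family=sm.families.Binomial())
    res = model.fit(scale=1.0)
    if lagged_residual:
        lag = (
            pd.Series(res.resid_pearson, index=long.index)
            .groupby(long["__stratum"])
            .shift(1)
            .fillna(0.0)
        )
        X = X.assign(lag_resid=lag.to_numpy())
        res = sm.GLM(endog, X, family=sm.families.Binomial()).fit(scale=1.0)
    return res


@dataclass
class InteractionResults:
    """Joint stratified fit with the effect-modification tests."""

    modifier: str
    strata: list
    params: pd.Series
    cov_params: pd.DataFrame
    dispersion: float
    lrt_stat: float
    lrt_df: int
    lrt_p: float
    f_style_stat: float
    dispersion_flag: bool
    per_stratum: dict = field(default_factory=dict)
    trend: EffectEstimate | None = None
    llf_full: float = 0.0
    llf_reduced: float = 0.0

    def summary(self) -> str:
        lines = [
            f"Effect modification by {self.modifier} ({len(self.strata)} strata)",
            f"  LRT: chi2={self.lrt_stat:.3f}, df={self.lrt_df}, P={self.lrt_p:.4g}"
            + ("  [dispersion-flagged]" if self.dispersion_flag else ""),
            f"  dispersion-adjusted statistic: {self.f_style_stat:.3f} (phi={self.dispersion:.3f})",
        ]
        for lab in self.strata:
            lines.append("  " + str(self.per_stratum[lab]))
        if self.trend is not None:
            lines.append("  " + str(self.trend))
        return "\n".join(lines)

    def to_report(self) -> dict:
        rep = {
            "modifier": self.modifier,
            "strata": list(self.strata),
            "lrt": {"stat": self.lrt_stat, "df": self.lrt_df, "p": self.lrt_p},
            "f_style_stat": self.f_style_stat,
            "dispersion": self.dispersion,
            "dispersion_flag": self.dispersion_flag,
            "per_stratum_step_or": {
                str(lab): {
                    "odds_ratio": e.odds_ratio,
                    "ci": [e.ci_low, e.ci_high],
                    "p": e.p_value,
                }
                for lab, e in self.per_stratum.items()
            },
        }
        if self.trend is not None:
            t = self.trend
            rep["ordinal_trend"] = {
                "odds_ratio": t.odds_ratio,
                "ci": [t.ci_low, t.ci_high],
                "p": t.p_value,
            }
        return rep

    def forest_table(self) -> pd.DataFrame:
        """Per-stratum step odds ratios in a forest-plot-ready layout."""
        rows = [
            (lab, e.odds_ratio, e.ci_low, e.ci_high, e.p_value)
            for lab, e in self.per_stratum.items()
        ]
        return pd.DataFrame(rows, columns=["stratum", "step_or", "ci_low", "ci_high", "p"])


def fit_interaction(
    stratified_series: MonthlySeries,
    exposure_start: int,
    exposure_end: int,
    modifier: str = "stratum",
    stratum_order=None,
    lagged_residual: bool = True,
    dispersion_flag_threshold: float = 1.5,
) -> InteractionResults:
    """Joint step-only model with stratum-specific steps and an LRT for
    effect modification.

    The LRT compares the interaction model with the common-step model,
    both without the lagged-residual covariate so the two likelihoods are
    defined on identical data and covariate sets; per-stratum estimates
    and their dispersion-scaled intervals come from the lag-corrected
    interaction fit.  When the Pearson dispersion exceeds the flag
    threshold the LRT p-value is flagged and a dispersion-adjusted
    statistic (LRT / (df * phi)) is reported alongside.
    """
    long_full, labels = _joint_design(
        stratified_series, exposure_start, exposure_end, stratum_order, interactions="step"
    )
    long_red, _ = _joint_design(
        stratified_series, exposure_start, exposure_end, stratum_order, interactions="none"
    )
    res_full_plain = _fit_long(long_full, lagged_residual=False)
    res_red_plain = _fit_long(long_red, lagged_residual=False)
    lrt = max(0.0, 2.0 * (res_full_plain.llf - res_red_plain.llf))
    df = len(labels) - 1
    p = float(stats.chi2.sf(lrt, df))

    res = _fit_long(long_full, lagged_residual=lagged_residual)
    phi = float(res.pearson_chi2 / res.df_resid)
    params = res.params
    cov = pd.DataFrame(
        np.asarray(res.cov_params()) * phi, index=params.index, columns=params.index
    )
    per = {}
    for lab in labels:
        names = ["step"] + ([f"step:stratum[{lab}]"] if lab != labels[0] else [])
        c = np.zeros(len(params))
        for nm in names:
            c[params.index.get_loc(nm)] = 1.0
        b = float(c @ params.to_numpy())
        se = float(np.sqrt(c @ cov.to_numpy() @ c))
        per[lab] = _wald_effect(f"step_or[{lab}]", b, se)

    return InteractionResults(
        modifier=modifier,
        strata=labels,
        params=params,
        cov_params=cov,
        dispersion=phi,
        lrt_stat=float(lrt),
        lrt_df=df,
        lrt_p=p,
        f_style_stat=float(lrt / (df * phi)) if phi > 0 else float("nan"),
        dispersion_flag=phi > dispersion_flag_threshold,
        per_stratum=per,
        llf_full=float(res_full_plain.llf),
        llf_reduced=float(res_red_plain.llf),
    )


def ordinal_trend_test(
    stratified_series: MonthlySeries,
    exposure_start: int,
    exposure_end: int,
    stratum_order,
    scores=None,
    lagged_residual: bool = True,
) -> EffectEstimate:
    """Linear-trend test of the step effect across ordered strata.

    The stratum-specific step terms are replaced by a single
    score x step product (default scores 0..K-1 in the given stratum
    order); the Wald test on its coefficient is returned as a per-unit-
    score odds ratio.
    """
    labels = list(stratum_order)
    if scores is None:
        scores = np.arange(len(labels), dtype=float)
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(labels):
        raise ValueError("one score per stratum required")
    long, labels = _joint_design(
        stratified_series, exposure_start, exposure_end, labels, interactions="none"
    )
    score_map = dict(zip(labels, scores))
    long["step:score"] = long["step"] * long["__stratum"].map(score_map)
    res = _fit_long(long, lagged_residual=lagged_residual)
    phi = float(res.pearson_chi2 / res.df_resid)
    b = float(res.params["step:score"])
    se = float(np.sqrt(np.asarray(res.cov_params()).diagonal()[res.params.index.get_loc("step:score")] * phi))
    return _wald_effect("step_trend_or_per_score", b, se)


def aggregate_strata(series: MonthlySeries, mapping: dict) -> MonthlySeries:
    """Re-aggregate strata through a label -> new-label mapping, summing
    counts exactly."""
    if not series.stratified:
        raise ValueError("series must be stratified")
    df = series.data.copy()
    df["stratum"] = df["stratum"].map(mapping)
    if df["stratum"].isna().any():
        raise ValueError("mapping must cover every stratum label")
    agg = (
        df.groupby(["year", "month", "stratum"], as_index=False)[["denominator", "numerator"]]
        .sum()
        .sort_values(["stratum", "year", "month"])
        .reset_index(drop=True)
    )
    out = MonthlySeries(
        agg,
        outcome=series.outcome,
        prevention=series.prevention,
        grace_days=series.grace_days,
        meta=dict(series.meta),
    )
    return out


def binary_duration_contrast(
    duration_series: MonthlySeries,
    exposure_start: int,
    exposure_end: int,
    lagged_residual: bool = True,
) -> tuple[EffectEstimate, EffectEstimate]:
    """Step ORs for under- vs over-one-year of previous continuous
    prescription, collapsing the five duration categories into two."""
    from .cohort import DURATION_CATEGORIES

    mapping = {
        DURATION_CATEGORIES[0]: "lt1y",
        DURATION_CATEGORIES[1]: "lt1y",
        DURATION_CATEGORIES[2]: "ge1y",
        DURATION_CATEGORIES[3]: "ge1y",
        DURATION_CATEGORIES[4]: "ge1y",
    }
    mapping = {k: v for k, v in mapping.items() if k in duration_series.strata()}
    two = aggregate_strata(duration_series, mapping)
    fit = fit_interaction(
        two,
        exposure_start,
        exposure_end,
        modifier="duration_binary",
        stratum_order=["lt1y", "ge1y"],
        lagged_residual=lagged_residual,
    )
    return fit.per_stratum["lt1y"], fit.per_stratum["ge1y"]
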