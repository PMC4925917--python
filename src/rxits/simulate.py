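"""Synthetic data generators.

Two generators with known ground truth:

* :func:`generate_series` draws monthly binomial counts whose log odds
  follow the same segmented structure the ITS model estimates — baseline
  level, linear month-on-month trend, calendar-month seasonality, a level
  shift during a media-exposure window, a step (and optionally a slope
  change) after it, latent AR(1) noise and beta-binomial overdispersion.
  It is the parameter-recovery harness for the estimator.

* :func:`generate_population` draws a patient-level record stream
  (patients, prescriptions, risk scores, clinical events) with the same
  statistical structure, so the cohort engine can be validated end to end
  against configured truths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .series import MonthlySeries

__all__ = [
    "SeriesSimConfig",
    "PopulationSimConfig",
    "PopulationTables",
    "generate_series",
    "generate_population",
    "seasonal_harmonic",
]

_ETA_BOUND = 30.0  # |log odds| beyond which expit under/overflows to 0/1


def seasonal_harmonic(amplitude: float, phase: float = 0.0) -> np.ndarray:
    """Twelve calendar-month log-odds offsets on a sine wave, summing to zero."""
    m = np.arange(12)
    s = amplitude * np.sin(2 * np.pi * (m + phase) / 12)
    return s - s.mean()


@dataclass
class SeriesSimConfig:
    """Ground-truth parameters for a monthly binomial outcome series.

    All effect parameters are on the log-odds scale.  The exposure window
    is a closed interval of 0-based month indices; the post-exposure
    segment starts the month after ``exposure_end_index``.
    """

    n_months: int = 51
    exposure_start_index: int = 33  # Oct 2013 when the series starts Jan 2011
    exposure_end_index: int = 38  # Mar 2014
    baseline_logit: float = logit(0.08)
    trend_per_month: float = 0.0
    seasonal_amplitudes: np.ndarray = field(default_factory=lambda: np.zeros(12))
    step_log_or: float = 0.0
    trend_change_per_month: float = 0.0
    during_log_or: float = 0.0
    denominators: int | np.ndarray = 180_000
    ar1_rho: float = 0.0
    noise_sd: float = 0.0
    dispersion: float = 1.0
    seed: int = 0
    start_year: int = 2011
    start_month: int = 1

    def __post_init__(self) -> None:
        self.seasonal_amplitudes = np.asarray(self.seasonal_amplitudes, dtype=float)
        if self.seasonal_amplitudes.shape != (12,):
            raise ValueError("seasonal_amplitudes must have 12 entries")
        if abs(self.seasonal_amplitudes.sum()) > 1e-8:
            raise ValueError("seasonal_amplitudes must sum to zero")
        if not (0 <= self.exposure_start_index <= self.exposure_end_index < self.n_months):
            raise ValueError("exposure indices must satisfy 0 <= start <= end < n_months")
        if not 0 <= self.ar1_rho < 1:
            raise ValueError("ar1_rho must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.dispersion < 1:
            raise ValueError("dispersion must be >= 1")
        den = np.asarray(self.denominators)
        if (den < 1).any():
            raise ValueError("denominators must be >= 1")

    def denominator_array(self) -> np.ndarray:
        den = np.asarray(self.denominators, dtype=np.int64)
        if den.ndim == 0:
            den = np.full(self.n_months, int(den), dtype=np.int64)
        if den.shape != (self.n_months,):
            raise ValueError("denominators must be scalar or length n_months")
        return den

    def linear_predictor(self) -> np.ndarray:
        """Deterministic part of the monthly log odds (no AR noise)."""
        t = np.arange(self.n_months)
        cal = (self.start_month - 1 + t) % 12
        during = (t >= self.exposure_start_index) & (t <= self.exposure_end_index)
        after = t > self.exposure_end_index
        eta = (
            self.baseline_logit
            + self.trend_per_month * t
            + self.seasonal_amplitudes[cal]
            + self.during_log_or * during
            + self.step_log_or * after
            + self.trend_change_per_month * (t - self.exposure_end_index) * after
        )
        return eta


def generate_series(config: SeriesSimConfig) -> MonthlySeries:
    """Draw one monthly series from the configured segmented-logit truth.

    The numerator for month *t* is binomial (or beta-binomial when
    ``dispersion > 1``) with denominator ``n_t`` and success probability
    ``expit(eta_t + e_t)``, where ``e_t`` is stationary AR(1) noise with
    marginal standard deviation ``noise_sd`` and lag-1 correlation
    ``ar1_rho``.  Identical configs (including seed) give identical output.
    """
    eta0 = config.linear_predictor()
    if np.abs(eta0).max() > _ETA_BOUND:
        raise ValueError("parameter combination implies probability numerically at 0 or 1")
    rng = np.random.default_rng(config.seed)
    n = config.denominator_array()

    e = np.zeros(config.n_months)
    if config.noise_sd > 0:
        z = rng.standard_normal(config.n_months)
        e[0] = config.noise_sd * z[0]
        innov_sd = config.noise_sd * math.sqrt(1 - config.ar1_rho**2)
        for t in range(1, config.n_months):
            e[t] = config.ar1_rho * e[t - 1] + innov_sd * z[t]

    p = expit(eta0 + e)
    if config.dispersion > 1:
        if config.dispersion >= n.min():
            raise ValueError("dispersion must be smaller than the smallest denominator")
        # beta-binomial with Var = n p (1-p) * dispersion
        s = (n - config.dispersion) / (config.dispersion - 1)
        p_draw = rng.beta(p * s, (1 - p) * s)
        num = rng.binomial(n, p_draw)
    else:
        num = rng.binomial(n, p)

    series = MonthlySeries.from_arrays(
        num,
        n,
        start_year=config.start_year,
        start_month=config.start_month,
        outcome="simulated",
        meta={"true_p": p, "true_eta": eta0, "seed": config.seed},
    )
    return series


# ----------------------------------------------------------------------
# Patient-level simulator
# ----------------------------------------------------------------------


@dataclass
class PopulationSimConfig:
    """Parameters of the patient-level record-stream generator.

    Prescribing is modelled as renewal chains: each prescription is a
    discrete supply (quantity / daily dose days); at every renewal point
    the patient stops with a probability whose log odds carry the same
    trend / seasonal / exposure-step structure as the series generator,
    so the cohort engine's output series has a known segmented truth.
    """

    n_patients: int = 2000
    study_start: date = date(2011, 1, 1)
    study_end: date = date(2015, 3, 31)
    exposure_start: date = date(2013, 10, 1)
    exposure_end: date = date(2014, 3, 31)
    # demography
    age_min: int = 45
    age_max: int = 85
    male_fraction: float = 0.5
    diabetes_prevalence: float = 0.2
    prevalent_cvd_fraction: float = 0.15
    registration_lead_years_max: float = 10.0
    # hazards (per month unless stated)
    death_hazard: float = 0.001
    transfer_hazard: float = 0.001
    cv_event_hazard: float = 0.002
    risk_score_hazard: float = 0.01
    risk_score_mean: float = 16.0
    risk_score_sd: float = 9.0
    # statin exposure and initiation
    fraction_on_statin_at_start: float = 0.5
    init_prob_primary: float = 0.6
    init_prob_secondary: float = 0.7
    init_grace_primary_days: int = 28
    init_grace_secondary_days: int = 60
    # prescribing / cessation mechanics
    supply_days: tuple = (28, 56, 84)
    supply_weights: tuple = (0.7, 0.2, 0.1)
    daily_dose: float = 1.0
    renewal_gap_max_days: int = 21
    cease_base_prob: float = 0.06
    cease_trend_log_or_per_month: float = 0.0
    cease_seasonal_amplitude: float = 0.0
    cease_step_log_or: float = 0.0
    cease_during_log_or: float = 0.0
    restart_prob: float = 0.3
    restart_gap_days: tuple = (60, 365)
    drug_codes: tuple = ("statin_a", "statin_b", "statin_c")
    risk_threshold: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.study_end <= self.study_start:
            raise ValueError("study_end must follow study_start")
        for name in (
            "male_fraction",
            "diabetes_prevalence",
            "prevalent_cvd_fraction",
            "fraction_on_statin_at_start",
            "init_prob_primary",
            "init_prob_secondary",
            "cease_base_prob",
            "restart_prob",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("death_hazard", "transfer_hazard", "cv_event_hazard", "risk_score_hazard"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class PopulationTables:
    """The four record tables the cohort engine consumes."""

    patients: pd.DataFrame
    prescriptions: pd.DataFrame
    risk_scores: pd.DataFrame
    events: pd.DataFrame

    def write(self, directory) -> dict:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("patients", "prescriptions", "risk_scores", "events"):
            p = d / f"{name}.csv"
            getattr(self, name).to_csv(p, index=False, date_format="%Y-%m-%d")
            paths[name] = p
        return paths


_DAYS_PER_MONTH = 30.4375


def _exp_days(rng: np.random.Generator, monthly_hazard: float) -> float:
    if monthly_hazard <= 0:
        return math.inf
    return rng.exponential(_DAYS_PER_MONTH / monthly_hazard)


def _cease_logit(cfg: PopulationSimConfig, when: date) -> float:
    months = (when.year - cfg.study_start.year) * 12 + (when.month - cfg.study_start.month)
    eta = logit(cfg.cease_base_prob) + cfg.cease_trend_log_or_per_month * months
    if cfg.cease_seasonal_amplitude:
        eta += seasonal_harmonic(cfg.cease_seasonal_amplitude)[when.month - 1]
    if cfg.exposure_start <= when <= cfg.exposure_end:
        eta += cfg.cease_during_log_or
    elif when > cfg.exposure_end:
        eta += cfg.cease_step_log_or
    return eta


def generate_population(config: PopulationSimConfig) -> PopulationTables:
    """Simulate internally consistent patient, prescription, score and event tables.

    No prescription is issued after a patient's follow-up ends; clinical
    events and risk scores fall within follow-up; cessation decisions are
    per-renewal Bernoulli draws on the configured log-odds scale.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    horizon = cfg.study_end + timedelta(days=120)  # observe grace windows past the series tail

    patients, prescriptions, scores, events = [], [], [], []

    for pid in range(1, cfg.n_patients + 1):
        age = rng.uniform(cfg.age_min, cfg.age_max)
        birth_year = cfg.study_start.year - int(age)
        sex = "M" if rng.random() < cfg.male_fraction else "F"
        reg_start = cfg.study_start - timedelta(
            days=int(rng.uniform(370, cfg.registration_lead_years_max * 365.25))
        )
        death_t = _exp_days(rng, cfg.death_hazard)
        transfer_t = _exp_days(rng, cfg.transfer_hazard)
        death_date = None
        if death_t <= transfer_t and math.isfinite(death_t):
            death_date = cfg.study_start + timedelta(days=int(death_t))
        end_t = min(death_t, transfer_t)
        followup_end = horizon
        if math.isfinite(end_t):
            followup_end = min(horizon, cfg.study_start + timedelta(days=int(end_t)))
        if death_date is not None and death_date > followup_end:
            death_date = None

        diabetes_date = None
        if rng.random() < cfg.diabetes_prevalence:
            diabetes_date = reg_start + timedelta(days=int(rng.uniform(0, 1000)))
            if diabetes_date >= followup_end:
                diabetes_date = None

        # cardiovascular events: optionally prevalent, then one incident draw
        first_event = None
        if rng.random() < cfg.prevalent_cvd_fraction:
            first_event = reg_start + timedelta(days=int(rng.uniform(0, 350)))
        else:
            ev_t = _exp_days(rng, cfg.cv_event_hazard)
            if math.isfinite(ev_t):
                cand = cfg.study_start + timedelta(days=int(ev_t))
                if cand < followup_end:
                    first_event = cand
        if first_event is not None:
            events.append((pid, first_event, "cv_event"))

        # risk-score recording: Poisson process over follow-up
        t_cursor = cfg.study_start
        first_high_score = None
        while True:
            gap = _exp_days(rng, cfg.risk_score_hazard)
            if not math.isfinite(gap):
                break
            t_cursor = t_cursor + timedelta(days=int(gap) + 1)
            if t_cursor >= followup_end or t_cursor > horizon:
                break
            val = float(np.clip(rng.normal(cfg.risk_score_mean, cfg.risk_score_sd), 0.5, 70.0))
            scores.append((pid, t_cursor, round(val, 1)))
            if first_high_score is None and val >= cfg.risk_threshold:
                first_high_score = t_cursor

        # statin exposure: prevalent user chain, or initiation on first indication
        chain_starts = []
        if rng.random() < cfg.fraction_on_statin_at_start:
            start = reg_start + timedelta(days=int(rng.uniform(380, 2000)))
            if start < cfg.study_start:
                chain_starts.append(start)
        else:
            indication = None
            grace = None
            prob = None
            if first_event is not None and first_event >= cfg.study_start:
                indication, grace, prob = (
                    first_event,
                    cfg.init_grace_secondary_days,
                    cfg.init_prob_secondary,
                )
            if first_high_score is not None and (
                indication is None or first_high_score < indication
            ):
                indication, grace, prob = (
                    first_high_score,
                    cfg.init_grace_primary_days,
                    cfg.init_prob_primary,
                )
            if indication is not None and rng.random() < prob:
                chain_starts.append(indication + timedelta(days=int(rng.uniform(0, grace + 1))))

        # prescription renewal chains
        while chain_starts:
            issue = chain_starts.pop()
            drug = cfg.drug_codes[rng.integers(len(cfg.drug_codes))]
            while issue < followup_end and issue <= horizon:
                supply = int(rng.choice(cfg.supply_days, p=cfg.supply_weights))
                quantity = int(round(supply * cfg.daily_dose))
                prescriptions.append((pid, drug, issue, quantity, cfg.daily_dose))
                end = issue + timedelta(days=supply)
                p_stop = expit(_cease_logit(cfg, end))
                if rng.random() < p_stop:
                    if rng.random() < cfg.restart_prob:
                        lo, hi = cfg.restart_gap_days
                        restart = end + timedelta(days=int(rng.uniform(lo, hi)))
                        if restart < followup_end:
                            chain_starts.append(restart)
                    break
                issue = end + timedelta(days=int(rng.integers(0, cfg.renewal_gap_max_days + 1)))

        patients.append(
            (pid, sex, birth_year, reg_start, followup_end, death_date, diabetes_date)
        )

    pt = pd.DataFrame(
        patients,
        columns=[
            "patient_id",
            "sex",
            "birth_year",
            "registration_start",
            "followup_end",
            "death_date",
            "diabetes_date",
        ],
    )
    rx = pd.DataFrame(
        prescriptions,
        columns=["patient_id", "drug_code", "issue_date", "quantity", "daily_dose"],
    )
    rs = pd.DataFrame(scores, columns=["patient_id", "date", "score"])
    ev = pd.DataFrame(events, columns=["patient_id", "date", "category"])
    for df, cols in (
        (pt, ["registration_start", "followup_end", "death_date", "diabetes_date"]),
        (rx, ["issue_date"]),
        (rs, ["date"]),
        (ev, ["date"]),
    ):
        for c in cols:
            df[c] = pd.to_datetime(df[c])
    return PopulationTables(pt, rx, rs, ev)
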