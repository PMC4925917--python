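"""Cohort engine: raw record tables to monthly outcome series.

Implements drug-utilisation outcome definitions on longitudinal
primary-care tables:

* *Initiation*: among patients newly eligible for treatment in a calendar
  month (a first high 10-year cardiovascular risk score for primary
  prevention, an incident cardiovascular event for secondary), the
  proportion receiving a first prescription within a grace window
  (28 days / 60 days).  Denominators require the patient to remain alive,
  registered and (primary prevention) event-free through the full window.
* *Cessation*: among prescription episodes ending in a calendar month,
  the proportion with no further prescription issued within a 28-day
  grace period of the episode's computed end date.  Patients contribute
  one unit per qualifying episode.

Day counting is inclusive: a next issue exactly ``grace_days`` after the
end date is a continuation; one day later is a cessation.
"""

from __future__ import annotations

import calendar
import logging
import math
from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .series import MonthlySeries

__all__ = [
    "CohortConfig",
    "compute_episode_end",
    "episodes_from_prescriptions",
    "classify_prevention",
    "build_initiation_series",
    "build_cessation_series",
    "stratify_cessation",
    "build_risk_score_series",
    "AGE_GROUPS",
    "DURATION_CATEGORIES",
    "RISK_CATEGORIES",
]

log = logging.getLogger("rxits.cohort")

AGE_GROUPS = ["40-49", "50-59", "60-69", "70-79", "80+"]
DURATION_CATEGORIES = ["le6m", "6m-1y", "1y-2y", "2y-4y", "gt4y"]
RISK_CATEGORIES = ("any", "lt10", "10to20", "20to30", "ge30")
MODIFIERS = ("age_group", "sex", "diabetes", "duration")


@dataclass
class CohortConfig:
    """Eligibility rules, grace periods and stratification cut points."""

    study_start: date = date(2011, 1, 1)
    study_end: date = date(2015, 3, 31)
    exposure_start: date = date(2013, 10, 1)
    exposure_end: date = date(2014, 3, 31)
    min_age: float = 40.0  # exclusive: eligible when exact age > min_age
    min_registration_days: int = 365
    risk_threshold: float = 20.0
    initiation_grace_primary_days: int = 28
    initiation_grace_secondary_days: int = 60
    cessation_grace_days: int = 28
    duration_cutpoints: tuple = (182, 365, 730, 1460)

    def __post_init__(self) -> None:
        if self.study_end <= self.study_start:
            raise ValueError("study_end must follow study_start")
        cuts = tuple(self.duration_cutpoints)
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError("duration cut points must be strictly increasing")
        for f in (
            "min_registration_days",
            "risk_threshold",
            "initiation_grace_primary_days",
            "initiation_grace_secondary_days",
            "cessation_grace_days",
        ):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


# ----------------------------------------------------------------------
# episodes
# ----------------------------------------------------------------------


def compute_episode_end(start_date, quantity, daily_dose, fallback_dose=None):
    """End date of a prescription: start + ceil(quantity / daily dose) days.

    ``fallback_dose`` (typically the per-drug median) is used when the
    daily dose is missing; with neither available a ValueError is raised
    and the caller drops the record.
    """
    dose = daily_dose
    if dose is None or (isinstance(dose, float) and math.isnan(dose)):
        dose = fallback_dose
    if dose is None or (isinstance(dose, float) and math.isnan(dose)) or dose <= 0:
        raise ValueError("no usable daily dose for episode end computation")
    if quantity < 1:
        raise ValueError("quantity must be >= 1")
    days = int(math.ceil(quantity / dose))
    return start_date + timedelta(days=days)


def episodes_from_prescriptions(
    prescriptions: pd.DataFrame, codes=None
) -> pd.DataFrame:
    """Convert a prescription table to episodes with computed end dates.

    Restricts to ``codes`` (an iterable of drug code strings) when given.
    Missing daily doses fall back to the per-drug median dose computed
    over the input; records with no computable dose are dropped and
    counted in the log.
    """
    rx = prescriptions.copy()
    if codes is not None:
        codes = set(codes)
        rx = rx[rx["drug_code"].isin(codes)]
    rx = rx.reset_index(drop=True)
    if rx.empty:
        return pd.DataFrame(
            columns=["patient_id", "drug_code", "start_date", "end_date", "quantity", "daily_dose"]
        )
    dose = pd.to_numeric(rx["daily_dose"], errors="coerce")
    dose = dose.where(dose > 0)
    fallback = dose.groupby(rx["drug_code"]).transform("median")
    eff = dose.fillna(fallback)
    bad = eff.isna() | (eff <= 0) | (rx["quantity"] < 1)
    if bad.any():
        log.warning("dropped %d prescriptions with no computable duration", int(bad.sum()))
        rx, eff = rx[~bad].reset_index(drop=True), eff[~bad].reset_index(drop=True)
    days = np.ceil(rx["quantity"].to_numpy(dtype=float) / eff.to_numpy()).astype(int)
    out = pd.DataFrame(
        {
            "patient_id": rx["patient_id"].to_numpy(),
            "drug_code": rx["drug_code"].to_numpy(),
            "start_date": pd.to_datetime(rx["issue_date"]),
            "quantity": rx["quantity"].to_numpy(),
            "daily_dose": eff.to_numpy(),
        }
    )
    out["end_date"] = out["start_date"] + pd.to_timedelta(days, unit="D")
    return out.sort_values(["patient_id", "start_date"]).reset_index(drop=True)


# ----------------------------------------------------------------------
# helpers
# ----------------------------------------------------------------------


def _first_event_dates(events: pd.DataFrame) -> pd.Series:
    if events.empty:
        return pd.Series(dtype="datetime64[ns]")
    return events.groupby("patient_id")["date"].min()


def classify_prevention(patient_id, reference_date, event_table) -> str:
    """``secondary`` iff the patient has a cardiovascular event strictly
    before the reference date, else ``primary``."""
    ev = event_table[event_table["patient_id"] == patient_id]
    ref = pd.Timestamp(reference_date)
    if (pd.to_datetime(ev["date"]) < ref).any():
        return "secondary"
    return "primary"


def _exact_age(dates: pd.Series, birth_year: pd.Series) -> np.ndarray:
    """Age in exact years from a mid-year (July 1) date of birth."""
    dob = pd.to_datetime({"year": birth_year, "month": 7, "day": 1})
    return (pd.to_datetime(dates).to_numpy() - dob.to_numpy()) / np.timedelta64(1, "D") / 365.25


def _month_range(cfg: CohortConfig, grace_days: int) -> pd.DataFrame:
    """Study months whose grace window is fully observable.

    A trailing month is dropped when a grace window opening on its last
    day would extend past the study end."""
    months = []
    y, m = cfg.study_start.year, cfg.study_start.month
    while (y, m) <= (cfg.study_end.year, cfg.study_end.month):
        last = date(y, m, calendar.monthrange(y, m)[1])
        if last + timedelta(days=grace_days) <= cfg.study_end:
            months.append((y, m))
        else:
            log.info("dropping trailing month %04d-%02d: grace window unobservable", y, m)
        m += 1
        if m == 13:
            y, m = y + 1, 1
    return pd.DataFrame(months, columns=["year", "month"])


def _to_series(units: pd.DataFrame, months: pd.DataFrame, stratum=None, **meta) -> MonthlySeries:
    """Aggregate unit-level rows (year, month, outcome, [stratum]) to counts."""
    keys = ["year", "month"] + ([stratum] if stratum else [])
    if units.empty:
        agg = pd.DataFrame(columns=keys + ["denominator", "numerator"])
    else:
        agg = (
            units.groupby(keys)
            .agg(denominator=("outcome", "size"), numerator=("outcome", "sum"))
            .reset_index()
        )
    if stratum:
        labels = sorted(units[stratum].dropna().unique()) if not units.empty else []
        if not labels:
            raise ValueError("no populated strata in the input window")
        grid = months.merge(pd.DataFrame({stratum: labels}), how="cross")
        agg = grid.merge(agg, on=keys, how="left").rename(columns={stratum: "stratum"})
    else:
        agg = months.merge(agg, on=keys, how="left")
    for c in ("denominator", "numerator"):
        agg[c] = pd.to_numeric(agg[c], errors="coerce").fillna(0).astype(int)
    return MonthlySeries(agg, **meta)


# ----------------------------------------------------------------------
# initiation
# ----------------------------------------------------------------------


def _first_statin_issue(episodes: pd.DataFrame) -> pd.Series:
    if episodes.empty:
        return pd.Series(dtype="datetime64[ns]")
    return episodes.groupby("patient_id")["start_date"].min()


def build_initiation_series(
    tables, config: CohortConfig, prevention: str, codes=None
) -> MonthlySeries:
    """Monthly proportion of newly eligible patients starting treatment.

    Primary prevention: indication is the first risk score at or above
    the threshold; 28-day grace.  Secondary: incident first
    cardiovascular event at least a year into follow-up; 60-day grace.
    The indexing month is the month of the indication.
    """
    if prevention not in ("primary", "secondary"):
        raise ValueError("prevention must be 'primary' or 'secondary'")
    cfg = config
    pts = tables.patients.set_index("patient_id")
    episodes = episodes_from_prescriptions(tables.prescriptions, codes)
    first_rx = _first_statin_issue(episodes)
    first_ev = _first_event_dates(tables.events)

    if prevention == "primary":
        grace = cfg.initiation_grace_primary_days
        sc = tables.risk_scores
        qual = sc[sc["score"] >= cfg.risk_threshold]
        ind = qual.groupby("patient_id")["date"].min().rename("indication")
    else:
        grace = cfg.initiation_grace_secondary_days
        ind = first_ev.rename("indication")

    df = ind.reset_index().merge(
        pts[["birth_year", "registration_start", "followup_end", "death_date"]],
        left_on="patient_id",
        right_index=True,
    )
    df["first_rx"] = df["patient_id"].map(first_rx)
    df["first_ev"] = df["patient_id"].map(first_ev)

    start = pd.Timestamp(cfg.study_start)
    grace_end = df["indication"] + pd.Timedelta(days=grace)

    ok = (df["indication"] >= start) & (df["indication"] <= pd.Timestamp(cfg.study_end))
    ok &= _exact_age(df["indication"], df["birth_year"]) > cfg.min_age
    ok &= (df["indication"] - df["registration_start"]).dt.days >= cfg.min_registration_days
    # treatment-naive at the indication
    ok &= df["first_rx"].isna() | (df["first_rx"] >= df["indication"])
    # alive and registered through the full grace window
    ok &= df["followup_end"] >= grace_end
    if prevention == "primary":
        # event-free before and throughout the grace window
        ok &= df["first_ev"].isna() | (df["first_ev"] > grace_end)
    else:
        # incident events only: at least a year after follow-up start
        ok &= (df["indication"] - df["registration_start"]).dt.days >= 365

    df = df[ok].copy()
    df["outcome"] = (
        df["first_rx"].notna()
        & (df["first_rx"] >= df["indication"])
        & ((df["first_rx"] - df["indication"]).dt.days <= grace)
    ).astype(int)
    df["year"] = df["indication"].dt.year
    df["month"] = df["indication"].dt.month

    months = _month_range(cfg, grace)
    units = df.merge(months, on=["year", "month"])  # drop trailing months
    return _to_series(
        units, months, outcome="initiation", prevention=prevention, grace_days=grace
    )


# ----------------------------------------------------------------------
# cessation
# ----------------------------------------------------------------------


def _cessation_units(tables, cfg: CohortConfig, codes=None) -> pd.DataFrame:
    """Episode-level table with outcome and covariates, before prevention split."""
    episodes = episodes_from_prescriptions(tables.prescriptions, codes)
    if episodes.empty:
        return episodes.assign(outcome=[], prevention=[])
    pts = tables.patients.set_index("patient_id")
    first_ev = _first_event_dates(tables.events)
    grace = cfg.cessation_grace_days

    ep = episodes.copy()
    ep["birth_year"] = ep["patient_id"].map(pts["birth_year"])
    ep["registration_start"] = ep["patient_id"].map(pts["registration_start"])
    ep["followup_end"] = ep["patient_id"].map(pts["followup_end"])
    ep["diabetes_date"] = ep["patient_id"].map(pts["diabetes_date"])
    ep["sex"] = ep["patient_id"].map(pts["sex"])
    ep["first_ev"] = ep["patient_id"].map(first_ev)

    n0 = len(ep)
    grace_end = ep["end_date"] + pd.Timedelta(days=grace)
    keep = (ep["end_date"] >= pd.Timestamp(cfg.study_start)) & (
        ep["end_date"] <= pd.Timestamp(cfg.study_end)
    )
    keep &= _exact_age(ep["end_date"], ep["birth_year"]) > cfg.min_age
    keep &= ep["followup_end"] >= grace_end  # alive, under follow-up through grace
    ep = ep[keep].copy()
    log.info("cessation: %d of %d episodes eligible", len(ep), n0)

    # next further statin issue after this episode's own issue date
    nxt = []
    for pid, g in ep.assign(orig=np.arange(len(ep))).groupby("patient_id"):
        issues = episodes.loc[episodes["patient_id"] == pid, "start_date"].sort_values().to_numpy()
        for start, orig in zip(g["start_date"].to_numpy(), g["orig"].to_numpy()):
            later = issues[issues > start]
            nxt.append((orig, later.min() if len(later) else np.datetime64("NaT")))
    nxt.sort()
    ep["next_issue"] = pd.to_datetime([v for _, v in nxt])

    gap = (ep["next_issue"] - ep["end_date"]).dt.days
    ep["outcome"] = (ep["next_issue"].isna() | (gap > grace)).astype(int)

    # prevention status at the episode end; same-day events exclude from primary
    ev_before = ep["first_ev"].notna() & (ep["first_ev"] < ep["end_date"])
    ev_in_window = ep["first_ev"].notna() & (ep["first_ev"] >= ep["end_date"]) & (
        ep["first_ev"] <= ep["end_date"] + pd.Timedelta(days=grace)
    )
    ep["prevention"] = np.where(ev_before, "secondary", "primary")
    dropped = int((ev_in_window & ~ev_before).sum())
    if dropped:
        log.info("cessation: %d primary episodes dropped (event inside grace window)", dropped)
    ep = ep[~(ev_in_window & (ep["prevention"] == "primary"))].copy()

    ep["year"] = ep["end_date"].dt.year
    ep["month"] = ep["end_date"].dt.month
    return ep


def build_cessation_series(
    tables, config: CohortConfig, prevention: str, codes=None
) -> MonthlySeries:
    """Monthly proportion of ending prescription episodes not renewed
    within the grace period."""
    if prevention not in ("primary", "secondary"):
        raise ValueError("prevention must be 'primary' or 'secondary'")
    ep = _cessation_units(tables, config, codes)
    months = _month_range(config, config.cessation_grace_days)
    units = ep[ep["prevention"] == prevention].merge(months, on=["year", "month"])
    return _to_series(
        units,
        months,
        outcome="cessation",
        prevention=prevention,
        grace_days=config.cessation_grace_days,
    )


# ----------------------------------------------------------------------
# stratification
# ----------------------------------------------------------------------


def _duration_category(days: float, cuts) -> str:
    for c, lab in zip(cuts, DURATION_CATEGORIES):
        if days <= c:
            return lab
    return DURATION_CATEGORIES[-1]


def _continuous_duration(ep_all: pd.DataFrame, grace: int) -> pd.DataFrame:
    """Chain start date for each episode: the first issue of the unbroken
    run of episodes (no gap above ``grace`` days between the running
    maximum end date and the next issue)."""
    out = ep_all.sort_values(["patient_id", "start_date"]).reset_index()
    chain_start = np.empty(len(out), dtype="datetime64[ns]")
    for _, g in out.groupby("patient_id"):
        run_end = None
        cs = None
        for i in g.index:
            s, e = out.at[i, "start_date"], out.at[i, "end_date"]
            if run_end is None or (s - run_end).days > grace:
                cs = s
                run_end = e
            else:
                run_end = max(run_end, e)
            chain_start[i] = cs
    out["chain_start"] = chain_start
    return out.set_index("index")[["chain_start"]]


def stratify_cessation(
    tables, config: CohortConfig, modifier: str, prevention: str = "primary", codes=None
) -> MonthlySeries:
    """Cessation series broken down by an effect modifier.

    ``modifier`` is one of ``age_group``, ``sex``, ``diabetes`` or
    ``duration`` (length of the previous continuous prescription; the
    duration analysis is restricted to episodes whose chain began at
    least a year after registration).
    """
    if modifier not in MODIFIERS:
        raise ValueError(f"modifier must be one of {MODIFIERS}")
    cfg = config
    ep = _cessation_units(tables, cfg, codes)
    ep = ep[ep["prevention"] == prevention].copy()

    if modifier == "age_group":
        age = _exact_age(ep["end_date"], ep["birth_year"])
        bins = [cfg.min_age, 50, 60, 70, 80, np.inf]
        ep["stratum_val"] = pd.cut(age, bins=bins, labels=AGE_GROUPS, right=False)
        ep["stratum_val"] = ep["stratum_val"].astype(str)
    elif modifier == "sex":
        ep["stratum_val"] = ep["sex"]
        ep = ep[ep["stratum_val"].isin(["M", "F"])]
    elif modifier == "diabetes":
        has = ep["diabetes_date"].notna() & (ep["diabetes_date"] <= ep["end_date"])
        ep["stratum_val"] = np.where(has, "diabetes", "no_diabetes")
    else:  # duration
        episodes = episodes_from_prescriptions(tables.prescriptions, codes)
        chain = _continuous_duration(episodes, cfg.cessation_grace_days)
        # align on (patient, start): recompute chains on the full episode table
        key = episodes[["patient_id", "start_date"]].copy()
        key["chain_start"] = chain["chain_start"].to_numpy()
        ep = ep.merge(key, on=["patient_id", "start_date"], how="left")
        ok = (ep["chain_start"] - ep["registration_start"]).dt.days >= 365
        n_dropped = int((~ok).sum())
        if n_dropped:
            log.info("duration stratification: %d episodes excluded (chain began <1y after registration)", n_dropped)
        ep = ep[ok].copy()
        days = (ep["end_date"] - ep["chain_start"]).dt.days
        ep["stratum_val"] = [
            _duration_category(d, cfg.duration_cutpoints) for d in days
        ]

    months = _month_range(cfg, cfg.cessation_grace_days)
    units = ep.merge(months, on=["year", "month"]).rename(columns={"stratum_val": "strat"})
    s = _to_series(
        units,
        months,
        stratum="strat",
        outcome="cessation",
        prevention=prevention,
        grace_days=cfg.cessation_grace_days,
        meta={"modifier": modifier},
    )
    return s


# ----------------------------------------------------------------------
# risk-score recording
# ----------------------------------------------------------------------


def _risk_category(score: float) -> str:
    if score < 10:
        return "lt10"
    if score < 20:
        return "10to20"
    if score < 30:
        return "20to30"
    return "ge30"


def build_risk_score_series(tables, config: CohortConfig, category: str = "any") -> MonthlySeries:
    """Monthly proportion of patients under follow-up with a risk score
    recorded in the given band (``any``, ``lt10``, ``10to20``, ``20to30``,
    ``ge30``; bands are closed on the left: 20.0 falls in ``20to30``)."""
    if category not in RISK_CATEGORIES:
        raise ValueError(f"category must be one of {RISK_CATEGORIES}")
    cfg = config
    months = _month_range(cfg, 0)
    pts = tables.patients
    sc = tables.risk_scores.copy()
    if category != "any":
        sc = sc[[(_risk_category(v) == category) for v in sc["score"]]]
    sc = sc.assign(year=sc["date"].dt.year, month=sc["date"].dt.month)
    num = (
        sc.groupby(["year", "month"])["patient_id"].nunique().rename("numerator").reset_index()
    )

    rows = []
    reg = pts["registration_start"].to_numpy()
    fue = pts["followup_end"].to_numpy()
    for y, m in months.itertuples(index=False):
        first = np.datetime64(date(y, m, 1))
        last = np.datetime64(date(y, m, calendar.monthrange(y, m)[1]))
        den = int(((reg <= last) & (fue >= first)).sum())
        rows.append((y, m, den))
    df = pd.DataFrame(rows, columns=["year", "month", "denominator"])
    df = df.merge(num, on=["year", "month"], how="left").fillna({"numerator": 0})
    df["numerator"] = np.minimum(df["numerator"].astype(int), df["denominator"])
    return MonthlySeries(df, outcome=f"risk_score_{category}", meta={"category": category})
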