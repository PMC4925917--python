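from datetime import date

import pandas as pd
import pytest

from rxits.simulate import PopulationTables


def make_tables(patients, prescriptions=(), scores=(), events=()):
    """Hand-built record tables for boundary fixtures.

    patients: (pid, sex, birth_year, reg_start, followup_end, death, diabetes)
    prescriptions: (pid, drug_code, issue_date, quantity, daily_dose)
    scores: (pid, date, score)
    events: (pid, date, category)
    """
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
        list(prescriptions),
        columns=["patient_id", "drug_code", "issue_date", "quantity", "daily_dose"],
    )
    rs = pd.DataFrame(list(scores), columns=["patient_id", "date", "score"])
    ev = pd.DataFrame(list(events), columns=["patient_id", "date", "category"])
    for df, cols in (
        (pt, ["registration_start", "followup_end", "death_date", "diabetes_date"]),
        (rx, ["issue_date"]),
        (rs, ["date"]),
        (ev, ["date"]),
    ):
        for c in cols:
            df[c] = pd.to_datetime(df[c])
    return PopulationTables(pt, rx, rs, ev)


def patient(pid, birth_year=1950, reg=date(2005, 1, 1), end=date(2016, 1, 1),
            sex="F", death=None, diabetes=None):
    return (pid, sex, birth_year, reg, end, death, diabetes)


@pytest.fixture(scope="session")
def sim_tables():
    """A moderately sized synthetic population with a cessation step."""
    import numpy as np

    from rxits.simulate import PopulationSimConfig, generate_population

    cfg = PopulationSimConfig(
        n_patients=6000, seed=42, cease_step_log_or=float(np.log(1.5))
    )
    return generate_population(cfg)
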