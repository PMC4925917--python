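"""Table schemas, validated readers, run configuration and the pipeline.

The interchange dialect is CSV with ISO-8601 dates and a header row.
Four record tables feed the cohort engine:

``patients``
    patient_id, sex (M/F), birth_year, registration_start, followup_end,
    death_date (optional), diabetes_date (optional)
``prescriptions``
    patient_id, drug_code, issue_date, quantity, daily_dose (optional)
``risk_scores``
    patient_id, date, score (percent 10-year cardiovascular risk)
``events``
    patient_id, date, category

Drug code lists are newline-delimited text files of opaque code strings.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    CohortConfig,
    build_cessation_series,
    build_initiation_series,
    build_risk_score_series,
    stratify_cessation,
)
from .impact import ImpactParams, impact_report
from .its import SegmentedBinomialITS
from .series import MonthlySeries
from .simulate import PopulationSimConfig, PopulationTables, generate_population
from .strata import fit_interaction

__all__ = [
    "SCHEMAS",
    "SchemaError",
    "read_tables",
    "read_code_list",
    "write_code_list",
    "RunConfig",
    "run_pipeline",
]

log = logging.getLogger("rxits.io")

SCHEMAS = {
    "patients": {
        "patient_id": "int",
        "sex": "str",
        "birth_year": "int",
        "registration_start": "date",
        "followup_end": "date",
        "death_date": "date?",
        "diabetes_date": "date?",
    },
    "prescriptions": {
        "patient_id": "int",
        "drug_code": "str",
        "issue_date": "date",
        "quantity": "float",
        "daily_dose": "float?",
    },
    "risk_scores": {"patient_id": "int", "date": "date", "score": "float"},
    "events": {"patient_id": "int", "date": "date", "category": "str"},
}


class SchemaError(ValueError):
    """A table violates its documented schema."""


def _parse_column(df: pd.DataFrame, name: str, col: str, kind: str, path) -> None:
    optional = kind.endswith("?")
    kind = kind.rstrip("?")
    if kind == "date":
        raw = df[col]
        parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
        bad = parsed.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise SchemaError(
                f"{path}: unparseable date {raw.iloc[row]!r} in column {col!r} at row {row + 2}"
            )
        if not optional and parsed.isna().any():
            row = int(np.flatnonzero(parsed.isna())[0])
            raise SchemaError(f"{path}: missing required date in {col!r} at row {row + 2}")
        df[col] = parsed
    elif kind in ("int", "float"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        if not optional and parsed.isna().any():
            row = int(np.flatnonzero(parsed.isna())[0])
            raise SchemaError(f"{path}: non-numeric value in {col!r} at row {row + 2}")
        df[col] = parsed.astype("int64" if kind == "int" and not optional else float)


def _validate(df: pd.DataFrame, name: str, path, strict: bool) -> pd.DataFrame:
    schema = SCHEMAS[name]
    missing = [c for c in schema if not c.endswith("?") and c not in df.columns]
    # optional columns may be absent entirely
    required = [c for c, k in schema.items() if not k.endswith("?")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: table {name!r} missing columns {missing}")
    for col, kind in schema.items():
        if col not in df.columns:
            df[col] = pd.NaT if kind.startswith("date") else np.nan
            continue
        _parse_column(df, name, col, kind, path)
    return df


def read_tables(paths: dict | str | Path, strict: bool = False) -> PopulationTables:
    """Read and validate the four record tables.

    ``paths`` is a directory containing ``<name>.csv`` files or a mapping
    of table name to path.  Duplicate patient ids in the patient table
    are a schema error; rows in the other tables referencing unknown
    patients are dropped with a logged count (or raise in strict mode).
    """
    if not isinstance(paths, dict):
        d = Path(paths)
        paths = {name: d / f"{name}.csv" for name in SCHEMAS}
    frames = {}
    for name in SCHEMAS:
        p = Path(paths[name])
        df = pd.read_csv(p)
        frames[name] = _validate(df, name, p, strict)
        log.info("read %s: %d rows", p, len(df))
    pts = frames["patients"]
    dup = pts["patient_id"].duplicated()
    if dup.any():
        row = int(np.flatnonzero(dup)[0])
        raise SchemaError(
            f"{paths['patients']}: duplicate patient_id {pts['patient_id'].iloc[row]} at row {row + 2}"
        )
    known = set(pts["patient_id"])
    for name in ("prescriptions", "risk_scores", "events"):
        df = frames[name]
        orphan = ~df["patient_id"].isin(known)
        if orphan.any():
            if strict:
                row = int(np.flatnonzero(orphan)[0])
                raise SchemaError(
                    f"{paths[name]}: unknown patient_id "
                    f"{df['patient_id'].iloc[row]} at row {row + 2}"
                )
            log.warning("%s: dropped %d rows with unknown patient ids", name, int(orphan.sum()))
            frames[name] = df[~orphan].reset_index(drop=True)
    return PopulationTables(
        frames["patients"], frames["prescriptions"], frames["risk_scores"], frames["events"]
    )


def read_code_list(path) -> set:
    """Newline-delimited drug code list (blank lines and # comments ignored)."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def write_code_list(codes, path) -> None:
    Path(path).write_text("\n".join(sorted(codes)) + "\n")


# ----------------------------------------------------------------------
# run configuration and pipeline
# ----------------------------------------------------------------------


def _as_date(v) -> date:
    if isinstance(v, date):
        return v
    return date.fromisoformat(str(v))


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    outdir: str = "rxits_output"
    seed: int = 0
    tables_dir: str | None = None  # read tables from here instead of simulating
    simulation: dict = field(default_factory=dict)  # PopulationSimConfig overrides
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides
    model_form: str = "step_only"
    modifiers: tuple = ("age_group", "sex", "diabetes", "duration")
    impact: dict = field(default_factory=dict)  # ImpactParams overrides
    codes: str | None = None  # drug code list path
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def cohort_config(self) -> CohortConfig:
        kw = dict(self.cohort)
        for k in ("study_start", "study_end", "exposure_start", "exposure_end"):
            if k in kw:
                kw[k] = _as_date(kw[k])
        return CohortConfig(**kw)

    def population_config(self) -> PopulationSimConfig:
        kw = dict(self.simulation)
        for k in ("study_start", "study_end", "exposure_start", "exposure_end"):
            if k in kw:
                kw[k] = _as_date(kw[k])
        kw.setdefault("seed", self.seed)
        cc = self.cohort_config()
        kw.setdefault("study_start", cc.study_start)
        kw.setdefault("study_end", cc.study_end)
        kw.setdefault("exposure_start", cc.exposure_start)
        kw.setdefault("exposure_end", cc.exposure_end)
        return PopulationSimConfig(**kw)

    def impact_params(self) -> ImpactParams:
        return ImpactParams(**self.impact)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (date, pd.Timestamp)):
        return str(o)[:10]
    if isinstance(o, tuple):
        return list(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """simulate/read -> cohorts -> fits -> stratified analysis -> impact.

    Deterministic given the config seed.  Writes every artifact under
    ``config.outdir`` and returns the manifest (also written there).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "seed": config.seed,
        "outputs": [],
        "versions": _versions(),
    }
    stage = "setup"
    try:
        cc = config.cohort_config()
        codes = read_code_list(config.codes) if config.codes else None

        stage = "simulate"
        if config.tables_dir:
            tables = read_tables(config.tables_dir)
        else:
            tables = generate_population(config.population_config())
            paths = tables.write(out / "tables")
            manifest["outputs"] += [str(p) for p in paths.values()]

        stage = "cohorts"
        series: dict[str, MonthlySeries] = {
            "initiation_primary": build_initiation_series(tables, cc, "primary", codes),
            "initiation_secondary": build_initiation_series(tables, cc, "secondary", codes),
            "cessation_primary": build_cessation_series(tables, cc, "primary", codes),
            "cessation_secondary": build_cessation_series(tables, cc, "secondary", codes),
            "risk_score_any": build_risk_score_series(tables, cc, "any"),
        }
        for name, s in series.items():
            p = out / f"series_{name}.csv"
            s.to_csv(p)
            manifest["outputs"].append(str(p))

        stage = "fit"
        fits = {}
        post_split = {}
        for name, s in series.items():
            e0 = s.month_of(cc.exposure_start.year, cc.exposure_start.month)
            e1 = s.month_of(cc.exposure_end.year, cc.exposure_end.month)
            try:
                fits[name] = SegmentedBinomialITS(s, e0, e1, config.model_form).fit()
                if name.startswith("cessation"):
                    post_split[name] = SegmentedBinomialITS(s, e0, e1, "post_split_6m").fit()
            except ValueError as err:
                log.warning("fit skipped for %s: %s", name, err)
                continue
            _write_json(fits[name].to_report(), out / f"fit_{name}.json")
            fits[name].predict_curve().to_csv(out / f"curve_{name}.csv", index=False)
            manifest["outputs"] += [str(out / f"fit_{name}.json"), str(out / f"curve_{name}.csv")]

        stage = "stratify"
        for modifier in config.modifiers:
            try:
                strat = stratify_cessation(tables, cc, modifier, "primary", codes)
                e0 = strat.totals().month_of(cc.exposure_start.year, cc.exposure_start.month)
                e1 = strat.totals().month_of(cc.exposure_end.year, cc.exposure_end.month)
                res = fit_interaction(strat, e0, e1, modifier=modifier)
            except ValueError as err:
                log.warning("stratified fit skipped for %s: %s", modifier, err)
                continue
            strat.to_csv(out / f"series_cessation_primary_by_{modifier}.csv")
            _write_json(res.to_report(), out / f"interaction_{modifier}.json")
            res.forest_table().to_csv(out / f"forest_{modifier}.csv", index=False)
            manifest["outputs"] += [
                str(out / f"series_cessation_primary_by_{modifier}.csv"),
                str(out / f"interaction_{modifier}.json"),
                str(out / f"forest_{modifier}.csv"),
            ]

        stage = "impact"
        cess_fits = [post_split[k] for k in sorted(post_split)]
        if cess_fits:
            result = impact_report(cess_fits, config.impact_params())
            _write_json(result.to_report(), out / "impact.json")
            manifest["outputs"].append(str(out / "impact.json"))
    except Exception as err:
        manifest["failed_stage"] = stage
        manifest["error"] = str(err)
        _write_json(manifest, out / "manifest.json")
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err

    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], default=_json_default, sort_keys=True).encode()
    ).hexdigest()
    _write_json(manifest, out / "manifest.json")
    return manifest


def _versions() -> dict:
    import statsmodels

    from . import __version__

    return {
        "rxits": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
    }
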