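"""Per-encounter feature construction from the raw multi-table cohort.

Builds the modelling table: admission-history features (prior admission flag,
prior length of stay, counts and recency), surgery-history features,
vital-sign in-range flags, latest-lab-value columns with test counts, age,
and the carried-through raw categorical fields.  Filtering keeps adult
cardiac inpatient encounters from the modelling years while retaining the
excluded-year encounters in a history index so prior-admission features can
still look at them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_cohort import (
    CARDIAC_UNITS,
    RETAINED_ASSAYS,
    SOURCE_CATEGORY_LOOKUP,
    RawCohort,
)

__all__ = [
    "EngineeringConfig",
    "SchemaError",
    "filter_encounters",
    "derive_history_features",
    "derive_vital_flags",
    "derive_lab_features",
    "compute_age",
    "build_feature_table",
    "write_feature_table",
]


class SchemaError(ValueError):
    """A required column is absent from an input table."""


#: Default in-range windows per vital sign, overridable via config.
DEFAULT_VITAL_RANGES: dict[str, tuple[float, float]] = {
    "Temperature": (36.1, 37.2),
    "Heart Rate": (60.0, 100.0),
    "Respiratory Rate": (12.0, 18.0),
    "Oxygen Saturation": (95.0, 100.0),
    "Systolic Blood Pressure": (90.0, 120.0),
    "Diastolic Blood Pressure": (60.0, 80.0),
}

TRAINING_YEARS = (2019, 2021, 2022)
MIN_AGE_YEARS = 14

CATEGORICAL_FEATURES = [
    "SEX", "ADMIT-TYPE", "ADMIT-MODE", "NURSE-UNIT", "SOURCE-CATEGORY",
]

HISTORY_COUNT_FEATURES = [
    "LAST-YEAR-ADMISSION-COUNT", "LAST-ADMISSION-DAYS", "LAST-SURGERY-DAYS",
]


@dataclass(frozen=True)
class EngineeringConfig:
    cardiac_units: tuple[str, ...] = CARDIAC_UNITS
    vital_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_VITAL_RANGES))
    retained_assays: tuple[str, ...] = RETAINED_ASSAYS
    training_years: tuple[int, ...] = TRAINING_YEARS
    min_age: int = MIN_AGE_YEARS
    source_category_lookup: dict[str, str] = field(
        default_factory=lambda: dict(SOURCE_CATEGORY_LOOKUP))

    def validate(self) -> None:
        for vital, (lo, hi) in self.vital_ranges.items():
            if lo > hi:
                raise ValueError(f"vital range for {vital!r} has low > high")


def _require(df: pd.DataFrame, cols: list[str], table: str) -> None:
    for col in cols:
        if col not in df.columns:
            raise SchemaError(f"{table} table is missing column {col!r}")


def compute_age(birth, arrival) -> int:
    """Completed calendar years between birth and arrival (floor)."""
    birth = pd.Timestamp(birth)
    arrival = pd.Timestamp(arrival)
    if arrival < birth:
        raise ValueError("arrival precedes birth")
    years = arrival.year - birth.year
    if (arrival.month, arrival.day) < (birth.month, birth.day):
        years -= 1
    return int(years)


def _ages(births: pd.Series, arrivals: pd.Series) -> pd.Series:
    b, a = pd.to_datetime(births), pd.to_datetime(arrivals)
    if (a < b).any():
        raise ValueError("arrival precedes birth for some encounter")
    years = a.dt.year - b.dt.year
    before_birthday = (a.dt.month * 100 + a.dt.day) < (b.dt.month * 100 + b.dt.day)
    return (years - before_birthday.astype(int)).astype(int)


def filter_encounters(
    cohort: RawCohort, config: EngineeringConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split encounters into (training set, history index).

    The training set keeps adult (age >= 14) cardiac-unit inpatient
    encounters discharged alive to home with arrival year in the modelling
    years.  The history index holds *all* encounters (training years and the
    excluded history-only years alike) so prior-admission features can be
    computed against it.
    """
    config = config or EngineeringConfig()
    config.validate()
    enc = cohort.encounters
    _require(enc, ["ENCNTR-ID", "PATIENT-ID", "NURSE-UNIT", "ENCOUNTER-TYPE",
                   "DISCHARGE-DISPOSITION", "DISCHARGE-TO-LOCATION",
                   "BIRTH-DT-TM", "ADMISSION-ARRIVE-DT-TM",
                   "ADMISSION-DISCH-DT-TM"], "encounters")
    history = enc.copy()
    if not len(enc):
        return enc.copy(), history
    arrive = pd.to_datetime(enc["ADMISSION-ARRIVE-DT-TM"])
    age = _ages(enc["BIRTH-DT-TM"], enc["ADMISSION-ARRIVE-DT-TM"])
    keep = (
        enc["NURSE-UNIT"].isin(config.cardiac_units)
        & (enc["ENCOUNTER-TYPE"] == "inpatient")
        & (enc["DISCHARGE-DISPOSITION"] == "Alive and discharge with approval")
        & (enc["DISCHARGE-TO-LOCATION"] == "Home")
        & (age >= config.min_age)
        & arrive.dt.year.isin(config.training_years)
    )
    training = enc.loc[keep].reset_index(drop=True)
    return training, history


def _floor_days(delta: pd.Series) -> pd.Series:
    return np.floor(delta.dt.total_seconds() / 86400.0)


def derive_history_features(
    training: pd.DataFrame,
    history: pd.DataFrame,
    surgeries: pd.DataFrame,
    prior_admissions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Admission- and surgery-history columns for each training encounter.

    Prior-admission dates come primarily from the chronologically previous
    admission of the same patient in the history index (ties on arrival
    timestamp broken by ascending encounter id).  Where a prior-admission
    table is supplied, its non-null rows take precedence and its null rows
    are repaired by that shift-by-one recalibration, so no
    ``HAS-PRIOR-ADMISSION = 1`` row is left without computable dates.
    Day deltas are floors of elapsed time; the last-year window is the
    half-open 365 days before arrival.
    """
    _require(history, ["ENCNTR-ID", "PATIENT-ID", "ADMISSION-ARRIVE-DT-TM",
                       "ADMISSION-DISCH-DT-TM"], "history")
    _require(surgeries, ["PATIENT-ID", "ARRIVE-DT-TM", "DISCH-DT-TM"], "surgeries")

    training = training.reset_index(drop=True)
    out = training[["ENCNTR-ID"]].copy()
    n = len(training)
    if n == 0:
        for col in ["HAS-PRIOR-ADMISSION", "PRIOR-LOS-DAYS",
                    "LAST-YEAR-ADMISSION-COUNT", "LAST-ADMISSION-DAYS",
                    "LAST-YEAR-LOS-MAX", "HAS-PRIOR-SURGERY",
                    "HAS-PRIOR-SURGERY-60-DAYS", "LAST-SURGERY-DAYS"]:
            out[col] = pd.Series(dtype=float)
        return out

    hist = history.copy()
    hist["_arrive"] = pd.to_datetime(hist["ADMISSION-ARRIVE-DT-TM"])
    hist["_disch"] = pd.to_datetime(hist["ADMISSION-DISCH-DT-TM"])
    hist = hist.sort_values(["PATIENT-ID", "_arrive", "ENCNTR-ID"])
    grp = hist.groupby("PATIENT-ID", sort=False)
    # shift-by-one recalibration: previous admission's dates per patient
    hist["_prior_arrive"] = grp["_arrive"].shift(1)
    hist["_prior_disch"] = grp["_disch"].shift(1)
    recal = hist.set_index("ENCNTR-ID")[["_prior_arrive", "_prior_disch"]]

    prior_arrive = recal["_prior_arrive"].reindex(training["ENCNTR-ID"]).values
    prior_disch = recal["_prior_disch"].reindex(training["ENCNTR-ID"]).values
    if prior_admissions is not None and len(prior_admissions):
        _require(prior_admissions, ["ENCNTR-ID", "PRIOR-ADMISSION-ARRIVE",
                                    "PRIOR-ADMISSION-DISCHARGE"], "prior_admissions")
        pa = prior_admissions.drop_duplicates("ENCNTR-ID").set_index("ENCNTR-ID")
        table_arrive = pd.to_datetime(
            pa["PRIOR-ADMISSION-ARRIVE"]).reindex(training["ENCNTR-ID"]).values
        table_disch = pd.to_datetime(
            pa["PRIOR-ADMISSION-DISCHARGE"]).reindex(training["ENCNTR-ID"]).values
        prior_arrive = np.where(pd.notna(table_arrive), table_arrive, prior_arrive)
        prior_disch = np.where(pd.notna(table_disch), table_disch, prior_disch)
    prior_arrive = pd.Series(pd.to_datetime(prior_arrive), index=training.index)
    prior_disch = pd.Series(pd.to_datetime(prior_disch), index=training.index)

    arrive = pd.to_datetime(training["ADMISSION-ARRIVE-DT-TM"]).reset_index(drop=True)
    has_prior = prior_arrive.notna().astype(int).values
    out["HAS-PRIOR-ADMISSION"] = has_prior
    prior_los = _floor_days(prior_disch - prior_arrive)
    out["PRIOR-LOS-DAYS"] = np.where(has_prior == 1, prior_los, np.nan)
    last_adm_days = _floor_days(arrive - prior_disch)
    out["LAST-ADMISSION-DAYS"] = np.where(has_prior == 1, last_adm_days, np.nan)

    # last-year counts from the history index, half-open window [t-365d, t)
    year_counts = np.zeros(n, dtype=float)
    year_los_max = np.full(n, np.nan)
    hist_by_pat = {pid: g for pid, g in hist.groupby("PATIENT-ID", sort=False)}
    pats = training["PATIENT-ID"].values
    enc_ids = training["ENCNTR-ID"].values
    for i in range(n):
        g = hist_by_pat.get(pats[i])
        if g is None:
            continue
        t = arrive.iloc[i]
        window = (g["_arrive"] >= t - pd.Timedelta(days=365)) & (g["_arrive"] < t)
        window &= g["ENCNTR-ID"].values != enc_ids[i]
        cnt = int(window.sum())
        year_counts[i] = cnt
        if cnt:
            in_win = g.loc[window]
            year_los_max[i] = np.floor(
                (in_win["_disch"] - in_win["_arrive"]).dt.total_seconds().max()
                / 86400.0)
    out["LAST-YEAR-ADMISSION-COUNT"] = year_counts
    out["LAST-YEAR-LOS-MAX"] = year_los_max

    # surgery features from the latest surgery discharged before arrival
    has_surg = np.zeros(n, dtype=int)
    last_surg_days = np.full(n, np.nan)
    surg = surgeries.copy()
    if len(surg):
        surg["_disch"] = pd.to_datetime(surg["DISCH-DT-TM"])
        surg_by_pat = {pid: g["_disch"].values for pid, g in
                       surg.groupby("PATIENT-ID", sort=False)}
        for i in range(n):
            dates = surg_by_pat.get(pats[i])
            if dates is None:
                continue
            t = np.datetime64(arrive.iloc[i])
            before = dates[dates <= t]
            if len(before):
                has_surg[i] = 1
                last = before.max()
                last_surg_days[i] = np.floor(
                    (t - last) / np.timedelta64(1, "s") / 86400.0)
    out["HAS-PRIOR-SURGERY"] = has_surg
    out["LAST-SURGERY-DAYS"] = last_surg_days
    out["HAS-PRIOR-SURGERY-60-DAYS"] = (
        (has_surg == 1) & (last_surg_days <= 60)).astype(int)
    return out


def derive_vital_flags(
    encounters: pd.DataFrame,
    vital_ranges: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Per-vital in-range flags: 1 iff low <= reading <= high, NaN if missing."""
    ranges = vital_ranges or DEFAULT_VITAL_RANGES
    for vital, (lo, hi) in ranges.items():
        if lo > hi:
            raise ValueError(f"vital range for {vital!r} has low > high")
    out = encounters[["ENCNTR-ID"]].copy() if "ENCNTR-ID" in encounters else pd.DataFrame(index=encounters.index)
    for vital, (lo, hi) in ranges.items():
        if vital not in encounters.columns:
            raise SchemaError(f"encounters table is missing column {vital!r}")
        vals = pd.to_numeric(encounters[vital], errors="coerce")
        flag = ((vals >= lo) & (vals <= hi)).astype(float)
        flag[vals.isna()] = np.nan
        out[f"{vital}-IN-RANGE"] = flag.values
    return out


def derive_lab_features(
    labs: pd.DataFrame,
    retained_assays: tuple[str, ...],
    arrivals: pd.DataFrame,
) -> pd.DataFrame:
    """Latest retained-assay values at/before arrival plus lab-count features.

    ``TASK-ASSAY-COUNT`` counts every lab row of the encounter (retained or
    not); ``LAST-MONTH-TASK-ASSAY-COUNT`` counts rows in the 30 days before
    arrival.
    """
    _require(arrivals, ["ENCNTR-ID", "ADMISSION-ARRIVE-DT-TM"], "arrivals")
    out = arrivals[["ENCNTR-ID"]].copy()
    n = len(out)
    for assay in retained_assays:
        out[f"LAB-{assay}"] = np.nan
    out["TASK-ASSAY-COUNT"] = 0.0
    out["LAST-MONTH-TASK-ASSAY-COUNT"] = 0.0
    if not len(labs) or n == 0:
        return out
    _require(labs, ["ENCNTR-ID", "TASK-ASSAY", "RESULT-VALUE-NUMERIC",
                    "RESULT-DT-TM"], "labs")
    lab = labs.copy()
    lab["_dt"] = pd.to_datetime(lab["RESULT-DT-TM"])
    arrive_map = pd.Series(
        pd.to_datetime(arrivals["ADMISSION-ARRIVE-DT-TM"]).values,
        index=arrivals["ENCNTR-ID"].values)
    lab = lab[lab["ENCNTR-ID"].isin(arrive_map.index)]
    lab["_arrive"] = lab["ENCNTR-ID"].map(arrive_map)

    counts = lab.groupby("ENCNTR-ID").size()
    month_counts = lab[
        (lab["_dt"] >= lab["_arrive"] - pd.Timedelta(days=30))
        & (lab["_dt"] < lab["_arrive"])
    ].groupby("ENCNTR-ID").size()
    out["TASK-ASSAY-COUNT"] = (
        out["ENCNTR-ID"].map(counts).fillna(0).astype(float).values)
    out["LAST-MONTH-TASK-ASSAY-COUNT"] = (
        out["ENCNTR-ID"].map(month_counts).fillna(0).astype(float).values)

    at_or_before = lab[lab["_dt"] <= lab["_arrive"]]
    retained = at_or_before[at_or_before["TASK-ASSAY"].isin(retained_assays)]
    retained = retained.dropna(subset=["RESULT-VALUE-NUMERIC"])
    if len(retained):
        latest = (retained.sort_values("_dt")
                  .groupby(["ENCNTR-ID", "TASK-ASSAY"]).last()["RESULT-VALUE-NUMERIC"])
        for assay in retained_assays:
            if assay in latest.index.get_level_values("TASK-ASSAY"):
                vals = latest.xs(assay, level="TASK-ASSAY")
                out[f"LAB-{assay}"] = out["ENCNTR-ID"].map(vals).values
    return out


def build_feature_table(
    cohort: RawCohort, config: EngineeringConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """Run the full engineering pipeline.

    Returns ``(features, metadata)`` where ``features`` has one row per
    filtered training encounter (target column ``LOS-DAYS`` included) and
    ``metadata`` records each feature's kind (categorical/numerical) and its
    missing-value rule group.
    """
    config = config or EngineeringConfig()
    training, history = filter_encounters(cohort, config)
    hist_feats = derive_history_features(
        training, history, cohort.surgeries, cohort.prior_admissions)
    vital_flags = derive_vital_flags(training, config.vital_ranges)
    lab_feats = derive_lab_features(
        cohort.labs, config.retained_assays, training)

    feats = training[["ENCNTR-ID", "PATIENT-ID"]].copy()
    if len(training):
        feats["AGE"] = _ages(training["BIRTH-DT-TM"],
                             training["ADMISSION-ARRIVE-DT-TM"]).values
        arrive = pd.to_datetime(training["ADMISSION-ARRIVE-DT-TM"])
        disch = pd.to_datetime(training["ADMISSION-DISCH-DT-TM"])
        feats["LOS-DAYS"] = np.floor(
            (disch - arrive).dt.total_seconds() / 86400.0).values
        feats["SOURCE-CATEGORY"] = (
            training["SOURCE-STRING"].map(config.source_category_lookup)
            .fillna("Other").values)
    else:
        feats["AGE"] = pd.Series(dtype=int)
        feats["LOS-DAYS"] = pd.Series(dtype=float)
        feats["SOURCE-CATEGORY"] = pd.Series(dtype=object)
    for col in ["SEX", "ADMIT-TYPE", "ADMIT-MODE", "NURSE-UNIT"]:
        feats[col] = training[col].values if len(training) else pd.Series(dtype=object)
    for vital in config.vital_ranges:
        feats[vital] = training[vital].values if len(training) else pd.Series(dtype=float)

    for block in (hist_feats, vital_flags, lab_feats):
        block = block.drop(columns=["ENCNTR-ID"], errors="ignore")
        for col in block.columns:
            feats[col] = block[col].values

    metadata = {"features": {}, "target": "LOS-DAYS",
                "id_columns": ["ENCNTR-ID", "PATIENT-ID"]}
    for col in feats.columns:
        if col in metadata["id_columns"] or col == "LOS-DAYS":
            continue
        entry = {"kind": "categorical" if col in CATEGORICAL_FEATURES else "numerical"}
        if col in HISTORY_COUNT_FEATURES:
            entry["impute"] = "zero"
        elif col.startswith("LAB-") or col.endswith("-IN-RANGE"):
            entry["impute"] = "minus_one"
        elif col in ("PRIOR-LOS-DAYS", "LAST-YEAR-LOS-MAX"):
            entry["impute"] = "zero"
        entry["los_related"] = col in ("PRIOR-LOS-DAYS", "LAST-YEAR-LOS-MAX")
        metadata["features"][col] = entry
    return feats, metadata


def write_feature_table(features: pd.DataFrame, metadata: dict,
                        out_csv: str | Path, out_meta: str | Path) -> None:
    features.to_csv(out_csv, index=False)
    Path(out_meta).write_text(json.dumps(metadata, indent=2, sort_keys=True))
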