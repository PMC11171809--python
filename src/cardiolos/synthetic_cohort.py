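"""Synthetic multi-table EHR-style cohort generator with planted structure.

Emulates the shape of a cardiac inpatient registry: an encounter table with
demographics, admission metadata and vital-sign readings; a long-format lab
table; a surgery-history table; and a prior-admission table.  Length of stay
is drawn from a lognormal-style model ``LOS = exp(intercept + Xb +
class_effect * class + noise)`` so the raw distribution is right-skewed and a
latent 4-level severity class carries real signal, which downstream cascade
classifiers can exploit.  The exact coefficients, per-encounter classes and
standardisation constants are retained in a sidecar truth record so tests can
do parameter recovery.

All randomness flows from a single ``numpy.random.Generator`` seeded from the
config; identical configs produce byte-identical CSV serialisations.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GeneratorConfig",
    "RawCohort",
    "ConfigError",
    "generate_cohort",
    "planted_truth",
    "write_cohort",
    "read_cohort",
    "SOURCE_CATEGORY_LOOKUP",
    "CARDIAC_UNITS",
    "ASSAY_NAMES",
    "RETAINED_ASSAYS",
]


class ConfigError(ValueError):
    """Raised for invalid generator configuration."""


# ---------------------------------------------------------------------------
# Categorical domains (cardinalities: SEX 2, ADMIT-TYPE 5, ADMIT-MODE 11,
# NURSE-UNIT 74, TASK-ASSAY 27).
# ---------------------------------------------------------------------------

SEX_LEVELS = ["F", "M"]
ADMIT_TYPES = ["Emergency", "Scheduled", "Direct admission", "Transfer", "Day case"]
ADMIT_MODES = [f"MODE-{i:02d}" for i in range(11)]
NURSE_UNITS = [f"UNIT-{i:02d}" for i in range(74)]
#: Units treated as cardiac wards by the default filter configuration.
CARDIAC_UNITS = tuple(f"UNIT-{i:02d}" for i in range(40))

ASSAY_NAMES = [
    "Hgb", "WBC", "Creat", "e-GFR", "Hgb A1c percent", "Na",
    "Pro-Brian Natriuretic Peptide", "Troponin-T", "RBC", "Urea", "K",
    "Cl", "Ca", "Mg", "Phos", "ALT", "AST", "ALP", "Bili Total", "Albumin",
    "Glucose", "Lactate", "CRP", "PT", "INR", "PTT", "Platelets",
]
assert len(ASSAY_NAMES) == 27
#: Clinically central assays whose latest value becomes a feature column.
RETAINED_ASSAYS = (
    "Hgb", "WBC", "Creat", "e-GFR", "Hgb A1c percent", "Na",
    "Pro-Brian Natriuretic Peptide", "Troponin-T",
)

#: High-cardinality admission-diagnosis strings grouped into 4 categories via
#: a fixed lookup (the grouping itself is supplied, not learned).
_SOURCE_GROUPS = {
    "Ischemic": ["Myocardial infarction", "Unstable angina", "NSTEMI", "STEMI",
                 "Coronary artery disease", "Ischemic cardiomyopathy"],
    "Structural": ["Mitral stenosis", "Aortic stenosis", "Mitral regurgitation",
                   "Aortic regurgitation", "Ventricular septal defect",
                   "Atrial septal defect"],
    "Arrhythmia": ["Bradycardia", "Atrial fibrillation", "Atrial flutter",
                   "Ventricular tachycardia", "Heart block", "SVT"],
    "Failure": ["Heart failure", "Cardiomyopathy", "Pulmonary edema",
                "Cardiogenic shock", "Myocarditis", "Pericardial effusion"],
}
SOURCE_CATEGORY_LOOKUP = {
    s: cat for cat, strings in _SOURCE_GROUPS.items() for s in strings
}
_SOURCE_STRINGS = sorted(SOURCE_CATEGORY_LOOKUP)

VITAL_COLUMNS = [
    "Oxygen Saturation", "Respiratory Rate", "Heart Rate",
    "Systolic Blood Pressure", "Diastolic Blood Pressure", "Temperature",
]

# (mean, sd, low clip, high clip) per vital; clips follow the registry ranges
_VITAL_MODEL = {
    "Oxygen Saturation": (96.0, 3.0, 20.0, 100.0),
    "Respiratory Rate": (16.0, 3.5, 10.0, 60.0),
    "Heart Rate": (82.0, 16.0, 20.0, 220.0),
    "Systolic Blood Pressure": (122.0, 18.0, 60.0, 237.0),
    "Diastolic Blood Pressure": (74.0, 12.0, 30.0, 157.0),
    "Temperature": (36.8, 0.45, 34.6, 39.5),
}

_DEFAULT_COEFFS = {
    "AGE": 0.15,
    "Heart Rate": 0.10,
    "Respiratory Rate": 0.08,
    "Oxygen Saturation": -0.08,
}

_DEFAULT_MISSINGNESS = {
    "labs.RESULT-VALUE-NUMERIC": 0.004,
    "prior_admissions.PRIOR-ADMISSION-ARRIVE": 0.285,
    "prior_admissions.PRIOR-ADMISSION-DISCHARGE": 0.285,
}

N_CLASSES = 4


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort generative model."""

    n_patients: int = 1000
    encounters_per_patient_mean: float = 1.4
    seed: int = 0
    los_log_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_COEFFS))
    noise_sd: float = 0.45
    intercept: float = 1.6
    class_effect: float = 0.35
    missingness: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MISSINGNESS))
    date_range: tuple[str, str] = ("2018-01-01", "2022-12-31")

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigError(f"n_patients must be >= 0, got {self.n_patients}")
        if self.encounters_per_patient_mean < 1:
            raise ConfigError("encounters_per_patient_mean must be >= 1")
        if not self.noise_sd > 0:
            raise ConfigError(f"noise_sd must be > 0, got {self.noise_sd}")
        for key, frac in self.missingness.items():
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(
                    f"missingness[{key!r}] must be in [0, 1], got {frac}")
        start, end = (pd.Timestamp(d) for d in self.date_range)
        if end <= start:
            raise ConfigError("date_range end must be after start")


ENCOUNTER_COLUMNS = [
    "ENCNTR-ID", "PATIENT-ID", "SEX", "BIRTH-DT-TM", "ADMIT-TYPE",
    "ADMIT-MODE", "NURSE-UNIT", "SOURCE-STRING", "ENCOUNTER-TYPE",
    "DISCHARGE-DISPOSITION", "DISCHARGE-TO-LOCATION",
    "ADMISSION-ARRIVE-DT-TM", "ADMISSION-DISCH-DT-TM",
] + VITAL_COLUMNS

LAB_COLUMNS = ["ENCNTR-ID", "TASK-ASSAY", "RESULT-VALUE-NUMERIC", "RESULT-DT-TM"]
SURGERY_COLUMNS = ["PATIENT-ID", "ARRIVE-DT-TM", "DISCH-DT-TM"]
PRIOR_COLUMNS = ["ENCNTR-ID", "PRIOR-ADMISSION-ARRIVE", "PRIOR-ADMISSION-DISCHARGE"]


@dataclass
class RawCohort:
    """Multi-table raw cohort: encounters, labs, surgeries, prior admissions."""

    encounters: pd.DataFrame
    labs: pd.DataFrame
    surgeries: pd.DataFrame
    prior_admissions: pd.DataFrame
    truth: dict | None = None

    def validate(self) -> None:
        for name, df, cols in (
            ("encounters", self.encounters, ENCOUNTER_COLUMNS),
            ("labs", self.labs, LAB_COLUMNS),
            ("surgeries", self.surgeries, SURGERY_COLUMNS),
            ("prior_admissions", self.prior_admissions, PRIOR_COLUMNS),
        ):
            missing = set(cols) - set(df.columns)
            if missing:
                raise ValueError(f"{name} table missing columns: {sorted(missing)}")
        enc_ids = set(self.encounters["ENCNTR-ID"])
        for name, df in (("labs", self.labs), ("prior_admissions", self.prior_admissions)):
            unknown = set(df["ENCNTR-ID"]) - enc_ids
            if unknown:
                raise ValueError(f"{name} references unknown encounters: {sorted(unknown)[:5]}")


def _empty_cohort() -> RawCohort:
    return RawCohort(
        encounters=pd.DataFrame(columns=ENCOUNTER_COLUMNS),
        labs=pd.DataFrame(columns=LAB_COLUMNS),
        surgeries=pd.DataFrame(columns=SURGERY_COLUMNS),
        prior_admissions=pd.DataFrame(columns=PRIOR_COLUMNS),
        truth={"classes": {}, "coefficients": {}, "standardization": {},
               "intercept": 0.0, "class_effect": 0.0, "seed": None},
    )


def generate_cohort(config: GeneratorConfig) -> RawCohort:
    """Generate a full cohort; deterministic given the config (incl. seed).

    LOS in fractional days is ``exp(intercept + sum_f coef_f * z_f +
    class_effect * class + eps)`` with ``eps ~ N(0, noise_sd)`` and ``z_f``
    the generation-time z-score of feature ``f``; the discharge timestamp is
    arrival plus that fractional stay.
    """
    config.validate()
    if config.n_patients == 0:
        cohort = _empty_cohort()
        cohort.truth["seed"] = config.seed
        return cohort

    rng = np.random.default_rng(config.seed)
    start, end = (pd.Timestamp(d) for d in config.date_range)
    span_days = (end - start).days

    n_pat = config.n_patients
    patient_ids = np.arange(1, n_pat + 1)
    # births: ages roughly 10-95 at mid-window so the age>=14 filter bites
    mid = start + (end - start) / 2
    ages = rng.uniform(10.0, 95.0, n_pat)
    births = mid - pd.to_timedelta(ages * 365.2425, unit="D")
    sexes = rng.choice(SEX_LEVELS, n_pat)

    n_enc_per_pat = 1 + rng.poisson(config.encounters_per_patient_mean - 1.0, n_pat)
    n_enc = int(n_enc_per_pat.sum())
    enc_patient = np.repeat(patient_ids, n_enc_per_pat)
    enc_birth = np.repeat(births.values, n_enc_per_pat)
    enc_sex = np.repeat(sexes, n_enc_per_pat)

    arrive = start + pd.to_timedelta(
        rng.uniform(0, span_days * 86400.0, n_enc), unit="s")
    arrive = pd.Series(arrive).dt.floor("min")
    # order encounters within patient chronologically for readability
    order = np.lexsort((arrive.values, enc_patient))
    enc_patient = enc_patient[order]
    enc_birth = enc_birth[order]
    enc_sex = enc_sex[order]
    arrive = arrive.iloc[order].reset_index(drop=True)
    enc_ids = np.arange(100001, 100001 + n_enc)

    # latent 4-level severity class; tilts several observables
    classes = rng.choice(N_CLASSES, n_enc, p=[0.3, 0.3, 0.25, 0.15])

    admit_type_probs = np.array([
        [0.15, 0.45, 0.20, 0.10, 0.10],
        [0.25, 0.35, 0.20, 0.10, 0.10],
        [0.45, 0.20, 0.15, 0.15, 0.05],
        [0.60, 0.10, 0.10, 0.18, 0.02],
    ])
    admit_type = np.array([
        rng.choice(ADMIT_TYPES, p=admit_type_probs[c]) for c in classes])
    admit_mode = rng.choice(ADMIT_MODES, n_enc)
    # cardiac units dominate; severity pushes toward the first (ICU-like) units
    unit_idx = np.minimum(
        rng.integers(0, len(NURSE_UNITS), n_enc),
        rng.integers(0, 30, n_enc) + (3 - classes) * 8,
    )
    nurse_unit = np.array(NURSE_UNITS)[unit_idx]
    source_probs = np.array([
        [0.30, 0.35, 0.25, 0.10],
        [0.30, 0.25, 0.30, 0.15],
        [0.30, 0.15, 0.25, 0.30],
        [0.25, 0.10, 0.15, 0.50],
    ])
    group_names = list(_SOURCE_GROUPS)
    source_string = np.empty(n_enc, dtype=object)
    for i, c in enumerate(classes):
        grp = rng.choice(group_names, p=source_probs[c])
        source_string[i] = _SOURCE_GROUPS[grp][rng.integers(len(_SOURCE_GROUPS[grp]))]

    encounter_type = rng.choice(
        ["inpatient", "outpatient"], n_enc, p=[0.92, 0.08])
    disposition = rng.choice(
        ["Alive and discharge with approval", "Discharged against advice", "Deceased"],
        n_enc, p=[0.9, 0.06, 0.04])
    discharge_to = rng.choice(
        ["Home", "Other facility"], n_enc, p=[0.92, 0.08])

    vitals = {}
    for v, (mu, sd, lo, hi) in _VITAL_MODEL.items():
        shift = {"Heart Rate": 4.0, "Respiratory Rate": 1.0,
                 "Oxygen Saturation": -0.8}.get(v, 0.0)
        vals = rng.normal(mu + shift * classes, sd, n_enc)
        vitals[v] = np.clip(np.round(vals, 1), lo, hi)

    age_years = (arrive.values - enc_birth) / np.timedelta64(1, "s") / (86400 * 365.2425)
    age_years = np.floor(age_years)

    feature_values = {"AGE": age_years, "SEX": (enc_sex == "M").astype(float)}
    feature_values.update(vitals)

    # linear predictor on z-scored planted features
    linpred = np.full(n_enc, config.intercept, dtype=float)
    standardization: dict[str, list[float]] = {}
    for fname, coef in config.los_log_coefficients.items():
        if fname not in feature_values:
            raise ConfigError(f"unknown planted feature {fname!r}")
        col = np.asarray(feature_values[fname], dtype=float)
        mu, sd = float(col.mean()), float(col.std())
        sd = sd if sd > 0 else 1.0
        standardization[fname] = [mu, sd]
        linpred += coef * (col - mu) / sd
    linpred += config.class_effect * classes
    noise = rng.normal(0.0, config.noise_sd, n_enc)
    los_frac_days = np.exp(linpred + noise)
    discharge = arrive + pd.to_timedelta(
        np.round(los_frac_days * 86400.0), unit="s")

    encounters = pd.DataFrame({
        "ENCNTR-ID": enc_ids,
        "PATIENT-ID": enc_patient,
        "SEX": enc_sex,
        "BIRTH-DT-TM": pd.Series(enc_birth).dt.floor("D"),
        "ADMIT-TYPE": admit_type,
        "ADMIT-MODE": admit_mode,
        "NURSE-UNIT": nurse_unit,
        "SOURCE-STRING": source_string,
        "ENCOUNTER-TYPE": encounter_type,
        "DISCHARGE-DISPOSITION": disposition,
        "DISCHARGE-TO-LOCATION": discharge_to,
        "ADMISSION-ARRIVE-DT-TM": arrive,
        "ADMISSION-DISCH-DT-TM": discharge,
        **vitals,
    })[ENCOUNTER_COLUMNS]

    # ------------------------------------------------------------------ labs
    n_labs_per_enc = rng.poisson(5.0 + 2.0 * classes)
    lab_enc = np.repeat(enc_ids, n_labs_per_enc)
    lab_arrive = np.repeat(arrive.values, n_labs_per_enc)
    n_labs = int(n_labs_per_enc.sum())
    lab_assay = rng.choice(ASSAY_NAMES, n_labs)
    lab_value = np.round(np.abs(rng.normal(50.0, 30.0, n_labs)), 2)
    lab_offset_days = rng.uniform(0.0, 45.0, n_labs)
    lab_dt = pd.Series(lab_arrive) - pd.to_timedelta(
        np.round(lab_offset_days * 86400.0), unit="s")
    labs = pd.DataFrame({
        "ENCNTR-ID": lab_enc,
        "TASK-ASSAY": lab_assay,
        "RESULT-VALUE-NUMERIC": lab_value,
        "RESULT-DT-TM": lab_dt,
    })
    frac = config.missingness.get("labs.RESULT-VALUE-NUMERIC", 0.0)
    if frac > 0 and n_labs:
        mask = rng.random(n_labs) < frac
        labs.loc[mask, "RESULT-VALUE-NUMERIC"] = np.nan

    # ------------------------------------------------------------- surgeries
    has_surgery = rng.random(n_pat) < 0.35
    surg_patients = patient_ids[has_surgery]
    n_surg = len(surg_patients)
    surg_arrive = start + pd.to_timedelta(
        rng.uniform(0, span_days * 86400.0, n_surg), unit="s")
    surg_arrive = pd.Series(surg_arrive).dt.floor("min")
    surg_disch = surg_arrive + pd.to_timedelta(
        np.round(rng.uniform(0.5, 10.0, n_surg) * 86400.0), unit="s")
    surgeries = pd.DataFrame({
        "PATIENT-ID": surg_patients,
        "ARRIVE-DT-TM": surg_arrive,
        "DISCH-DT-TM": surg_disch,
    })

    # ------------------------------------------------- prior admission table
    enc_sorted = encounters.sort_values(
        ["PATIENT-ID", "ADMISSION-ARRIVE-DT-TM", "ENCNTR-ID"])
    grp = enc_sorted.groupby("PATIENT-ID", sort=False)
    prior_arrive = grp["ADMISSION-ARRIVE-DT-TM"].shift(1)
    prior_disch = grp["ADMISSION-DISCH-DT-TM"].shift(1)
    prior = pd.DataFrame({
        "ENCNTR-ID": enc_sorted["ENCNTR-ID"].values,
        "PRIOR-ADMISSION-ARRIVE": prior_arrive.values,
        "PRIOR-ADMISSION-DISCHARGE": prior_disch.values,
    })
    # only encounters that actually have a prior admission appear; injected
    # nulls are then the table's entire missingness, repairable downstream
    prior = prior[prior["PRIOR-ADMISSION-ARRIVE"].notna()]
    prior = prior.sort_values("ENCNTR-ID").reset_index(drop=True)
    for col in ("PRIOR-ADMISSION-ARRIVE", "PRIOR-ADMISSION-DISCHARGE"):
        frac = config.missingness.get(f"prior_admissions.{col}", 0.0)
        if frac > 0:
            mask = rng.random(len(prior)) < frac
            prior.loc[mask, col] = pd.NaT

    truth = {
        "seed": config.seed,
        "classes": {int(e): int(c) for e, c in zip(enc_ids, classes)},
        "coefficients": dict(config.los_log_coefficients),
        "intercept": config.intercept,
        "class_effect": config.class_effect,
        "noise_sd": config.noise_sd,
        "standardization": standardization,
    }
    cohort = RawCohort(encounters, labs, surgeries, prior, truth=truth)
    cohort.validate()
    return cohort


def planted_truth(cohort: RawCohort) -> dict:
    """Return the hidden generative record attached by :func:`generate_cohort`."""
    if cohort.truth is None:
        raise ValueError("cohort carries no planted truth record "
                         "(was it produced by generate_cohort?)")
    return cohort.truth


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_TABLE_FILES = {
    "encounters": "encounters.csv",
    "labs": "labs.csv",
    "surgeries": "surgeries.csv",
    "prior_admissions": "prior_admissions.csv",
}

_DATETIME_COLUMNS = {
    "encounters": ["BIRTH-DT-TM", "ADMISSION-ARRIVE-DT-TM", "ADMISSION-DISCH-DT-TM"],
    "labs": ["RESULT-DT-TM"],
    "surgeries": ["ARRIVE-DT-TM", "DISCH-DT-TM"],
    "prior_admissions": ["PRIOR-ADMISSION-ARRIVE", "PRIOR-ADMISSION-DISCHARGE"],
}


def write_cohort(cohort: RawCohort, out_dir: str | Path) -> None:
    """Write one CSV per table (ISO-8601 datetimes) plus a truth.json sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for attr, fname in _TABLE_FILES.items():
        df = getattr(cohort, attr).copy()
        for col in _DATETIME_COLUMNS[attr]:
            if len(df):
                df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%dT%H:%M:%S")
        df.to_csv(out / fname, index=False)
    if cohort.truth is not None:
        (out / "truth.json").write_text(json.dumps(cohort.truth, sort_keys=True))


def read_cohort(in_dir: str | Path) -> RawCohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    src = Path(in_dir)
    tables = {}
    for attr, fname in _TABLE_FILES.items():
        df = pd.read_csv(src / fname)
        for col in _DATETIME_COLUMNS[attr]:
            df[col] = pd.to_datetime(df[col])
        tables[attr] = df
    truth_path = src / "truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else None
    if truth is not None:
        truth["classes"] = {int(k): v for k, v in truth["classes"].items()}
    return RawCohort(truth=truth, **tables)


def config_to_dict(config: GeneratorConfig) -> dict:
    d = dataclasses.asdict(config)
    d["date_range"] = list(d["date_range"])
    return d
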