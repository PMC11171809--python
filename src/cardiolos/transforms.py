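"""Statistical preprocessing: log transform, IQR winsorization, min-max
scaling, dummy encoding, rule-based imputation and quantile target binning.

Every fit/apply transform derives its parameters exclusively from the data
handed to ``fit`` (the leakage contract); fitted parameters serialize to
plain JSON for exact reapplication.  Quantiles use linear interpolation
between order statistics throughout.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "log_transform",
    "inverse_log_transform",
    "iqr_winsorize",
    "Winsorizer",
    "MinMaxScalerDF",
    "DummyEncoder",
    "impute_missing",
    "bin_target_qcut",
    "assign_classes",
    "TargetBundle",
]


def log_transform(values):
    """Monotone skew-reducing map ``x -> ln(1 + x)``; domain ``x >= 0``."""
    arr = np.asarray(values, dtype=float)
    if np.any(arr[np.isfinite(arr)] < 0):
        raise ValueError("log_transform requires nonnegative values")
    return np.log1p(arr)


def inverse_log_transform(values):
    return np.expm1(np.asarray(values, dtype=float))


def _fences_and_caps(arr: np.ndarray) -> dict:
    q1, q3, p10, p90 = np.percentile(arr, [25, 75, 10, 90])
    iqr = q3 - q1
    return {
        "q1": float(q1), "q3": float(q3), "iqr": float(iqr),
        "lower_fence": float(q1 - 1.5 * iqr),
        "upper_fence": float(q3 + 1.5 * iqr),
        "p10": float(p10), "p90": float(p90),
    }


def iqr_winsorize(values) -> tuple[np.ndarray, dict]:
    """Cap values outside the Tukey fences.

    Values below ``Q1 - 1.5*IQR`` become the input's 10th percentile; values
    above ``Q3 + 1.5*IQR`` become its 90th percentile.  Returns the capped
    array and a fence report.
    """
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size == 0:
        raise ValueError("iqr_winsorize: all values missing")
    if finite.size < 4:
        raise ValueError("iqr_winsorize requires at least 4 finite values")
    report = _fences_and_caps(finite)
    out = arr.copy()
    low = arr < report["lower_fence"]
    high = arr > report["upper_fence"]
    out[low] = report["p10"]
    out[high] = report["p90"]
    report["n_capped_low"] = int(low.sum())
    report["n_capped_high"] = int(high.sum())
    return out, report


class Winsorizer:
    """Fit/apply version of :func:`iqr_winsorize` honouring the leakage
    contract: fences and caps come from the fit data only."""

    def __init__(self):
        self.report_: dict | None = None

    def fit(self, values) -> "Winsorizer":
        arr = np.asarray(values, dtype=float)
        finite = arr[np.isfinite(arr)]
        if finite.size < 4:
            raise ValueError("Winsorizer requires at least 4 finite values")
        self.report_ = _fences_and_caps(finite)
        return self

    def transform(self, values) -> np.ndarray:
        if self.report_ is None:
            raise RuntimeError("Winsorizer is not fitted")
        arr = np.asarray(values, dtype=float).copy()
        r = self.report_
        arr[arr < r["lower_fence"]] = r["p10"]
        arr[arr > r["upper_fence"]] = r["p90"]
        return arr

    def to_dict(self) -> dict:
        return {"kind": "winsorize", "params": self.report_}

    @classmethod
    def from_dict(cls, d: dict) -> "Winsorizer":
        obj = cls()
        obj.report_ = d["params"]
        return obj


class MinMaxScalerDF:
    """Column-wise min-max scaling fitted on the training partition.

    Train min maps to 0 and train max to 1; apply-partition values are scaled
    with the *train* parameters and may fall outside [0, 1].  A constant
    training column maps to all zeros (with a warning).
    """

    def __init__(self, columns: list[str] | None = None):
        self.columns = columns
        self.params_: dict[str, tuple[float, float]] | None = None

    def fit(self, df: pd.DataFrame) -> "MinMaxScalerDF":
        cols = self.columns if self.columns is not None else list(df.columns)
        self.params_ = {}
        for col in cols:
            vals = pd.to_numeric(df[col], errors="raise").astype(float)
            lo, hi = float(np.nanmin(vals)), float(np.nanmax(vals))
            if hi == lo:
                warnings.warn(f"constant training column {col!r}; mapping to 0")
            self.params_[col] = (lo, hi)
        return self

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        if self.params_ is None:
            raise RuntimeError("MinMaxScalerDF is not fitted")
        out = df.copy()
        for col, (lo, hi) in self.params_.items():
            if hi == lo:
                out[col] = 0.0
            else:
                out[col] = (pd.to_numeric(out[col]).astype(float) - lo) / (hi - lo)
        return out

    def to_dict(self) -> dict:
        return {"kind": "minmax", "params": self.params_}

    @classmethod
    def from_dict(cls, d: dict) -> "MinMaxScalerDF":
        obj = cls()
        obj.params_ = {k: tuple(v) for k, v in d["params"].items()}
        obj.columns = list(obj.params_)
        return obj


def minmax_fit_apply(train_values, apply_values=None) -> np.ndarray:
    """Convenience wrapper: fit min-max on ``train_values`` and scale
    ``apply_values`` (defaults to the train vector) with those parameters."""
    train = np.asarray(train_values, dtype=float)
    apply_arr = train if apply_values is None else np.asarray(apply_values, dtype=float)
    lo, hi = float(np.nanmin(train)), float(np.nanmax(train))
    if hi == lo:
        warnings.warn("constant training column; mapping to 0")
        return np.zeros_like(apply_arr)
    return (apply_arr - lo) / (hi - lo)


class DummyEncoder:
    """First-level-dropped indicator encoding with levels fixed at fit time.

    A k-level feature yields k-1 indicator columns named
    ``<feature>=<level>``; an unseen level at apply time encodes as all
    zeros.  ``parent_map_`` maps every output column (indicator or numeric
    passthrough) to its originating feature, which subset selection uses to
    resolve pre-encoding feature names to encoded columns.
    """

    def __init__(self, categorical: list[str]):
        self.categorical = list(categorical)
        self.levels_: dict[str, list[str]] | None = None
        self.parent_map_: dict[str, str] | None = None
        self.output_columns_: list[str] | None = None

    def fit(self, df: pd.DataFrame) -> "DummyEncoder":
        self.levels_ = {}
        for col in self.categorical:
            lv = sorted(pd.Series(df[col]).dropna().astype(str).unique())
            self.levels_[col] = lv
        self.parent_map_ = {}
        self.output_columns_ = []
        for col in df.columns:
            if col in self.levels_:
                for level in self.levels_[col][1:]:
                    name = f"{col}={level}"
                    self.parent_map_[name] = col
                    self.output_columns_.append(name)
            else:
                self.parent_map_[col] = col
                self.output_columns_.append(col)
        return self

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        if self.levels_ is None:
            raise RuntimeError("DummyEncoder is not fitted")
        pieces = {}
        for col in df.columns:
            if col in self.levels_:
                vals = df[col].astype(str)
                for level in self.levels_[col][1:]:
                    pieces[f"{col}={level}"] = (vals == level).astype(float).values
            else:
                pieces[col] = df[col].values
        out = pd.DataFrame(pieces, index=df.index)
        return out[[c for c in self.output_columns_ if c in out.columns]]

    def to_dict(self) -> dict:
        return {"kind": "dummy", "params": {"levels": self.levels_,
                                            "categorical": self.categorical}}

    @classmethod
    def from_dict(cls, d: dict) -> "DummyEncoder":
        obj = cls(d["params"]["categorical"])
        obj.levels_ = d["params"]["levels"]
        return obj


def impute_missing(features: pd.DataFrame, metadata: dict) -> pd.DataFrame:
    """Fill nulls per feature rule: history counts -> 0, labs/vital flags ->
    -1.  A null in a feature without a declared rule raises, naming it."""
    out = features.copy()
    meta = metadata["features"]
    skip = set(metadata.get("id_columns", [])) | {metadata.get("target")}
    for col in out.columns:
        if col in skip:
            continue
        if not out[col].isna().any():
            continue
        rule = meta.get(col, {}).get("impute")
        if rule == "zero":
            out[col] = out[col].fillna(0.0)
        elif rule == "minus_one":
            out[col] = out[col].fillna(-1.0)
        else:
            raise ValueError(
                f"feature {col!r} contains nulls but declares no imputation rule")
    return out


@dataclass
class TargetBundle:
    """Per-encounter targets: raw days, log scale, and 4-level category."""

    los_days: np.ndarray
    los_log: np.ndarray
    los_category: np.ndarray
    interval_table: list[dict] = field(default_factory=list)
    log_edges: np.ndarray | None = None

    def validate(self) -> None:
        n = len(self.los_days)
        assert len(self.los_log) == n and len(self.los_category) == n
        assert set(np.unique(self.los_category)) <= set(range(len(self.interval_table)))


def bin_target_qcut(los_days, n_bins: int = 4) -> TargetBundle:
    """Quantile-cut the log-transformed stay into ``n_bins`` classes.

    Classes are left-open/right-closed on strictly increasing quantile edges
    of the log-scale values (the lowest edge is pulled below the minimum so
    every value maps to exactly one class).  The interval table reports
    day-scale edges: back-transformed quantile edges rounded to 1 decimal.
    """
    days = np.asarray(los_days, dtype=float)
    if not np.all(np.isfinite(days)):
        raise ValueError("bin_target_qcut requires finite values")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    logs = log_transform(days)
    n_distinct = len(np.unique(logs))
    eff_bins = n_bins
    if n_distinct < n_bins:
        eff_bins = max(2, n_distinct)
        warnings.warn(f"only {n_distinct} distinct values; reducing to "
                      f"{eff_bins} bins")
    cats, edges = pd.qcut(logs, eff_bins, labels=False, retbins=True,
                          duplicates="drop")
    cats = np.asarray(cats).astype(int)
    eff_bins = len(edges) - 1
    edges[0] = min(edges[0], logs.min()) - 1e-9
    day_edges = np.round(inverse_log_transform(edges), 1)
    counts = np.bincount(cats, minlength=eff_bins)
    table = [
        {"class": int(c), "left": float(day_edges[c]),
         "right": float(day_edges[c + 1]), "frequency": int(counts[c])}
        for c in range(eff_bins)
    ]
    return TargetBundle(los_days=days, los_log=logs,
                        los_category=cats.astype(int),
                        interval_table=table, log_edges=edges)


def assign_classes(los_days, day_edges) -> np.ndarray:
    """Assign classes from day-scale edges; class c iff value in
    ``(edge_c, edge_{c+1}]``.  Useful for fixed published interval tables."""
    days = np.asarray(los_days, dtype=float)
    edges = np.asarray(day_edges, dtype=float)
    if np.any(days <= edges[0]) or np.any(days > edges[-1]):
        raise ValueError("value outside the interval table range")
    return (np.searchsorted(edges, days, side="left") - 1).astype(int)


def save_transforms(transforms: dict, path: str | Path, fold_id=None) -> None:
    payload = {"fold_id": fold_id,
               "transforms": {name: t.to_dict() for name, t in transforms.items()}}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def load_transforms(path: str | Path) -> dict:
    payload = json.loads(Path(path).read_text())
    registry = {"winsorize": Winsorizer, "minmax": MinMaxScalerDF,
                "dummy": DummyEncoder}
    return {name: registry[d["kind"]].from_dict(d)
            for name, d in payload["transforms"].items()}
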