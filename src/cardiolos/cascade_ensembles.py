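"""Classifier/regressor cascade architectures over pluggable base learners.

Four architectures are provided:

* ``avg_vote`` — independent regressors averaged arithmetically.
* ``seq2`` — a 4-class stay-category classifier whose class-probability
  columns are appended to the regressor's feature block.
* ``seq3`` — as ``seq2``, then a second regressor fed the first regressor's
  scalar prediction (and only that) alongside its own feature block.
* ``parallel`` — classifier and first regressor fitted side by side on raw
  feature blocks; the second regressor receives both the 4 probability
  columns and the first regressor's prediction.

Each component may use its own named feature subset (resolved through the
subset registry and the encoder's parent map).  Downstream levels are
trained on in-sample upstream outputs by default, with an out-of-fold
cross-fitting mode behind ``cross_fit``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import cross_val_predict

from .learners import LearnerSpec, build_estimator
from .transforms import inverse_log_transform

__all__ = [
    "CascadeSpec",
    "FittedCascade",
    "ArchitectureError",
    "augment_features",
    "resolve_columns",
    "fit_cascade",
    "fit_avg_vote",
    "fit_sequential_cascade",
    "fit_parallel_cascade",
    "predict_cascade",
]

ARCHITECTURES = ("single", "avg_vote", "seq2", "seq3", "parallel")
N_CLASSES = 4


class ArchitectureError(ValueError):
    """Structural violation of a cascade architecture contract."""


@dataclass(frozen=True)
class CascadeSpec:
    """Declarative cascade description: which components, which subsets."""

    architecture: str
    regressors: tuple[LearnerSpec, ...]
    classifier: LearnerSpec | None = None
    name: str = ""

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ArchitectureError(
                f"unknown architecture {self.architecture!r}")
        n_reg = len(self.regressors)
        if self.architecture == "single":
            if self.classifier is not None:
                raise ArchitectureError("single takes no classifier")
            if n_reg != 1:
                raise ArchitectureError("single needs exactly 1 regressor")
        elif self.architecture == "avg_vote":
            if self.classifier is not None:
                raise ArchitectureError("avg_vote takes no classifier")
            if n_reg < 2:
                raise ArchitectureError("avg_vote needs >= 2 regressors")
        else:
            if self.classifier is None:
                raise ArchitectureError(
                    f"{self.architecture} requires a classifier")
            expected = {"seq2": 1, "seq3": 2, "parallel": 2}[self.architecture]
            if n_reg != expected:
                raise ArchitectureError(
                    f"{self.architecture} needs exactly {expected} "
                    f"regressor(s), got {n_reg}")

    @classmethod
    def from_dict(cls, d: dict) -> "CascadeSpec":
        clf = d.get("classifier")
        return cls(
            architecture=d["architecture"],
            regressors=tuple(LearnerSpec(**r) for r in d["regressors"]),
            classifier=LearnerSpec(**clf) if clf else None,
            name=d.get("name", ""),
        )


def augment_features(X: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Append meta-feature columns to a feature block, order preserved."""
    if len(meta.columns) == 0:
        return X.copy()
    if len(meta) != len(X):
        raise ValueError(
            f"meta row count {len(meta)} != feature row count {len(X)}")
    meta = meta.set_index(X.index)
    return pd.concat([X, meta], axis=1)


def resolve_columns(
    columns, subset_features: list[str], parent_map: dict[str, str] | None
) -> list[str]:
    """Map pre-encoding feature names to the encoded columns they produced.

    Indicator columns inherit their parent categorical feature's selection
    status via ``parent_map`` (encoded column -> parent feature).
    """
    wanted = set(subset_features)
    if parent_map is None:
        parent_map = {c: c for c in columns}
    out = [c for c in columns if parent_map.get(c, c) in wanted]
    if not out:
        raise ValueError("feature subset resolves to zero encoded columns")
    return out


def _proba_frame(clf, X: np.ndarray, index) -> pd.DataFrame:
    proba = clf.predict_proba(X)
    if proba.shape[1] != N_CLASSES:
        raise ArchitectureError(
            f"classifier emitted {proba.shape[1]} probability columns, "
            f"expected {N_CLASSES}")
    cols = [f"CLS-PROBA-{c}" for c in clf.classes_]
    return pd.DataFrame(proba, columns=cols, index=index)


@dataclass
class FittedCascade:
    """Predict-capable realization of a :class:`CascadeSpec`."""

    spec: CascadeSpec
    components: dict = field(default_factory=dict)
    inventories: dict = field(default_factory=dict)
    input_columns: list[str] = field(default_factory=list)
    class_order: list[int] | None = None
    seed_record: dict = field(default_factory=dict)

    def _check_input(self, X: pd.DataFrame) -> None:
        missing = [c for c in self.input_columns if c not in X.columns]
        extra = [c for c in X.columns if c not in self.input_columns]
        if missing or extra:
            raise ValueError(
                f"input columns do not match the recorded inventory; "
                f"missing={missing[:5]}, extra={extra[:5]}")

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        self._check_input(X)
        arch = self.spec.architecture
        inv = self.inventories
        if arch in ("avg_vote", "single"):
            preds = [
                self.components[f"regressor_{i}"].predict(
                    X[inv[f"regressor_{i}"]].values)
                for i in range(len(self.spec.regressors))
            ]
            return np.mean(preds, axis=0)

        clf = self.components["classifier"]
        proba = _proba_frame(clf, X[inv["classifier"]].values, X.index)
        if arch == "seq2":
            X_r = augment_features(X[inv["regressor_0_base"]], proba)
            return self.components["regressor_0"].predict(X_r.values)
        if arch == "seq3":
            X_r1 = augment_features(X[inv["regressor_0_base"]], proba)
            r1_hat = self.components["regressor_0"].predict(X_r1.values)
            X_r2 = augment_features(
                X[inv["regressor_1_base"]],
                pd.DataFrame({"REG1-PRED": r1_hat}, index=X.index))
            return self.components["regressor_1"].predict(X_r2.values)
        # parallel
        r1_hat = self.components["regressor_0"].predict(
            X[inv["regressor_0_base"]].values)
        meta = pd.concat(
            [proba, pd.DataFrame({"REG1-PRED": r1_hat}, index=X.index)], axis=1)
        X_r2 = augment_features(X[inv["regressor_1_base"]], meta)
        return self.components["regressor_1"].predict(X_r2.values)

    def predict_days(self, X: pd.DataFrame, target_scaler=None) -> np.ndarray:
        """Back-transform predictions to the day scale (inverting the target
        min-max scaling if a fitted scaler is given, then ``expm1``)."""
        yhat = self.predict(X)
        if target_scaler is not None:
            lo, hi = target_scaler
            yhat = yhat * (hi - lo) + lo
        return inverse_log_transform(yhat)

    def manifest(self) -> dict:
        return {
            "architecture": self.spec.architecture,
            "name": self.spec.name,
            "class_order": self.class_order,
            "inventories": self.inventories,
            "input_columns": self.input_columns,
            "seeds": self.seed_record,
        }


def _subset_block(X, registry, parent_map, spec: LearnerSpec):
    if registry is None:
        return list(X.columns)
    return resolve_columns(X.columns, registry.features(spec.feature_subset),
                           parent_map)


def fit_avg_vote(
    X: pd.DataFrame, y_reg, spec: CascadeSpec,
    registry=None, parent_map=None,
) -> FittedCascade:
    """Fit independent regressors; prediction is their exact arithmetic mean
    (``single`` is the degenerate one-regressor case)."""
    if spec.architecture not in ("avg_vote", "single"):
        raise ArchitectureError("spec.architecture must be 'avg_vote' or 'single'")
    fitted = FittedCascade(spec=spec, input_columns=list(X.columns))
    y = np.asarray(y_reg, dtype=float)
    for i, lspec in enumerate(spec.regressors):
        cols = _subset_block(X, registry, parent_map, lspec)
        est = build_estimator(lspec)
        est.fit(X[cols].values, y)
        fitted.components[f"regressor_{i}"] = est
        fitted.inventories[f"regressor_{i}"] = cols
        fitted.seed_record[f"regressor_{i}"] = lspec.seed
    return fitted


def _fit_classifier(X, y_cls, spec, registry, parent_map, fitted, cross_fit):
    cols = _subset_block(X, registry, parent_map, spec.classifier)
    clf = build_estimator(spec.classifier)
    y = np.asarray(y_cls)
    clf.fit(X[cols].values, y)
    fitted.components["classifier"] = clf
    fitted.inventories["classifier"] = cols
    fitted.seed_record["classifier"] = spec.classifier.seed
    fitted.class_order = [int(c) for c in clf.classes_]
    if cross_fit:
        proba = cross_val_predict(
            build_estimator(spec.classifier), X[cols].values, y,
            cv=5, method="predict_proba")
        if proba.shape[1] != N_CLASSES:
            raise ArchitectureError(
                f"classifier emitted {proba.shape[1]} probability columns, "
                f"expected {N_CLASSES}")
        proba = pd.DataFrame(
            proba, columns=[f"CLS-PROBA-{c}" for c in clf.classes_],
            index=X.index)
    else:
        proba = _proba_frame(clf, X[cols].values, X.index)
    return proba


def fit_sequential_cascade(
    X: pd.DataFrame, y_reg, y_cls, spec: CascadeSpec,
    registry=None, parent_map=None, cross_fit: bool = False,
) -> FittedCascade:
    """Fit a depth-2 or depth-3 sequential cascade.

    seq2: regressor trained on its subset plus the 4 class-probability
    columns.  seq3: additionally a second regressor trained on its subset
    plus the first regressor's scalar prediction (and not the
    probabilities).
    """
    if spec.architecture not in ("seq2", "seq3"):
        raise ArchitectureError("spec.architecture must be 'seq2' or 'seq3'")
    fitted = FittedCascade(spec=spec, input_columns=list(X.columns))
    y = np.asarray(y_reg, dtype=float)
    proba = _fit_classifier(X, y_cls, spec, registry, parent_map, fitted,
                            cross_fit)

    r0_cols = _subset_block(X, registry, parent_map, spec.regressors[0])
    X_r0 = augment_features(X[r0_cols], proba)
    reg0 = build_estimator(spec.regressors[0])
    reg0.fit(X_r0.values, y)
    fitted.components["regressor_0"] = reg0
    fitted.inventories["regressor_0_base"] = r0_cols
    fitted.seed_record["regressor_0"] = spec.regressors[0].seed

    if spec.architecture == "seq3":
        r0_hat = reg0.predict(X_r0.values)
        r1_cols = _subset_block(X, registry, parent_map, spec.regressors[1])
        X_r1 = augment_features(
            X[r1_cols], pd.DataFrame({"REG1-PRED": r0_hat}, index=X.index))
        reg1 = build_estimator(spec.regressors[1])
        reg1.fit(X_r1.values, y)
        fitted.components["regressor_1"] = reg1
        fitted.inventories["regressor_1_base"] = r1_cols
        fitted.seed_record["regressor_1"] = spec.regressors[1].seed
    return fitted


def fit_parallel_cascade(
    X: pd.DataFrame, y_reg, y_cls, spec: CascadeSpec,
    registry=None, parent_map=None, cross_fit: bool = False,
) -> FittedCascade:
    """Fit the parallel cascade: classifier and Regressor-1 independently on
    raw subset blocks; Regressor-2 on its subset plus the 4 probability
    columns plus Regressor-1's prediction (width d + 5)."""
    if spec.architecture != "parallel":
        raise ArchitectureError("spec.architecture must be 'parallel'")
    fitted = FittedCascade(spec=spec, input_columns=list(X.columns))
    y = np.asarray(y_reg, dtype=float)
    proba = _fit_classifier(X, y_cls, spec, registry, parent_map, fitted,
                            cross_fit)

    r0_cols = _subset_block(X, registry, parent_map, spec.regressors[0])
    reg0 = build_estimator(spec.regressors[0])
    reg0.fit(X[r0_cols].values, y)
    fitted.components["regressor_0"] = reg0
    fitted.inventories["regressor_0_base"] = r0_cols
    fitted.seed_record["regressor_0"] = spec.regressors[0].seed

    r0_hat = reg0.predict(X[r0_cols].values)
    meta = pd.concat(
        [proba, pd.DataFrame({"REG1-PRED": r0_hat}, index=X.index)], axis=1)
    r1_cols = _subset_block(X, registry, parent_map, spec.regressors[1])
    X_r1 = augment_features(X[r1_cols], meta)
    reg1 = build_estimator(spec.regressors[1])
    reg1.fit(X_r1.values, y)
    fitted.components["regressor_1"] = reg1
    fitted.inventories["regressor_1_base"] = r1_cols
    fitted.seed_record["regressor_1"] = spec.regressors[1].seed
    return fitted


def fit_cascade(
    X: pd.DataFrame, y_reg, y_cls, spec: CascadeSpec,
    registry=None, parent_map=None, cross_fit: bool = False,
) -> FittedCascade:
    """Dispatch to the architecture-specific fit function."""
    if spec.architecture in ("avg_vote", "single"):
        return fit_avg_vote(X, y_reg, spec, registry, parent_map)
    if spec.architecture in ("seq2", "seq3"):
        return fit_sequential_cascade(
            X, y_reg, y_cls, spec, registry, parent_map, cross_fit)
    return fit_parallel_cascade(
        X, y_reg, y_cls, spec, registry, parent_map, cross_fit)


def predict_cascade(fitted: FittedCascade, X: pd.DataFrame) -> np.ndarray:
    """Functional alias for :meth:`FittedCascade.predict`."""
    return fitted.predict(X)


def save_manifest(fitted: FittedCascade, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(
        json.dumps(fitted.manifest(), indent=2, sort_keys=True))
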