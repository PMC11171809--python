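"""Metrics, randomized hyperparameter search and nested cross-validation.

The regression metrics are the plain definitions — MAE, MSE, RMSE = sqrt(MSE)
and R2 = 1 - SSE/SST — computed on the modelling scale (min-max-scaled,
winsorized log stay by default).  Nested CV uses stratified outer folds on
the 4-level stay category, fits every transform and runs the randomized
search strictly inside each outer-training fold, and logs the row indices
touched during fitting so leakage is checkable by instrumentation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import KFold, StratifiedKFold

from .cascade_ensembles import CascadeSpec, fit_cascade
from .feature_selection import SubsetRegistry, build_subset_registry, score_features
from .learners import LearnerSpec, build_estimator, default_search_spaces
from .transforms import (
    DummyEncoder,
    MinMaxScalerDF,
    Winsorizer,
    bin_target_qcut,
    impute_missing,
    log_transform,
)

__all__ = [
    "compute_metrics",
    "accuracy_from_counts",
    "randomized_search",
    "nested_cv_evaluate",
    "error_profile",
    "CVReport",
    "Preprocessor",
    "prepare_modeling_data",
]

REGRESSION_METRICS = ("MAE", "MSE", "RMSE", "R2")


def accuracy_from_counts(tp: int, tn: int, fp: int, fn: int) -> float:
    """Acc = (TP + TN) / (TP + TN + FP + FN)."""
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("no classified examples")
    return (tp + tn) / total


def compute_metrics(y, y_hat, task: str = "regression") -> dict[str, float]:
    """Evaluate the five headline formulas.

    Regression: MAE, MSE, RMSE (exactly sqrt(MSE)) and R2.  Classification:
    Acc as the fraction of exact label matches.  Zero-variance actuals make
    R2 undefined; it is reported as NaN with a warning.
    """
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if len(y) != len(y_hat):
        raise ValueError("length mismatch between actuals and predictions")
    n = len(y)
    if n == 0:
        raise ValueError("empty input")
    if task == "classification":
        return {"Acc": float(np.mean(y == y_hat))}
    err = y - y_hat
    mae = float(np.abs(err).sum() / n)
    mse = float((err ** 2).sum() / n)
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0.0:
        warnings.warn("zero-variance actuals: R2 undefined")
        r2 = float("nan")
    else:
        r2 = 1.0 - (err ** 2).sum() / sst
    return {"MAE": mae, "MSE": mse, "RMSE": float(np.sqrt(mse)),
            "R2": float(r2)}


# ---------------------------------------------------------------------------
# randomized hyperparameter search
# ---------------------------------------------------------------------------

def _sample_config(space: dict[str, list], rng: np.random.Generator) -> dict:
    return {k: v[rng.integers(len(v))] for k, v in space.items()}


def randomized_search(
    X: np.ndarray,
    y: np.ndarray,
    spec: LearnerSpec,
    search_space: dict[str, list],
    n_iter: int = 20,
    inner_folds: int = 3,
    seed: int = 0,
    task: str = "regression",
    return_trace: bool = False,
):
    """Sample ``n_iter`` configurations and return the one minimizing mean
    inner-fold MSE (regression) or maximizing accuracy (classification)."""
    if not search_space or any(len(v) == 0 for v in search_space.values()):
        raise ValueError("empty search space")
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if task == "classification":
        cv = StratifiedKFold(inner_folds, shuffle=True, random_state=seed)
        splits = list(cv.split(X, y))
    else:
        cv = KFold(inner_folds, shuffle=True, random_state=seed)
        splits = list(cv.split(X))
    trace = []
    for _ in range(n_iter):
        params = _sample_config(search_space, rng)
        fold_scores = []
        for tr, va in splits:
            est = build_estimator(spec.with_params(params))
            est.fit(X[tr], y[tr])
            pred = est.predict(X[va])
            if task == "classification":
                fold_scores.append(float(np.mean(pred == y[va])))
            else:
                fold_scores.append(float(np.mean(
                    (np.asarray(pred, dtype=float) - y[va].astype(float)) ** 2)))
        trace.append((params, float(np.mean(fold_scores))))
    if task == "classification":
        best = max(trace, key=lambda t: t[1])
    else:
        best = min(trace, key=lambda t: t[1])
    if return_trace:
        return best[0], trace
    return best[0]


# ---------------------------------------------------------------------------
# preprocessing pipeline (fit on training partitions only)
# ---------------------------------------------------------------------------

class Preprocessor:
    """Impute -> dummy-encode -> min-max scale, with target log +
    winsorize + min-max.  Records the row ids seen during ``fit`` so tests
    can verify the leakage contract by instrumentation."""

    def __init__(self, metadata: dict, scale_target: bool = True):
        self.metadata = metadata
        self.scale_target = scale_target
        self.fit_rows_: list | None = None

    def fit(self, features: pd.DataFrame, los_days) -> "Preprocessor":
        self.fit_rows_ = list(features.index)
        cat = [c for c, m in self.metadata["features"].items()
               if m["kind"] == "categorical" and c in features.columns]
        filled = impute_missing(features, self.metadata)
        X = filled[[c for c in filled.columns
                    if c in self.metadata["features"]]]
        self.encoder_ = DummyEncoder(cat).fit(X)
        encoded = self.encoder_.transform(X)
        self.scaler_ = MinMaxScalerDF().fit(encoded)

        y_log = log_transform(np.asarray(los_days, dtype=float))
        self.target_winsorizer_ = Winsorizer().fit(y_log)
        y_w = self.target_winsorizer_.transform(y_log)
        if self.scale_target:
            self.target_range_ = (float(y_w.min()), float(y_w.max()))
        else:
            self.target_range_ = None
        return self

    @property
    def parent_map(self) -> dict[str, str]:
        return self.encoder_.parent_map_

    def transform_features(self, features: pd.DataFrame) -> pd.DataFrame:
        filled = impute_missing(features, self.metadata)
        X = filled[[c for c in filled.columns
                    if c in self.metadata["features"]]]
        return self.scaler_.transform(self.encoder_.transform(X))

    def transform_target(self, los_days) -> np.ndarray:
        y = self.target_winsorizer_.transform(
            log_transform(np.asarray(los_days, dtype=float)))
        if self.target_range_ is not None:
            lo, hi = self.target_range_
            if hi > lo:
                y = (y - lo) / (hi - lo)
        return y


def prepare_modeling_data(
    features: pd.DataFrame, metadata: dict, scale_target: bool = True
):
    """Whole-dataset convenience path (no fold structure): fit the
    preprocessor on everything, bin the stay into 4 classes, and compute the
    subset registry once on the full table."""
    pre = Preprocessor(metadata, scale_target=scale_target).fit(
        features, features[metadata["target"]])
    X = pre.transform_features(features)
    y_reg = pre.transform_target(features[metadata["target"]])
    bundle = bin_target_qcut(features[metadata["target"]].values)
    scores = score_features(
        features, log_transform(features[metadata["target"]].values),
        "regression", metadata)
    scores += score_features(
        features, bundle.los_category, "classification", metadata)
    registry = build_subset_registry(
        scores, [c for c in features.columns if c in metadata["features"]])
    return X, y_reg, bundle, registry, pre


# ---------------------------------------------------------------------------
# nested cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    """Per-fold metrics with mean / best / STD aggregates."""

    architecture: str
    fold_metrics: list[dict] = field(default_factory=list)
    chosen_params: list[dict] = field(default_factory=list)
    fold_logs: list[dict] = field(default_factory=list)
    seed: int = 0

    def aggregate(self) -> dict[str, dict[str, float]]:
        out = {}
        for metric in self.fold_metrics[0]:
            vals = np.array([m[metric] for m in self.fold_metrics], dtype=float)
            best = float(vals.max()) if metric in ("R2", "Acc") else float(vals.min())
            out[metric] = {"mean": float(vals.mean()), "best": best,
                           "std": float(vals.std())}
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({
            "architecture": self.architecture,
            "seed": self.seed,
            "fold_metrics": self.fold_metrics,
            "chosen_params": self.chosen_params,
            "aggregate": self.aggregate(),
        }, indent=2, sort_keys=True, default=str)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def to_markdown(self) -> str:
        agg = self.aggregate()
        lines = [f"### {self.architecture}", "",
                 "| Metric | Mean | Best | STD |",
                 "|---|---|---|---|"]
        for metric, row in agg.items():
            lines.append(f"| {metric} | {row['mean']:.4f} | {row['best']:.4f}"
                         f" | {row['std']:.4f} |")
        return "\n".join(lines)


def _search_components(spec: CascadeSpec):
    comps = []
    if spec.classifier is not None:
        comps.append(("classifier", spec.classifier, "classification"))
    for i, r in enumerate(spec.regressors):
        comps.append((f"regressor_{i}", r, "regression"))
    return comps


def nested_cv_evaluate(
    features: pd.DataFrame,
    metadata: dict,
    spec: CascadeSpec,
    outer_folds: int = 5,
    n_iter: int = 20,
    inner_folds: int = 3,
    seed: int = 42,
    search_spaces: dict | None = None,
    registry: SubsetRegistry | None = None,
    scale_target: bool = True,
    cross_fit: bool = False,
) -> CVReport:
    """Five-fold (by default) nested CV of a cascade spec.

    Outer folds are stratified on the 4-level stay category.  Per outer
    fold: transforms are fitted on the training part only, each component's
    hyperparameters are chosen by randomized search on the training part,
    the cascade is refitted with the winners, and metrics are taken on the
    untouched test part.  ``fold_logs`` records fit-time and test row ids
    for leakage instrumentation.
    """
    search_spaces = search_spaces or default_search_spaces()
    target = metadata["target"]
    bundle = bin_target_qcut(features[target].values)
    y_cls_all = bundle.los_category
    if len(np.unique(y_cls_all)) < 2:
        raise ValueError("stratification error: fewer than 2 stay classes")

    skf = StratifiedKFold(outer_folds, shuffle=True, random_state=seed)
    report = CVReport(architecture=spec.name or spec.architecture, seed=seed)
    features = features.reset_index(drop=True)

    if registry is None:
        # fixed subsets computed once on the full table
        scores = score_features(
            features, log_transform(features[target].values), "regression",
            metadata)
        scores += score_features(features, y_cls_all, "classification", metadata)
        registry = build_subset_registry(
            scores, [c for c in features.columns if c in metadata["features"]])

    for fold_i, (tr_idx, te_idx) in enumerate(
            skf.split(features, y_cls_all)):
        tr = features.iloc[tr_idx]
        te = features.iloc[te_idx]
        pre = Preprocessor(metadata, scale_target=scale_target).fit(
            tr, tr[target])
        X_tr = pre.transform_features(tr)
        X_te = pre.transform_features(te)
        y_tr = pre.transform_target(tr[target])
        y_te = pre.transform_target(te[target])
        cls_tr = y_cls_all[tr_idx]

        search_rows = list(tr.index)
        chosen: dict[str, dict] = {}
        new_spec = spec
        comps = _search_components(spec)
        tuned_regs = list(spec.regressors)
        tuned_clf = spec.classifier
        for name, lspec, task in comps:
            space = search_spaces.get(lspec.family)
            if not space:
                continue
            cols = (X_tr.columns if registry is None else
                    [c for c in X_tr.columns
                     if pre.parent_map.get(c, c)
                     in set(registry.features(lspec.feature_subset))])
            y_search = cls_tr if task == "classification" else y_tr
            best = randomized_search(
                X_tr[list(cols)].values, y_search, lspec, space,
                n_iter=n_iter, inner_folds=inner_folds,
                seed=seed + 1000 * fold_i, task=task)
            chosen[name] = best
            if name == "classifier":
                tuned_clf = lspec.with_params(best)
            else:
                tuned_regs[int(name.split("_")[1])] = lspec.with_params(best)
        new_spec = CascadeSpec(
            architecture=spec.architecture, regressors=tuple(tuned_regs),
            classifier=tuned_clf, name=spec.name)

        fitted = fit_cascade(X_tr, y_tr, cls_tr, new_spec, registry,
                             pre.parent_map, cross_fit=cross_fit)
        y_hat = fitted.predict(X_te)
        report.fold_metrics.append(compute_metrics(y_te, y_hat))
        report.chosen_params.append(chosen)
        report.fold_logs.append({
            "fit_rows": sorted(set(pre.fit_rows_) | set(search_rows)),
            "test_rows": sorted(te.index),
        })
    return report


# ---------------------------------------------------------------------------
# error profiles / reporting artifacts
# ---------------------------------------------------------------------------

def error_profile(actual_days, predicted_days) -> dict:
    """Histogram of rounded day differences (actual - predicted,
    half-to-even rounding)."""
    a = np.asarray(actual_days, dtype=float).ravel()
    p = np.asarray(predicted_days, dtype=float).ravel()
    if len(a) != len(p):
        raise ValueError("length mismatch between actuals and predictions")
    diffs = np.rint(a - p).astype(int)
    values, counts = np.unique(diffs, return_counts=True)
    return {"differences": diffs,
            "histogram": {int(v): int(c) for v, c in zip(values, counts)},
            "n": len(a)}


def confusion_profile(actual_cls, predicted_cls, n_classes: int = 4) -> dict:
    """Confusion matrix (rows = actual classes) plus per-class supports."""
    a = np.asarray(actual_cls).ravel()
    p = np.asarray(predicted_cls).ravel()
    if len(a) != len(p):
        raise ValueError("length mismatch")
    labels = list(range(n_classes))
    cm = _sk_confusion(a, p, labels=labels)
    return {"matrix": cm,
            "supports": {c: int((a == c).sum()) for c in labels},
            "correct": int(np.trace(cm))}


def plot_error_histogram(profile: dict, out_png: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    hist = profile["histogram"]
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(list(hist.keys()), list(hist.values()), color="#28708f")
    ax.set_xlabel("actual - predicted stay (days)")
    ax.set_ylabel("count")
    fig.tight_layout()
    fig.savefig(out_png, dpi=120)
    plt.close(fig)


def plot_confusion(profile: dict, out_png: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    cm = profile["matrix"]
    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(cm, cmap="Blues")
    for i in range(cm.shape[0]):
        for j in range(cm.shape[1]):
            ax.text(j, i, str(cm[i, j]), ha="center", va="center")
    ax.set_xlabel("predicted class")
    ax.set_ylabel("actual class")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(out_png, dpi=120)
    plt.close(fig)
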