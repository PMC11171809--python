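"""Univariate feature scoring and the named feature-subset registry.

Four method/target pairings are supported:

* ``pearson`` — numeric feature vs numeric target; keep if ``|r| >= 0.1``.
* ``kruskal_R`` — categorical feature vs numeric target (groups are the
  feature's categories); keep if ``p <= 0.05``.
* ``kruskal_C`` — numeric feature vs categorical target (groups are the
  target classes); keep if ``p <= 0.05``.
* ``chi_square`` — categorical feature vs categorical target on the observed
  contingency table, no continuity correction; keep if ``p <= 0.05``.

Single-method selections feed a registry of named subsets: FS-1 is every
feature, FS-2..FS-5 the single-method selections, FS-6..FS-10 their set
unions.  Selection operates on pre-encoding feature names; dummy-encoded
indicator columns inherit their parent's status downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SelectionScore",
    "SubsetRegistry",
    "score_features",
    "build_subset_registry",
    "SUBSET_COMBINATIONS",
]

PEARSON_THRESHOLD = 0.1
P_VALUE_THRESHOLD = 0.05

#: Method combination behind each registry subset name.
SUBSET_COMBINATIONS: dict[str, tuple[str, ...]] = {
    "FS-1": (),
    "FS-2": ("pearson",),
    "FS-3": ("kruskal_R",),
    "FS-4": ("kruskal_C",),
    "FS-5": ("chi_square",),
    "FS-6": ("pearson", "kruskal_R"),
    "FS-7": ("kruskal_C", "chi_square"),
    "FS-8": ("kruskal_C", "kruskal_R"),
    "FS-9": ("chi_square", "pearson"),
    "FS-10": ("chi_square", "kruskal_R"),
}


@dataclass
class SelectionScore:
    feature: str
    method: str  # pearson | kruskal_R | kruskal_C | chi_square
    statistic: float
    p_value: float | None
    selected: bool
    reason: str = ""


def _is_degenerate(series: pd.Series) -> bool:
    return series.dropna().nunique() < 2


def score_features(
    features: pd.DataFrame,
    target,
    task: str,
    metadata: dict,
) -> list[SelectionScore]:
    """Score every eligible feature against the target for the given task.

    ``task='regression'`` pairs numeric features with Pearson correlation and
    categorical features with Kruskal-Wallis (groups = categories);
    ``task='classification'`` pairs numeric features with Kruskal-Wallis
    (groups = target classes) and categorical features with the chi-square
    test of independence.  Constant features are reported unselected with
    reason ``degenerate``.
    """
    if task not in ("regression", "classification"):
        raise ValueError(f"unknown task {task!r}")
    y = np.asarray(target)
    meta = metadata["features"]
    skip = set(metadata.get("id_columns", [])) | {metadata.get("target")}
    scores: list[SelectionScore] = []
    for col in features.columns:
        if col in skip or col not in meta:
            continue
        kind = meta[col]["kind"]
        series = features[col]
        if task == "regression" and kind == "numerical":
            method = "pearson"
        elif task == "regression" and kind == "categorical":
            method = "kruskal_R"
        elif task == "classification" and kind == "numerical":
            method = "kruskal_C"
        else:
            method = "chi_square"

        if _is_degenerate(series):
            scores.append(SelectionScore(col, method, float("nan"), None,
                                         False, reason="degenerate"))
            continue

        if method == "pearson":
            x = pd.to_numeric(series, errors="raise").astype(float).values
            mask = np.isfinite(x)
            r, _ = stats.pearsonr(x[mask], y[mask])
            scores.append(SelectionScore(
                col, method, float(r), None, bool(abs(r) >= PEARSON_THRESHOLD)))
        elif method in ("kruskal_R", "kruskal_C"):
            if method == "kruskal_R":
                groups = [y[(series == level).values]
                          for level in series.dropna().unique()]
            else:
                x = pd.to_numeric(series, errors="raise").astype(float).values
                groups = [x[(y == cls) & np.isfinite(x)] for cls in np.unique(y)]
            groups = [g for g in groups if len(g) > 0]
            try:
                stat, p = stats.kruskal(*groups)
            except ValueError:
                scores.append(SelectionScore(col, method, float("nan"), None,
                                             False, reason="degenerate"))
                continue
            scores.append(SelectionScore(col, method, float(stat), float(p),
                                         bool(p <= P_VALUE_THRESHOLD)))
        else:  # chi_square
            table = pd.crosstab(series, pd.Series(y, index=series.index))
            stat, p, _, _ = stats.chi2_contingency(table.values, correction=False)
            scores.append(SelectionScore(col, method, float(stat), float(p),
                                         bool(p <= P_VALUE_THRESHOLD)))
    return scores


@dataclass
class SubsetRegistry:
    """Named feature subsets with the method combination that produced each."""

    subsets: dict[str, list[str]]
    combinations: dict[str, tuple[str, ...]]

    def features(self, name: str) -> list[str]:
        if name not in self.subsets:
            raise KeyError(f"unknown feature subset {name!r}")
        return list(self.subsets[name])

    def __contains__(self, name: str) -> bool:
        return name in self.subsets

    def sizes(self) -> dict[str, int]:
        return {name: len(f) for name, f in self.subsets.items()}

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"subsets": self.subsets,
             "combinations": {k: list(v) for k, v in self.combinations.items()}},
            indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "SubsetRegistry":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        return cls(subsets=d["subsets"],
                   combinations={k: tuple(v) for k, v in d["combinations"].items()})


def build_subset_registry(
    scores: list[SelectionScore], all_features: list[str]
) -> SubsetRegistry:
    """Assemble FS-1..FS-10 from per-method selections.

    Combined subsets are set unions of their constituent single-method
    selections; ordering follows ``all_features`` so the registry is
    deterministic given the scores.
    """
    by_method: dict[str, set[str]] = {
        "pearson": set(), "kruskal_R": set(), "kruskal_C": set(),
        "chi_square": set()}
    for s in scores:
        if s.method not in by_method:
            raise ValueError(f"unknown selection method {s.method!r}")
        if s.selected:
            by_method[s.method].add(s.feature)

    order = {f: i for i, f in enumerate(all_features)}

    def ordered(featset: set[str]) -> list[str]:
        return sorted(featset, key=lambda f: order.get(f, len(order)))

    subsets = {"FS-1": list(all_features)}
    for name, methods in SUBSET_COMBINATIONS.items():
        if not methods:
            continue
        union: set[str] = set()
        for m in methods:
            union |= by_method[m]
        subsets[name] = ordered(union)
    return SubsetRegistry(subsets=subsets, combinations=dict(SUBSET_COMBINATIONS))


def scores_to_frame(scores: list[SelectionScore]) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in scores])
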