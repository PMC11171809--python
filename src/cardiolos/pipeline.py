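"""End-to-end experiment orchestration: simulate -> engineer -> select ->
train -> evaluate -> report, driven by a single YAML config."""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import evaluation, feature_engineering, feature_selection, synthetic_cohort
from .cascade_ensembles import CascadeSpec, fit_cascade, save_manifest
from .learners import default_search_spaces, small_search_spaces
from .transforms import bin_target_qcut, log_transform

log = logging.getLogger("cardiolos")

__all__ = ["ExperimentConfig", "run_experiment", "load_config"]


@dataclass
class ExperimentConfig:
    """Validated single-file experiment description."""

    output_dir: Path
    input_dir: Path | None = None
    simulate: dict = field(default_factory=dict)
    cascades: list[dict] = field(default_factory=list)
    evaluation: dict = field(default_factory=dict)
    seed: int = 42
    raw: dict = field(default_factory=dict)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def validate(self) -> None:
        known_subsets = set(feature_selection.SUBSET_COMBINATIONS)
        for c in self.cascades:
            spec = CascadeSpec.from_dict(c)  # structural validation
            for comp in list(spec.regressors) + (
                    [spec.classifier] if spec.classifier else []):
                if comp.feature_subset not in known_subsets:
                    raise ValueError(
                        f"cascade {spec.name or spec.architecture!r} references "
                        f"undefined feature subset {comp.feature_subset!r}")


def load_config(path: str | Path) -> ExperimentConfig:
    raw = yaml.safe_load(Path(path).read_text())
    cfg = ExperimentConfig(
        output_dir=Path(raw["output_dir"]),
        input_dir=Path(raw["input_dir"]) if raw.get("input_dir") else None,
        simulate=raw.get("simulate", {}),
        cascades=raw.get("cascades", []),
        evaluation=raw.get("evaluation", {}),
        seed=int(raw.get("seed", 42)),
        raw=raw,
    )
    cfg.validate()
    return cfg


def _provenance(cfg: ExperimentConfig) -> dict:
    return {"config_hash": cfg.config_hash, "seed": cfg.seed}


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Execute all stages; every artifact embeds the config hash and seed.

    Returns a dict of produced artifact paths.  Re-running an identical
    config reproduces identical JSON reports.
    """
    cfg.validate()
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out / "experiment.log")
    log.addHandler(fh)
    try:
        # ------------------------------------------------------ 1. cohort
        if cfg.input_dir is not None:
            log.info("loading cohort from %s", cfg.input_dir)
            cohort = synthetic_cohort.read_cohort(cfg.input_dir)
        else:
            sim = dict(cfg.simulate)
            sim.setdefault("seed", cfg.seed)
            gen_cfg = synthetic_cohort.GeneratorConfig(**sim)
            log.info("simulating cohort (n_patients=%d, seed=%d)",
                     gen_cfg.n_patients, gen_cfg.seed)
            cohort = synthetic_cohort.generate_cohort(gen_cfg)
            synthetic_cohort.write_cohort(cohort, out / "cohort")
            artifacts["cohort"] = str(out / "cohort")

        # ------------------------------------------- 2. engineer features
        features, metadata = feature_engineering.build_feature_table(cohort)
        metadata["provenance"] = _provenance(cfg)
        feature_engineering.write_feature_table(
            features, metadata, out / "features.csv", out / "features_meta.json")
        artifacts["features"] = str(out / "features.csv")
        log.info("engineered %d rows x %d columns", *features.shape)

        # --------------------------------------------- 3. subset registry
        target = metadata["target"]
        bundle = bin_target_qcut(features[target].values)
        scores = feature_selection.score_features(
            features, log_transform(features[target].values), "regression",
            metadata)
        scores += feature_selection.score_features(
            features, bundle.los_category, "classification", metadata)
        registry = feature_selection.build_subset_registry(
            scores, [c for c in features.columns if c in metadata["features"]])
        registry.to_json(out / "registry.json")
        artifacts["registry"] = str(out / "registry.json")

        if not cfg.cascades:
            warnings.warn("no cascades configured; stopping after selection")
            (out / "report.json").write_text(json.dumps(
                {"provenance": _provenance(cfg), "reports": {}},
                indent=2, sort_keys=True))
            return artifacts

        # ------------------------------------- 4. train + 5. evaluate
        eval_opts = cfg.evaluation
        spaces = (small_search_spaces() if eval_opts.get("small_spaces")
                  else default_search_spaces())
        reports = {}
        for i, cdict in enumerate(cfg.cascades):
            spec = CascadeSpec.from_dict(cdict)
            name = spec.name or f"{spec.architecture}-{i}"
            log.info("evaluating cascade %s", name)
            report = evaluation.nested_cv_evaluate(
                features, metadata, spec,
                outer_folds=int(eval_opts.get("outer_folds", 5)),
                n_iter=int(eval_opts.get("n_iter", 20)),
                inner_folds=int(eval_opts.get("inner_folds", 3)),
                seed=cfg.seed,
                search_spaces=spaces,
                registry=registry,
            )
            reports[name] = report

            # full-data fit for the serialized bundle
            X, y_reg, bundle2, _, pre = evaluation.prepare_modeling_data(
                features, metadata)
            fitted = fit_cascade(X, y_reg, bundle2.los_category, spec,
                                 registry, pre.parent_map)
            save_manifest(fitted, out / "models" / name)

        # ------------------------------------------------- 6. reporting
        report_payload = {
            "provenance": _provenance(cfg),
            "reports": {name: json.loads(r.to_json())
                        for name, r in reports.items()},
        }
        (out / "report.json").write_text(
            json.dumps(report_payload, indent=2, sort_keys=True))
        md = ["# Evaluation report",
              f"config hash: `{cfg.config_hash}`, seed: {cfg.seed}", ""]
        md += [reports[name].to_markdown() + "\n" for name in reports]
        (out / "report.md").write_text("\n".join(md))
        artifacts["report"] = str(out / "report.json")
        return artifacts
    finally:
        log.removeHandler(fh)
        fh.close()


def feature_table_from_dir(input_dir: str | Path):
    cohort = synthetic_cohort.read_cohort(input_dir)
    return feature_engineering.build_feature_table(cohort)


def registry_from_features(features: pd.DataFrame, metadata: dict):
    target = metadata["target"]
    bundle = bin_target_qcut(features[target].values)
    scores = feature_selection.score_features(
        features, log_transform(features[target].values), "regression", metadata)
    scores += feature_selection.score_features(
        features, bundle.los_category, "classification", metadata)
    return feature_selection.build_subset_registry(
        scores, [c for c in features.columns if c in metadata["features"]])
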