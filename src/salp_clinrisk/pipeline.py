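"""End-to-end orchestration: generate -> preprocess -> tune -> evaluate -> explain.

One seeded configuration drives every stage; all randomness flows from
per-stage child seeds spawned from the configuration seed, so identical
configurations produce byte-identical artifacts. The run directory receives
the cohort, partition tables, screening results, optimization traces, tidy
metric/curve tables, attributions, and a manifest sufficient to re-execute
the run.
"""

from __future__ import annotations

import json
import platform
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import evaluation, explain, preprocess, tuning
from .cohort import OUTCOME_COLUMN

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "run_from_manifest"]

_STAGE_NAMES = ("generate", "missingness", "split", "impute", "smote", "tune", "zoo", "explain")


@dataclass
class PipelineConfig:
    """Declarative description of one full analysis run."""

    seed: int = 0
    n_total: int = 774
    n_event: int = 47
    fractions: tuple[float, float, float] = (0.64, 0.16, 0.20)
    alpha: float = 0.05
    top_k: int | None = 9
    mice_cycles: int = 10
    smote_k: int = 5
    ssa_salps: int = 20
    ssa_iterations: int = 50
    cv_k: int = 5
    warm_start: bool = True
    tuned_families: tuple[str, ...] = ("random_forest", "xgboost")
    baseline_families: tuple[str, ...] = tuning.FAMILIES
    threshold: float = 0.5
    calibration_bins: int = 10
    dca_thresholds: tuple[float, ...] = tuple(np.round(np.arange(0.01, 0.51, 0.01), 2))
    sweep_grid: tuple[float, ...] = tuple(np.round(np.arange(0.05, 1.0, 0.05), 2))
    explain_background: int = 100
    explain_rows: int | None = None  # None -> whole test partition
    spec_path: str | None = None  # None -> built-in published-table specs

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fractions"] = list(self.fractions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("fractions", "tuned_families", "baseline_families",
                    "dca_thresholds", "sweep_grid"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class RunManifest:
    config: dict
    stage_seeds: dict
    partition_sizes: dict
    selected_features: list
    tuned_hyperparameters: dict
    library_versions: dict
    leakage_audit: dict
    timestamp: str
    out_dir: str

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGE_NAMES))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for name, child in zip(_STAGE_NAMES, children)
    }


class StageFailure(RuntimeError):
    pass


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunManifest:
    """Execute the full analysis and write all artifacts under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    try:
        manifest = _run(config, out, seeds)
    except Exception as exc:
        raise StageFailure(
            f"pipeline failed (stage context in traceback), seed={config.seed}"
        ) from exc
    return manifest


def _run(config: PipelineConfig, out: Path, seeds: dict[str, int]) -> RunManifest:
    # --- generate -----------------------------------------------------------
    if config.spec_path:
        specs = cohort_mod.specs_from_json(Path(config.spec_path).read_text())
    else:
        specs = cohort_mod.default_table1_specs()
    gen_cfg = cohort_mod.GeneratorConfig(
        n_total=config.n_total, n_event=config.n_event, seed=seeds["generate"]
    )
    complete = cohort_mod.generate_cohort(specs, gen_cfg)
    cohort = cohort_mod.inject_missingness(complete, specs, seed=seeds["missingness"])
    (out / "specs.json").write_text(cohort_mod.specs_to_json(specs))
    cohort.to_csv(out / "cohort.csv", index=False)

    # --- split / impute / screen / scale / SMOTE ---------------------------
    split = preprocess.split_cohort(cohort, config.fractions, seed=seeds["split"])
    (out / "splits.json").write_text(json.dumps(split.as_dict()))
    parts = {}
    for name, idx in (("train", split.train), ("validation", split.validation),
                      ("test", split.test)):
        part = cohort.iloc[idx].reset_index(drop=True)
        parts[name] = preprocess.impute_chained(
            part, n_cycles=config.mice_cycles, seed=seeds["impute"]
        )
        parts[name].to_csv(out / f"{name}_imputed.csv", index=False)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        screen = preprocess.screen_features(parts["train"], alpha=config.alpha,
                                            top_k=config.top_k)
    screen.to_json(out / "feature_screen.json", orient="records", indent=1)
    selected = screen.loc[screen["selected"], "variable"].tolist()
    if not selected:
        raise StageFailure("no feature passed the univariate screen")
    keep = selected + [OUTCOME_COLUMN]
    parts = {k: v[keep] for k, v in parts.items()}

    scaler, train_t, val_t, test_t = preprocess.standardize(
        parts["train"], parts["validation"], parts["test"]
    )
    train_bal = preprocess.apply_smote(train_t, k_neighbors=config.smote_k,
                                       seed=seeds["smote"])
    for name, df in (("train", train_t), ("validation", val_t), ("test", test_t),
                     ("train_smote", train_bal)):
        df.to_csv(out / f"{name}_scaled.csv", index=False)

    feature_cols = selected
    bin_idx = np.array(
        [feature_cols.index(c) for c in preprocess.infer_binary_columns(parts["train"])],
        dtype=int,
    )
    X_tr = train_t[feature_cols].to_numpy(float)
    y_tr = train_t[OUTCOME_COLUMN].to_numpy()
    X_bal = train_bal[feature_cols].to_numpy(float)
    y_bal = train_bal[OUTCOME_COLUMN].to_numpy()

    # --- tune + baselines ---------------------------------------------------
    models: list[tuning.ModelSpec] = []
    tuned_params: dict[str, dict] = {}
    for family in config.tuned_families:
        spec, result = tuning.tune(
            family, X_tr, y_tr,
            n_salps=config.ssa_salps, n_iterations=config.ssa_iterations,
            seed=seeds["tune"], cv_k=config.cv_k, warm_start=config.warm_start,
            smote_k=config.smote_k, binary_columns=bin_idx,
            X_final=X_bal, y_final=y_bal,
        )
        models.append(tuning.ModelSpec(
            family=f"ssa_{family}", hyperparameters=spec.hyperparameters,
            seed=spec.seed, estimator=spec.estimator,
        ))
        tuned_params[family] = dict(spec.hyperparameters)
        result.trace_frame().to_csv(out / f"trace_{family}.csv", index=False)
    models.extend(
        tuning.baseline_zoo(X_bal, y_bal, seed=seeds["zoo"],
                            families=config.baseline_families)
    )

    # --- evaluate -----------------------------------------------------------
    X_te = test_t[feature_cols].to_numpy(float)
    y_te = test_t[OUTCOME_COLUMN].to_numpy()
    metric_rows, curve_rows = [], []
    probs: dict[str, np.ndarray] = {}
    for spec in models:
        p = spec.predict_proba(X_te)
        probs[spec.family] = p
        cm = evaluation.confusion_at(p, y_te, config.threshold)
        report = evaluation.metrics_from(cm, p, y_te)
        row = {"model": spec.family, "tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn}
        row.update(report.as_dict())
        metric_rows.append(row)
        for kind, frame in (
            ("calibration", evaluation.calibration_curve(p, y_te, config.calibration_bins)),
            ("decision", evaluation.decision_curve(p, y_te, config.dca_thresholds)),
            ("sweep", evaluation.threshold_sweep(p, y_te, config.sweep_grid)),
        ):
            frame = frame.copy()
            frame.insert(0, "curve", kind)
            frame.insert(0, "model", spec.family)
            curve_rows.append(frame)
    metrics = pd.DataFrame(metric_rows)
    metrics.to_csv(out / "metrics.csv", index=False)
    (out / "metrics.json").write_text(
        json.dumps(metric_rows, indent=1, sort_keys=True, allow_nan=True, default=float)
    )
    pd.concat(curve_rows, ignore_index=True).to_csv(out / "curves.csv", index=False)

    # --- explain ------------------------------------------------------------
    rng = np.random.default_rng(seeds["explain"])
    n_bg = min(config.explain_background, len(train_t))
    background = train_t[feature_cols].iloc[
        np.sort(rng.choice(len(train_t), size=n_bg, replace=False))
    ]
    test_features = test_t[feature_cols]
    if config.explain_rows is not None and config.explain_rows < len(test_features):
        rows = np.sort(rng.choice(len(test_features), size=config.explain_rows, replace=False))
        test_features = test_features.iloc[rows]
    rankings = {}
    for spec in models:
        if not spec.family.startswith("ssa_"):
            continue
        attrs, ranking = explain.global_attributions(spec.estimator, test_features, background)
        ranking.to_csv(out / f"importance_{spec.family}.csv", index=False)
        attr_frame = attrs.frame()
        attr_frame["base"] = attrs.base
        attr_frame["model_output"] = attrs.outputs
        attr_frame.to_csv(out / f"attributions_{spec.family}.csv", index=False)
        rankings[spec.family] = ranking["feature"].tolist()

    # --- manifest -----------------------------------------------------------
    import sklearn
    import xgboost

    manifest = RunManifest(
        config=config.to_dict(),
        stage_seeds=seeds,
        partition_sizes={k: len(v) for k, v in
                         (("train", split.train), ("validation", split.validation),
                          ("test", split.test))},
        selected_features=selected,
        tuned_hyperparameters=tuned_params,
        library_versions={
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
            "xgboost": xgboost.__version__,
        },
        leakage_audit={
            "train_indices": split.train.tolist(),
            "validation_indices": split.validation.tolist(),
            "test_indices": split.test.tolist(),
            # stages below were fitted exclusively on the train partition
            "screen_indices": split.train.tolist(),
            "scaler_indices": split.train.tolist(),
            "smote_indices": split.train.tolist(),
        },
        timestamp=pd.Timestamp.now().isoformat(),
        out_dir=str(out),
    )
    manifest.save(out / "manifest.json")
    return manifest


def run_from_manifest(path: str | Path, out_dir: str | Path) -> RunManifest:
    """Re-execute a run from its saved manifest (numeric outputs reproduce)."""
    manifest = RunManifest.load(Path(path))
    return run_pipeline(PipelineConfig.from_dict(manifest.config), out_dir)
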