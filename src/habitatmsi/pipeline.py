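"""End-to-end orchestration: simulate → preprocess → subregions → MSI →
train → evaluate, with config, caching, and a run manifest.

The pipeline is a thin composition of the library modules. Stage outputs
that are tabular (the covariate table, the MSI feature table, rankings and
reports) are written under the run directory; the MSI feature table is
content-addressed by a hash of every upstream config key, so re-running an
unchanged config resumes from it and editing any upstream key invalidates
exactly the downstream stages that consume it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import (
    decision_curve,
    evaluate_model,
    subgroup_eval,
    youden_threshold,
)
from .modeling import (
    FeatureSelectionSpec,
    ModelGridSpec,
    ResampleSpec,
    grid_train,
    select_features,
    smote_resample,
    zscore_fit_apply,
)
from .msi import msi_feature_vector
from .preprocessing import WindowSpec, crop_voi, resample_isotropic, window_normalize
from .subregions import (
    SupervoxelSpec,
    assign_subregions,
    compute_supervoxels,
    fit_subregion_model,
    model_to_dict,
    subregion_stats,
)
from .synthetic import CohortRecipe, CohortResult, generate_cohort

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "ConfigError",
    "DependencyError",
    "run_pipeline",
    "extract_cohort_features",
    "train_and_evaluate",
    "run_msi_experiment",
]

ALL_STAGES = ("simulate", "preprocess", "subregions", "msi", "train", "evaluate")


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class DependencyError(RuntimeError):
    """An enabled stage is missing an upstream artifact."""


@dataclass
class PipelineConfig:
    """Full pipeline configuration: stage toggles plus every module spec."""

    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    out_dir: str = "habitat_run"
    cohort: CohortRecipe = field(default_factory=CohortRecipe)
    window: WindowSpec = field(default_factory=WindowSpec)
    resample_iso_mm: float | None = 1.0
    supervoxels: SupervoxelSpec = field(default_factory=SupervoxelSpec)
    k_candidates: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    msi_connectivity: int = 6
    resample: ResampleSpec = field(default_factory=ResampleSpec)
    selection: FeatureSelectionSpec = field(default_factory=FeatureSelectionSpec)
    grid: ModelGridSpec = field(default_factory=ModelGridSpec)
    feature_table: str | None = None  # external feature table for train-only runs

    def __post_init__(self) -> None:
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ConfigError(f"unknown stages: {sorted(bad)}")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        def enc(v):
            if dataclasses.is_dataclass(v) and not isinstance(v, type):
                return {k: enc(x) for k, x in dataclasses.asdict(v).items()}
            if isinstance(v, (tuple, list)):
                return [enc(x) for x in v]
            if isinstance(v, dict):
                return {k: enc(x) for k, x in v.items()}
            if isinstance(v, np.generic):
                return v.item()
            return v

        return {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(d) - set(known)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kw = dict(d)
        for key, sub in (
            ("cohort", CohortRecipe),
            ("window", WindowSpec),
            ("supervoxels", SupervoxelSpec),
            ("resample", ResampleSpec),
            ("selection", FeatureSelectionSpec),
            ("grid", ModelGridSpec),
        ):
            if key in kw and isinstance(kw[key], dict):
                sub_kw = {
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in kw[key].items()
                }
                try:
                    kw[key] = sub(**sub_kw)
                except TypeError as e:
                    raise ConfigError(f"bad keys under {key!r}: {e}") from e
        for key in ("stages", "k_candidates", "lasso_alpha_grid"):
            if key in kw and isinstance(kw[key], list):
                kw[key] = tuple(kw[key])
        try:
            return cls(**kw)
        except TypeError as e:
            raise ConfigError(str(e)) from e

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stages: dict[str, dict] = field(default_factory=dict)

    def record(self, stage: str, checksum: str, cached: bool = False) -> None:
        self.stages[stage] = {
            "checksum": checksum,
            "cached": cached,
            "timestamp": time.time(),
        }

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "config_hash": self.config_hash,
                    "version": self.version,
                    "stages": self.stages,
                },
                indent=2,
            )
        )


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _df_checksum(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.to_csv(index=False, float_format="%.10g").encode()
    ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Library-level stage compositions
# ---------------------------------------------------------------------------

def extract_cohort_features(
    cohort: CohortResult,
    window: WindowSpec = WindowSpec(),
    resample_iso_mm: float | None = 1.0,
    svspec: SupervoxelSpec = SupervoxelSpec(),
    k_candidates=(1, 2, 3, 4, 5, 6),
    connectivity: int = 6,
    seed: int = 0,
):
    """Run preprocess + subregion discovery + MSI extraction for a cohort.

    The subregion mixture is fitted on pooled training-cohort supervoxel
    phenotypes only and applied unchanged to every case. Returns the MSI
    feature table (row-aligned with ``cohort.table``), the fitted subregion
    model, and a per-case subregion-proportion table.
    """
    table = cohort.table
    svmaps, hu_vols = [], []
    for vol, mask in zip(cohort.volumes, cohort.masks):
        vol_c, mask_c = crop_voi(vol, mask, margin_vox=2)
        if resample_iso_mm is not None and tuple(vol_c.spacing) != (resample_iso_mm,) * 3:
            vol_c = resample_isotropic(vol_c, (resample_iso_mm,) * 3)
            mask_c = resample_isotropic(mask_c, (resample_iso_mm,) * 3)
        unit = window_normalize(vol_c, window)
        svmaps.append(compute_supervoxels(unit, mask_c, svspec))
        hu_vols.append(vol_c)

    train_idx = np.flatnonzero((table["cohort"] == "train").to_numpy())
    pooled = pd.concat([svmaps[i].phenotypes for i in train_idx], ignore_index=True)
    model = fit_subregion_model(pooled, k_candidates=k_candidates, seed=seed)

    feat_rows, prop_rows = [], []
    for i, (svmap, hu) in enumerate(zip(svmaps, hu_vols)):
        labelmap = assign_subregions(svmap, model)
        feat_rows.append(msi_feature_vector(labelmap, connectivity=connectivity))
        st = subregion_stats(labelmap, hu)
        prop_rows.append(
            {
                **{f"proportion_{int(r.subregion)}": r.proportion for r in st.itertuples()},
                **{f"mean_hu_{int(r.subregion)}": r.mean_hu for r in st.itertuples()},
            }
        )
    features = pd.DataFrame(feat_rows, index=table.index)
    proportions = pd.DataFrame(prop_rows, index=table.index)
    return features, model, proportions


def train_and_evaluate(
    features: pd.DataFrame,
    table: pd.DataFrame,
    resample: ResampleSpec = ResampleSpec(),
    selection: FeatureSelectionSpec = FeatureSelectionSpec(),
    grid: ModelGridSpec = ModelGridSpec(),
    seed: int = 0,
):
    """The modeling harness on a ready feature table.

    Training-cohort rows are SMOTE-rebalanced, z-score parameters and the
    feature selection are fitted on that rebalanced training set only, the
    preprocessor×classifier grid is ranked on validation AUC, and the best
    candidate is evaluated on all three cohorts at the Youden cut-point
    derived from the training cohort.
    """
    y = (table["grade"] == "high").astype(int).to_numpy()
    masks = {c: (table["cohort"] == c).to_numpy() for c in ("train", "val", "test")}
    X = features.to_numpy(dtype=float)

    res_spec = dataclasses.replace(resample, seed=seed)
    Xt_bal, yt_bal = smote_resample(X[masks["train"]], y[masks["train"]], res_spec)
    (Zt, Zv, Ztest, Zall), zparams = zscore_fit_apply(
        Xt_bal, X[masks["val"]], X[masks["test"]], X
    )
    sel_spec = dataclasses.replace(selection, seed=seed)
    sel = select_features(
        pd.DataFrame(Zt, columns=features.columns), yt_bal, sel_spec
    )
    cols = [features.columns.get_loc(c) for c in sel.selected]

    grid_spec = dataclasses.replace(grid, seed=seed)
    result = grid_train(
        (Zt[:, cols], yt_bal), (Zv[:, cols], y[masks["val"]]), grid_spec
    )
    best = result.best

    probs = {c: best.predict_proba(Zall[masks[c]][:, cols]) for c in masks}
    threshold = youden_threshold(probs["train"], y[masks["train"]])
    reports = {
        c: evaluate_model(probs[c], y[masks[c]], threshold, cohort=c) for c in masks
    }
    dca = decision_curve(
        probs["test"], y[masks["test"]], np.linspace(0.05, 0.95, 19)
    )
    subgroups = None
    if "diameter_mm" in table.columns:
        sel_test = masks["test"]
        subgroups = subgroup_eval(
            probs["test"], y[sel_test], table.loc[sel_test, "diameter_mm"], threshold
        )
    return {
        "selection": sel,
        "grid": result,
        "threshold": threshold,
        "probs": probs,
        "labels": {c: y[masks[c]] for c in masks},
        "reports": reports,
        "decision_curve": dca,
        "subgroups": subgroups,
    }


def run_msi_experiment(recipe: CohortRecipe | None = None, seed: int = 0) -> dict:
    """Full synthetic experiment: cohort → MSI features → fitted MSI model.

    Convenience wrapper used by the examples and the acceptance workflow;
    returns the cohort, feature table, subregion model and evaluation
    results in one dictionary.
    """
    recipe = recipe or CohortRecipe(seed=seed)
    cohort = generate_cohort(recipe)
    features, model, proportions = extract_cohort_features(cohort, seed=seed)
    results = train_and_evaluate(features, cohort.table, seed=seed)
    return {
        "cohort": cohort,
        "features": features,
        "subregion_model": model,
        "proportions": proportions,
        **results,
    }


# ---------------------------------------------------------------------------
# Orchestrated, cached runs
# ---------------------------------------------------------------------------

def _upstream_hash(config: PipelineConfig) -> str:
    d = config.to_dict()
    keys = ["cohort", "window", "resample_iso_mm", "supervoxels", "k_candidates",
            "msi_connectivity", "seed"]
    return _hash_obj({k: d[k] for k in keys})


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the enabled stages in dependency order and write a manifest.

    The MSI feature table is cached under the run directory keyed by a hash
    of all upstream config; if present, the image stages are skipped. A
    train stage without a feature table (no cached table, extraction
    disabled, and no external table) raises :class:`DependencyError`.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=_hash_obj(config.to_dict()), version=__version__)
    config.to_yaml(out / "config.yaml")

    stages = set(config.stages)
    up_hash = _upstream_hash(config)
    feat_path = out / f"msi_features_{up_hash}.csv"
    table_path = out / f"cohort_table_{up_hash}.csv"

    features = table = None
    image_stages = {"simulate", "preprocess", "subregions", "msi"} & stages
    if image_stages:
        if feat_path.exists() and table_path.exists():
            features = pd.read_csv(feat_path)
            table = pd.read_csv(table_path)
            model_doc = json.loads((out / "subregion_model.json").read_text())
            for s, chk in (
                ("simulate", _df_checksum(table)),
                ("preprocess", _df_checksum(table)),
                ("subregions", _hash_obj(model_doc)),
                ("msi", _df_checksum(features)),
            ):
                if s in image_stages:
                    manifest.record(s, chk, cached=True)
        else:
            missing = {"simulate", "preprocess", "subregions", "msi"} - stages
            if missing:
                raise DependencyError(
                    f"stages {sorted(image_stages)} need disabled upstream "
                    f"stages {sorted(missing)}"
                )
            cohort = generate_cohort(dataclasses.replace(config.cohort, seed=config.seed))
            table = cohort.table
            manifest.record("simulate", _df_checksum(table))
            features, model, proportions = extract_cohort_features(
                cohort,
                window=config.window,
                resample_iso_mm=config.resample_iso_mm,
                svspec=config.supervoxels,
                k_candidates=config.k_candidates,
                connectivity=config.msi_connectivity,
                seed=config.seed,
            )
            (out / "subregion_model.json").write_text(
                json.dumps(model_to_dict(model), indent=2)
            )
            manifest.record("preprocess", _df_checksum(table))
            manifest.record("subregions", _hash_obj(model_to_dict(model)))
            manifest.record("msi", _df_checksum(features))
            features.to_csv(feat_path, index=False)
            table.to_csv(table_path, index=False)

    if "train" in stages or "evaluate" in stages:
        if features is None:
            if config.feature_table and Path(config.feature_table).exists():
                features = pd.read_csv(config.feature_table)
                table = pd.read_csv(table_path) if table_path.exists() else None
            elif feat_path.exists():
                features = pd.read_csv(feat_path)
                table = pd.read_csv(table_path)
            if features is None or table is None:
                raise DependencyError(
                    "train stage needs an MSI feature table: enable the "
                    "extraction stages or pass feature_table"
                )
        drop = [c for c in ("patient_id", "cohort", "grade") if c in features.columns]
        feat_only = features.drop(columns=drop)
        results = train_and_evaluate(
            feat_only,
            table,
            resample=config.resample,
            selection=config.selection,
            grid=config.grid,
            seed=config.seed,
        )
        results["grid"].ranking.to_csv(out / "grid_ranking.csv", index=False)
        manifest.record("train", _df_checksum(results["grid"].ranking))
        if "evaluate" in stages:
            report_rows = []
            for c, r in results["reports"].items():
                report_rows.append(
                    {
                        "cohort": c,
                        "n": r.n,
                        "auc": r.auc,
                        "auc_lo": r.auc_ci[0],
                        "auc_hi": r.auc_ci[1],
                        "accuracy": r.accuracy,
                        "sensitivity": r.sensitivity,
                        "specificity": r.specificity,
                        "ppv": r.ppv,
                        "npv": r.npv,
                        "brier": r.brier,
                        "threshold": r.threshold,
                    }
                )
            rep = pd.DataFrame(report_rows)
            rep.to_csv(out / "eval_report.csv", index=False)
            results["decision_curve"].to_csv(out / "decision_curve.csv", index=False)
            manifest.record("evaluate", _df_checksum(rep))

    manifest.to_json(out / "manifest.json")
    return manifest
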