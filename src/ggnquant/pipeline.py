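"""End-to-end orchestration: generate -> extract -> filter -> analyze.

The pipeline is a pure function of its configuration: a fixed config (with
its master seed) produces a byte-identical report bundle.  Outputs mirror
the structure of a quantitative-CT nodule study:

* ``cohort.csv``            — per-nodule metadata (class, invasion extent, seed)
* ``features.csv``          — observer-averaged feature table
* ``features_obs1/2.csv``   — per-observer tables (when observer noise > 0)
* ``icc.csv``               — interobserver ICC per feature
* ``anova.csv``             — class comparison with Bonferroni correction
* ``spearman.csv``          — correlation of each feature with invasion extent
* ``logistic.csv`` / ``selection_trace.json`` — stepwise model + trace
* ``roc_points.csv``        — ROC curve of the fitted model
* ``rule_evaluation.json``  — two-threshold rule confusion statistics
* ``exclusions.json``       — nodules removed by the solid-component filter
* ``report.json``           — everything above in one machine-readable bundle
* ``manifest.json``         — config, seeds and library versions
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .errors import SpecificationError, StageError
from .features import FEATURE_NAMES, average_observers, extract_features
from .imaging_io import filter_cohort, write_exclusion_log, write_table
from .phantom import (
    CohortSpec,
    cohort_metadata,
    generate_cohort,
    simulate_observers,
)
from .stats import (
    ThresholdRule,
    anova_with_posthoc,
    evaluate_rule,
    icc_two_observers,
    roc_auc,
    spearman_vs_invasion,
    stepwise_logistic,
    vif_screen,
)

#: Bonferroni family sizes: the two size variables form one family, the
#: seven histogram variables (skewness, kurtosis, five percentiles) another.
FAMILY_SIZES = {
    "size_lung_mm": 2,
    "size_mediastinal_mm": 2,
    "skewness": 7,
    "kurtosis": 7,
    "p2_5_hu": 7,
    "p25_hu": 7,
    "p50_hu": 7,
    "p75_hu": 7,
    "p97_5_hu": 7,
}

ANALYSIS_FEATURES = list(FEATURE_NAMES)


class CohortConfig(BaseModel):
    n_ais: int = 38
    n_mia: int = 61
    n_inv: int = 92
    voxel_spacing_mm: tuple[float, float, float] = (0.7, 0.7, 1.25)
    observer_noise: float = 1.0

    @field_validator("n_ais", "n_mia", "n_inv")
    @classmethod
    def _nonneg(cls, v: int) -> int:
        if v < 0:
            raise ValueError("class counts must be non-negative")
        return v


class RuleConfig(BaseModel):
    p75_cutoff_hu: float = -470.0
    entropy_cutoff_bits: float = 7.90


class PipelineConfig(BaseModel):
    """Validated YAML-backed configuration of a full pipeline run."""

    cohort: CohortConfig = Field(default_factory=CohortConfig)
    rule: RuleConfig = Field(default_factory=RuleConfig)
    master_seed: int = 0
    bin_width_hu: float = 1.0
    solid_threshold_hu: float = -160.0
    solid_size_limit_mm: float = 5.0
    vif_threshold: float = 10.0
    anova_entry_p: float = 0.10
    removal_p: float = 0.10
    n_bootstrap: int = 2000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.model_validate(raw)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"[{name}] {exc}") from exc
        return wrapper
    return deco


@_stage("generate")
def stage_generate(config: PipelineConfig):
    spec = CohortSpec(
        n_ais=config.cohort.n_ais,
        n_mia=config.cohort.n_mia,
        n_inv=config.cohort.n_inv,
        voxel_spacing_mm=tuple(config.cohort.voxel_spacing_mm),
        observer_noise=config.cohort.observer_noise,
        master_seed=config.master_seed,
    )
    return generate_cohort(spec)


@_stage("extract")
def stage_extract(
    nodules, config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame | None, pd.DataFrame | None]:
    """Feature tables: observer-averaged plus the two per-observer tables.

    With observer noise 0 the ground-truth mask is measured once and the
    per-observer tables are None.
    """
    noise = config.cohort.observer_noise
    rows_avg, rows_o1, rows_o2 = [], [], []
    for vol, mask, rec in nodules:
        if noise > 0:
            m1, m2 = simulate_observers(mask, noise, seed=rec["seed"] ^ 0x5EED)
            f1 = extract_features(vol, m1, config.bin_width_hu, config.solid_threshold_hu)
            f2 = extract_features(vol, m2, config.bin_width_hu, config.solid_threshold_hu)
            favg = average_observers(f1, f2)
            rows_o1.append({"nodule_id": rec["nodule_id"], **f1.as_dict()})
            rows_o2.append({"nodule_id": rec["nodule_id"], **f2.as_dict()})
        else:
            favg = extract_features(vol, mask, config.bin_width_hu, config.solid_threshold_hu)
        rows_avg.append({"nodule_id": rec["nodule_id"], **favg.as_dict()})
    avg = pd.DataFrame(rows_avg)
    o1 = pd.DataFrame(rows_o1) if rows_o1 else None
    o2 = pd.DataFrame(rows_o2) if rows_o2 else None
    return avg, o1, o2


@_stage("analyze")
def stage_analyze(
    meta: pd.DataFrame,
    features: pd.DataFrame,
    obs1: pd.DataFrame | None,
    obs2: pd.DataFrame | None,
    config: PipelineConfig,
) -> dict[str, Any]:
    table = meta.merge(features, on="nodule_id")
    if table["class_label"].nunique() < 2 or (table["class_label"] == "INV").sum() in (
        0,
        len(table),
    ):
        raise SpecificationError("single-class outcome: need invasive and non-invasive nodules")

    # interobserver agreement
    icc_rows = []
    if obs1 is not None and obs2 is not None:
        merged = obs1.merge(obs2, on="nodule_id", suffixes=("_o1", "_o2"))
        for feat in ANALYSIS_FEATURES:
            a = merged[f"{feat}_o1"].to_numpy(dtype=float)
            b = merged[f"{feat}_o2"].to_numpy(dtype=float)
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() < 5 or (np.var(a[ok]) == 0 and np.var(b[ok]) == 0):
                continue
            icc, (lo, hi) = icc_two_observers(a[ok], b[ok])
            icc_rows.append({"feature": feat, "icc": icc, "ci_low": lo, "ci_high": hi})

    # class comparison
    anova_rows = []
    groups = tuple(g for g in ("AIS", "MIA", "INV") if (table["class_label"] == g).sum() >= 2)
    for feat in ANALYSIS_FEATURES:
        try:
            row = anova_with_posthoc(
                table, feat, family_size=FAMILY_SIZES.get(feat, 1), groups=groups
            )
        except Exception:
            continue
        anova_rows.append(
            {
                "feature": feat,
                "f_statistic": row.f_statistic,
                "p_raw": row.p_raw,
                "p_corrected": row.p_corrected,
                "family_size": row.family_size,
                **{
                    f"p_{a.lower()}_vs_{b.lower()}": p
                    for (a, b), p in row.pairwise_p.items()
                },
            }
        )
    anova_df = pd.DataFrame(anova_rows)

    # correlation with invasion extent
    spearman_rows = []
    for feat in ANALYSIS_FEATURES:
        try:
            rho, p = spearman_vs_invasion(table, feat)
        except Exception:
            continue
        spearman_rows.append({"feature": feat, "rho": rho, "p": p})

    # candidate screen (raw ANOVA P < entry threshold) then VIF
    candidates = [
        r["feature"]
        for r in anova_rows
        if r["p_raw"] < config.anova_entry_p and table[r["feature"]].notna().all()
    ]
    vif_report = None
    if len(candidates) >= 2:
        vif_report = vif_screen(table, candidates, threshold=config.vif_threshold)
        candidates = vif_report.retained

    # stepwise logistic + ROC of the fitted model
    model = stepwise_logistic(
        table, candidates, removal_p=config.removal_p
    )
    labels = (table["class_label"] == "INV").to_numpy(dtype=int)
    roc_model = None
    if model.variables:
        scores = model.predict_proba(table)
        roc_model = roc_auc(
            scores, labels, n_boot=config.n_bootstrap, seed=config.master_seed + 101
        )

    # the two-threshold rule, evaluated on the cohort
    rule = ThresholdRule(
        p75_cutoff_hu=config.rule.p75_cutoff_hu,
        entropy_cutoff_bits=config.rule.entropy_cutoff_bits,
    )
    rule_eval = evaluate_rule(table, rule)
    rule_scores = (
        (table["p75_hu"] >= rule.p75_cutoff_hu)
        & (table["entropy_bits"] >= rule.entropy_cutoff_bits)
    ).to_numpy(dtype=float)
    roc_rule = roc_auc(
        rule_scores, labels, n_boot=config.n_bootstrap, seed=config.master_seed + 202
    )

    return {
        "icc": pd.DataFrame(icc_rows),
        "anova": anova_df,
        "spearman": pd.DataFrame(spearman_rows),
        "candidates": candidates,
        "vif": vif_report,
        "model": model,
        "roc_model": roc_model,
        "roc_rule": roc_rule,
        "rule_eval": rule_eval,
        "table": table,
    }


def _jsonable(x: Any) -> Any:
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, np.ndarray):
        return [_jsonable(v) for v in x.tolist()]
    if isinstance(x, (np.floating, float)):
        x = float(x)
        return None if math.isnan(x) else x
    if isinstance(x, (np.integer,)):
        return int(x)
    return x


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict[str, Any]:
    """Run the full chain and write the report bundle under ``out_dir``.

    Returns the in-memory analysis dict (tables as DataFrames).  Identical
    config produces byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    nodules = stage_generate(config)
    meta = cohort_metadata(nodules)
    features, obs1, obs2 = stage_extract(nodules, config)

    retained_meta, exclusion_log = filter_cohort(
        meta, features, solid_size_limit_mm=config.solid_size_limit_mm
    )
    keep = features["nodule_id"].isin(retained_meta["nodule_id"])
    features_kept = features.loc[keep].reset_index(drop=True)
    obs1 = obs1.loc[obs1["nodule_id"].isin(retained_meta["nodule_id"])] if obs1 is not None else None
    obs2 = obs2.loc[obs2["nodule_id"].isin(retained_meta["nodule_id"])] if obs2 is not None else None

    analysis = stage_analyze(retained_meta, features_kept, obs1, obs2, config)

    write_table(meta, out / "cohort.csv")
    write_table(features_kept, out / "features.csv")
    if obs1 is not None:
        write_table(obs1, out / "features_obs1.csv")
        write_table(obs2, out / "features_obs2.csv")
    write_exclusion_log(exclusion_log, out / "exclusions.json")
    write_table(analysis["icc"], out / "icc.csv")
    write_table(analysis["anova"], out / "anova.csv")
    write_table(analysis["spearman"], out / "spearman.csv")

    model = analysis["model"]
    logistic_rows = [
        {
            "variable": v,
            "odds_ratio": model.odds_ratios[v],
            "ci_low": model.ci_95[v][0],
            "ci_high": model.ci_95[v][1],
            "p": model.p_values[v],
        }
        for v in model.variables
    ]
    write_table(pd.DataFrame(logistic_rows), out / "logistic.csv")
    (out / "selection_trace.json").write_text(
        json.dumps(_jsonable(model.trace), indent=2), encoding="utf-8"
    )

    roc_model = analysis["roc_model"]
    if roc_model is not None:
        write_table(
            pd.DataFrame(
                {"fpr": roc_model.fpr, "tpr": roc_model.tpr, "threshold": roc_model.thresholds}
            ),
            out / "roc_points.csv",
        )
    (out / "rule_evaluation.json").write_text(
        json.dumps(_jsonable(analysis["rule_eval"]), indent=2, sort_keys=True),
        encoding="utf-8",
    )

    report = {
        "n_generated": len(meta),
        "n_retained": len(retained_meta),
        "candidates": analysis["candidates"],
        "selected_variables": model.variables,
        "odds_ratios": model.odds_ratios,
        "model_auc": roc_model.auc if roc_model is not None else None,
        "model_auc_ci": list(roc_model.ci_95) if roc_model is not None else None,
        "rule_auc": analysis["roc_rule"].auc,
        "rule_evaluation": analysis["rule_eval"],
    }
    (out / "report.json").write_text(
        json.dumps(_jsonable(report), indent=2, sort_keys=True), encoding="utf-8"
    )

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": _jsonable(config.model_dump()),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    return analysis
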