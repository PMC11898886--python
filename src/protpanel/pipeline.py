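"""End-to-end orchestration: simulate -> process -> stats -> AL -> explain.

``run_pipeline`` executes every stage on a simulated cohort and gathers a
JSON-serializable report: the Table-2-style significance calls, both
models' confusion matrices with accuracy and macro metrics, the query
histories, and the per-class top SHAP features.  Given the same config and
seed, the report is byte-identical across runs (no timestamps inside).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io
from .al import ALConfig, ALResult, run_al
from .assay import summarize_wells
from .explain import (
    cap_background,
    class_predict_fn,
    explanation_frame,
    shapley_exact,
    top_features,
)
from .metrics import accuracy, macro_metrics
from .models import save_model
from .panel import GROUPS
from .stats import compare_groups, comparison_frame
from .synthetic import CohortConfig, generate_cohort, generate_plates

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    plate_noise_sd: float = 5.0
    cv_threshold: float = 0.2
    al: dict | None = None            # extra ALConfig kwargs (k, budget, ...)
    explain_per_class: int = 4        # test samples explained per true class


def _config_hash(config: PipelineConfig, seed: int) -> str:
    payload = json.dumps(
        {
            "seed": seed,
            "plate_noise_sd": config.plate_noise_sd,
            "cv_threshold": config.cv_threshold,
            "al": config.al,
            "explain_per_class": config.explain_per_class,
            "cohort": {
                "n_healthy": config.cohort.n_healthy,
                "n_localized": config.cohort.n_localized,
                "n_metastatic": config.cohort.n_metastatic,
                "noise_model": config.cohort.noise_model,
                "panel": sorted(config.cohort.panel.group_means.items()),
            },
        },
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _al_section(result: ALResult) -> dict:
    mm = macro_metrics(result.confusion)
    return {
        "confusion": result.confusion.tolist(),
        "accuracy_pct": accuracy(result.confusion),
        "macro_sensitivity": round(mm["macro_sensitivity"], 4),
        "macro_specificity": round(mm["macro_specificity"], 4),
        "per_class_recall": {k: round(v, 4) for k, v in mm["per_class_recall"].items()},
        "n_queries": len(result.state.query_history),
        "final_test_accuracy": result.final_accuracy,
        "query_history": [
            {"iteration": q.iteration, "sample_id": q.sample_id,
             "confidence": round(q.confidence, 6)}
            for q in result.state.query_history
        ],
    }


def run_pipeline(
    config: PipelineConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> dict:
    """Run every stage and return (and optionally write) the report bundle."""
    config = config if config is not None else PipelineConfig()
    cohort_cfg = config.cohort
    cohort_cfg.seed = seed
    panel = cohort_cfg.panel
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def _save(frame, name):
        if out is not None:
            frame.to_csv(out / name, index=False)

    logger.info("simulating cohort (n=%d)", cohort_cfg.n_total)
    truth = generate_cohort(cohort_cfg)
    _save(truth, "cohort_truth.csv")

    logger.info("simulating plate readouts and summarizing wells")
    plates = generate_plates(
        truth, panel=panel, plate_noise_sd=config.plate_noise_sd, seed=seed
    )
    features, qc = summarize_wells(
        plates,
        cv_threshold=config.cv_threshold,
        panel=panel,
        groups=truth.set_index("sample_id")["group"],
    )
    _save(features, "features.csv")
    _save(qc, "qc_flags.csv")

    logger.info("group statistics")
    results = compare_groups(features, panel=panel)
    stats_frame = comparison_frame(results)
    _save(stats_frame, "comparisons.csv")

    al_sections = {}
    explanations = []
    top = {}
    for spec in ("hierarchical_knn", "two_layer_nn"):
        logger.info("active learning with %s", spec)
        al_cfg = ALConfig(model_spec=spec, **(config.al or {}))
        result = run_al(features, config=al_cfg, seed=seed, panel=panel)
        al_sections[spec] = _al_section(result)
        _save(result.learning_curve, f"learning_curve_{spec}.csv")
        if out is not None:
            save_model(result.state.model, out / f"model_{spec}.json")

        if spec == "hierarchical_knn":
            # SHAP on a few test samples per class, hierarchical model
            indexed = features.set_index("sample_id", drop=False)
            labeled = indexed.loc[result.state.labeled_ids]
            background = cap_background(labeled[panel.columns].to_numpy(float))
            test = indexed.loc[result.state.test_ids]
            model = result.state.model
            for cls in GROUPS:
                members = test[test["group"] == cls].head(config.explain_per_class)
                for _, row in members.iterrows():
                    x = row[panel.columns].to_numpy(float)
                    post = model.predict(x)
                    cls_pred = post.predicted_class
                    fn = class_predict_fn(model, GROUPS.index(cls_pred))
                    explanations.append(
                        shapley_exact(
                            fn, x, background,
                            sample_id=row["sample_id"],
                            explained_class=cls_pred,
                        )
                    )
            for cls in GROUPS:
                try:
                    ranking, top3 = top_features(explanations, cls, panel=panel)
                    top[cls] = {"ranking": ranking, "top3": top3}
                except ValueError:
                    top[cls] = {"ranking": [], "top3": []}
            _save(explanation_frame(explanations, panel=panel), "shap.csv")

    report = {
        "seed": seed,
        "config_hash": _config_hash(config, seed),
        "n_samples": int(len(features)),
        "group_counts": {g: int((features["group"] == g).sum()) for g in GROUPS},
        "statistics": {
            "n_tests": len(results),
            "calls": [
                {"biomarker": r.biomarker, "pair": r.pair,
                 "test_used": r.test_used, "p_value": float(r.p_value),
                 "call": r.call}
                for r in results
            ],
        },
        "active_learning": al_sections,
        "top_features": top,
    }
    if out is not None:
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        io.write_feature_table(features, out / "features.csv")
    return report
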