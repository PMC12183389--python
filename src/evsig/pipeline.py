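"""End-to-end orchestration of the biomarker-discovery analysis.

Stages run in a fixed order (simulate/load -> preprocess -> dep -> rank ->
classify -> score -> evaluate -> survival) under one seeded configuration;
every stage writes its artifacts into the output directory and is recorded in
a run manifest.  Identical config + seed give bit-identical metric outputs.
Stage outputs already present on disk are reused when ``resume`` is set.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_io import FourClassLabel, Group, derive_labels, load_dataset, write_dataset
from .dep_volcano import group_selector, volcano_frame, volcano_select
from .eval_stats import km_logrank, roc_auc, sensitivity_at_fixed_specificity
from .hybrid import CnnConfig, train_hybrid
from .lsboost import rank_biomarkers, rmse_correlation
from .marker_score import evaluate_combinations, fit_logistic_score, risk_classify, score_samples
from .preprocess import filter_group_presence, filter_min_individuals, impute_for_ml
from .split import stratified_split
from .synthetic import SyntheticConfig, generate_cohort, generate_survival

__all__ = ["RunManifest", "run_full_pipeline", "DEFAULT_CONFIG", "load_config"]

logger = logging.getLogger(__name__)

STAGES = ["simulate", "preprocess", "dep", "rank", "classify", "score", "evaluate", "survival"]

#: Every analysis threshold is a named key with its standard default.
DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "simulate": {},  # SyntheticConfig overrides; or use input: {matrix, annotations}
    "input": None,
    "preprocess": {"min_individuals": 10, "min_group_presence": 0.7, "impute": "median"},
    "dep": {"p": 0.05, "log2fc": 1.0},
    "rank": {
        "top_k": 10,
        "iterations": 50,
        "n_learners": 100,
        "learning_rate": 0.1,
        "target": "one_vs_rest",
    },
    "classify": {"markers": "top_k", "train_fraction": 0.7, "epochs": 150},
    "score": {"markers": "top4", "exclusion_p": 0.1, "labels": "bc_vs_hc"},
    "evaluate": {"fixed_specificity": 0.95, "bootstrap": 2000},
    "survival": {"risk_cutoff": 0.5},
}


@dataclass
class RunManifest:
    config_digest: str
    seed: int
    stage_outputs: dict[str, str] = field(default_factory=dict)
    versions: dict[str, str] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)
    failed_stage: str | None = None
    error: str | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_digest": self.config_digest,
                "seed": self.seed,
                "stage_outputs": self.stage_outputs,
                "versions": self.versions,
                "timings": self.timings,
                "failed_stage": self.failed_stage,
                "error": self.error,
            },
            indent=2,
            sort_keys=True,
        )


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    config = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            config = _merge(config, yaml.safe_load(fh) or {})
    if overrides:
        config = _merge(config, overrides)
    return config


def config_digest(config: dict) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _derive_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def run_full_pipeline(
    config_path: str | Path | None = None,
    out_dir: str | Path = "evsig_run",
    seed: int | None = None,
    config: dict | None = None,
    resume: bool = False,
) -> RunManifest:
    """Execute all stages; on a stage failure the manifest records the stages
    completed and the failing stage's error, then the exception propagates."""
    cfg = config if config is not None else load_config(config_path)
    if seed is not None:
        cfg["seed"] = int(seed)
    seed = int(cfg["seed"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_digest=config_digest(cfg),
        seed=seed,
        versions={"evsig": __version__, "numpy": np.__version__, "pandas": pd.__version__},
    )

    state: dict[str, Any] = {}
    try:
        for stage in STAGES:
            t0 = time.perf_counter()
            _run_stage(stage, cfg, seed, out, state, resume)
            manifest.timings[stage] = round(time.perf_counter() - t0, 3)
            manifest.stage_outputs[stage] = str(state[f"{stage}_output"])
            (out / "manifest.json").write_text(manifest.to_json())
    except Exception as err:
        manifest.failed_stage = stage
        manifest.error = f"{type(err).__name__}: {err}"
        (out / "manifest.json").write_text(manifest.to_json())
        raise
    return manifest


def _run_stage(stage, cfg, seed, out: Path, state: dict, resume: bool) -> None:
    fn = globals()[f"_stage_{stage}"]
    fn(cfg, seed, out, state, resume)


def _stage_simulate(cfg, seed, out: Path, state, resume) -> None:
    matrix_path = out / "matrix.tsv"
    ann_path = out / "annotations.tsv"
    if cfg.get("input"):
        matrix, annotations = load_dataset(cfg["input"]["matrix"], cfg["input"]["annotations"])
        state["truth"] = None
    elif resume and matrix_path.exists() and ann_path.exists():
        matrix, annotations = load_dataset(matrix_path, ann_path)
        state["truth"] = None
    else:
        sim_cfg = SyntheticConfig(**{**cfg.get("simulate", {}), "seed": _derive_seed(seed, "simulate")})
        matrix, annotations = generate_cohort(sim_cfg)
        write_dataset(matrix, annotations, matrix_path, ann_path)
        truth = {
            "planted": {
                p.protein_id: {k.value: v for k, v in p.log2_effect_per_class.items()}
                for p in sim_cfg.planted
            },
            "true_hr": sim_cfg.survival_true_hr,
        }
        _dump_json(truth, out / "truth.json")
        state["truth"] = truth
        state["sim_config"] = sim_cfg
    state["matrix"], state["annotations"] = matrix, annotations
    state["simulate_output"] = matrix_path


def _stage_preprocess(cfg, seed, out: Path, state, resume) -> None:
    p = cfg["preprocess"]
    matrix, annotations = state["matrix"], state["annotations"]
    m1, rep1 = filter_min_individuals(matrix, annotations, min_n=p["min_individuals"])
    m2, rep2 = filter_group_presence(m1, annotations, min_fraction=p["min_group_presence"])
    state["filtered"] = m2
    state["imputed"] = impute_for_ml(m2) if p.get("impute", "median") == "median" else m2
    report = pd.DataFrame(
        {
            "filter": ["min_individuals", "group_presence"],
            "rule": [rep1.rule, rep2.rule],
            "n_input": [rep1.n_input, rep2.n_input],
            "n_output": [rep1.n_output, rep2.n_output],
        }
    )
    path = out / "presence_filters.tsv"
    report.to_csv(path, sep="\t", index=False)
    state["preprocess_output"] = path


def _stage_dep(cfg, seed, out: Path, state, resume) -> None:
    d = cfg["dep"]
    rows = volcano_select(
        state["filtered"],
        state["annotations"],
        group_selector(Group.LUMINAL, Group.HER2, Group.TNBC),
        group_selector(Group.HC),
        p_thresh=d["p"],
        fc_log2_thresh=d["log2fc"],
    )
    df = volcano_frame(rows)
    path = out / "volcano_bc_vs_hc.tsv"
    df.to_csv(path, sep="\t", index=False)
    state["volcano"] = rows
    state["dep_output"] = path


def _stage_rank(cfg, seed, out: Path, state, resume) -> None:
    r = cfg["rank"]
    labels = derive_labels(state["annotations"])
    ranking = rank_biomarkers(
        state["imputed"],
        labels,
        k=r["top_k"],
        n_iterations=r["iterations"],
        seed=_derive_seed(seed, "rank"),
        n_learners=r["n_learners"],
        learning_rate=r["learning_rate"],
        target=r.get("target", "one_vs_rest"),
    )
    state["ranking"] = ranking
    path = out / "rmse_ranking.tsv"
    ranking.to_frame().to_csv(path, sep="\t", index=False)
    pd.DataFrame(ranking.iteration_rmse, columns=ranking.protein_ids).to_csv(
        out / "iteration_rmse.tsv", sep="\t", index=False
    )
    corr = rmse_correlation(ranking, top_k=r["top_k"])
    corr.to_csv(out / "rmse_correlation_top.tsv", sep="\t")
    state["rank_output"] = path


def _stage_classify(cfg, seed, out: Path, state, resume) -> None:
    c = cfg["classify"]
    labels = derive_labels(state["annotations"])
    markers = c.get("markers", "top_k")
    if markers == "top_k":
        markers = state["ranking"].top(cfg["rank"]["top_k"])
    elif markers == "top4":
        markers = state["ranking"].top(4)
    elif markers in ("all", None):
        markers = None
    split_seed = _derive_seed(seed, "classify")
    split = stratified_split(
        state["imputed"].sample_ids, labels, c["train_fraction"], seed=split_seed
    )
    cnn_cfg = CnnConfig(epochs=c.get("epochs", 150), seed=split_seed)
    model, report = train_hybrid(
        state["imputed"], labels, marker_subset=markers, split=split,
        cnn_config=cnn_cfg, seed=split_seed,
    )
    state["classifier"] = model
    path = out / "classification_report.json"
    _dump_json({"test": report.to_dict(), "train": model.train_report.to_dict()}, path)
    pd.DataFrame(
        report.confusion,
        index=[c.value for c in report.classes],
        columns=[c.value for c in report.classes],
    ).to_csv(out / "confusion_test.tsv", sep="\t")
    state["classify_output"] = path


def _stage_score(cfg, seed, out: Path, state, resume) -> None:
    s = cfg["score"]
    matrix = state["imputed"]
    annotations = state["annotations"]
    markers = s.get("markers", "top4")
    if markers == "top4":
        markers = state["ranking"].top(4)
    values = matrix.to_frame().T[markers]
    mode = s.get("labels", "bc_vs_hc")
    if mode == "tnbc_vs_hc":
        keep = [a.group in (Group.TNBC, Group.HC) for a in annotations]
        fit_values = values.loc[[a.sample_id for a, k in zip(annotations, keep) if k]]
        y = np.array([a.group == Group.TNBC for a, k in zip(annotations, keep) if k], dtype=int)
    else:
        fit_values = values
        y = np.array([a.group != Group.HC for a in annotations], dtype=int)
    evaluations = evaluate_combinations(markers, fit_values, y)
    best = next(e for e in evaluations if e.is_best)
    model = fit_logistic_score(fit_values[list(best.markers)], y, exclusion_p=s["exclusion_p"])
    scores = score_samples(model, values)
    state["score_model"] = model
    state["scores"] = scores
    state["combinations"] = evaluations
    logger.info(
        "logit(p) = %.3f + %s",
        model.intercept,
        " + ".join(f"{b:.3f}*{m}" for m, b in model.coefficients.items()),
    )
    path = out / "score_model.json"
    _dump_json(
        {
            "best_combination": list(best.markers),
            "intercept": model.intercept,
            "coefficients": model.coefficients,
            "excluded": model.excluded,
            "scale_branch": model.scale_branch,
            "combinations": [
                {"markers": list(e.markers), "auc": e.auc, "auc_se": e.auc_se, "is_best": e.is_best}
                for e in evaluations
            ],
        },
        path,
    )
    scores.to_frame().to_csv(out / "scores.tsv", sep="\t")
    state["score_output"] = path


def _stage_evaluate(cfg, seed, out: Path, state, resume) -> None:
    e = cfg["evaluate"]
    annotations = state["annotations"]
    scores = state["scores"]
    y = np.array([a.group != Group.HC for a in annotations], dtype=int)
    roc = roc_auc(scores.to_numpy(), y)
    sens, ci = sensitivity_at_fixed_specificity(
        roc, e["fixed_specificity"], n_boot=e["bootstrap"], seed=_derive_seed(seed, "evaluate")
    )
    tnbc = np.array([a.group == Group.TNBC for a in annotations])
    hc = np.array([a.group == Group.HC for a in annotations])
    sel = tnbc | hc
    roc_tnbc = roc_auc(scores.to_numpy()[sel], tnbc[sel].astype(int))
    sens_t, ci_t = sensitivity_at_fixed_specificity(
        roc_tnbc, e["fixed_specificity"], n_boot=e["bootstrap"],
        seed=_derive_seed(seed, "evaluate_tnbc"),
    )
    metrics = {
        "bc_vs_hc": {
            "auc": roc.auc, "auc_se": roc.auc_se, "ci95": list(roc.ci95),
            "sensitivity_at_fixed_specificity": sens, "sensitivity_ci95": list(ci),
        },
        "tnbc_vs_hc": {
            "auc": roc_tnbc.auc, "auc_se": roc_tnbc.auc_se, "ci95": list(roc_tnbc.ci95),
            "sensitivity_at_fixed_specificity": sens_t, "sensitivity_ci95": list(ci_t),
        },
        "fixed_specificity": e["fixed_specificity"],
    }
    path = out / "roc_metrics.json"
    _dump_json(metrics, path)
    state["evaluate_output"] = path


def _recurrence_scores(cfg, state) -> pd.Series:
    """Recurrence-risk score used for the prognostic 0.5-cutoff grouping.

    The diagnostic (cancer vs control) score saturates near 1 for patients,
    so prognosis uses the same best-combination markers refit against the
    recurrence outcome among TNBC patients, then applied to all patients."""
    annotations = state["annotations"]
    matrix = state["imputed"]
    markers = list(next(e for e in state["combinations"] if e.is_best).markers)
    values = matrix.to_frame().T[markers]
    tnbc = [a for a in annotations if a.group == Group.TNBC]
    y = np.array(
        [derive_labels([a])[0] == FourClassLabel.TNBC_RECUR for a in tnbc], dtype=int
    )
    if 0 < y.sum() < len(y):
        fit_vals = values.loc[[a.sample_id for a in tnbc]]
        model = fit_logistic_score(
            fit_vals, y, exclusion_p=cfg["score"]["exclusion_p"]
        )
        return score_samples(model, values)
    return state["scores"]  # degenerate outcome: fall back to diagnostic score


def _stage_survival(cfg, seed, out: Path, state, resume) -> None:
    cutoff = cfg["survival"]["risk_cutoff"]
    annotations = state["annotations"]
    scores = _recurrence_scores(cfg, state)
    if not any(a.has_survival for a in annotations if a.group != Group.HC):
        # synthetic branch: survival linked to the dichotomized score
        sim_cfg = state.get("sim_config") or SyntheticConfig(seed=_derive_seed(seed, "survival"))
        annotations = generate_survival(annotations, scores.to_dict(), sim_cfg)
        state["annotations"] = annotations
    patients = [a for a in annotations if a.group != Group.HC and a.has_survival]
    risk = np.array(
        [risk_classify(scores[a.sample_id], cutoff) == "high_risk" for a in patients]
    )
    metrics: dict[str, Any] = {"risk_cutoff": cutoff, "n_high_risk": int(risk.sum())}
    for endpoint in ("rfs", "os"):
        t = np.array([getattr(a, f"{endpoint}_time") for a in patients], dtype=float)
        ev = np.array([getattr(a, f"{endpoint}_event") for a in patients], dtype=bool)
        res = km_logrank(t, ev, risk.astype(int))
        metrics[endpoint] = {
            "logrank_chi2": res.logrank_chi2,
            "logrank_p": res.logrank_p,
            "hazard_ratio": res.hazard_ratio,
            "hr_ci95": list(res.hr_ci95),
            "hr_p": res.hr_p,
        }
        curves = []
        for grp, (tt, ss) in res.km_curves.items():
            curves.append(pd.DataFrame({"group": grp, "time": tt, "survival": ss}))
        pd.concat(curves, ignore_index=True).to_csv(
            out / f"km_{endpoint}.tsv", sep="\t", index=False
        )
    path = out / "survival_metrics.json"
    _dump_json(metrics, path)
    state["survival_output"] = path
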