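"""End-to-end pipeline driver with a structured run configuration and manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .classifiers import (
    METHODS,
    eval_frame,
    evaluate_classifiers,
    rank_diagnostics,
    rank_parental_analytes,
    select_ranking_model,
)
from .encoding import class_balance_filter, encode_panel
from .io import compare_trials, load_panel, save_panel
from .moderated import panel_contrasts
from .performance import (
    predict_hp_classification,
    predict_hp_regression,
    record_frame,
    standard_scenarios,
)
from .preprocess import build_predictor_matrix, redundancy_filter, removal_log_frame
from .simulate import SimConfig, simulate_panel

log = logging.getLogger("hybripred")

STAGES = ("load", "preprocess", "encode", "classify", "rank", "predict")


@dataclass
class RunConfig:
    """All pipeline parameters; defaults follow the published protocol."""

    profiles: str | None = None  # input paths; None -> simulate
    phenotypes: str | None = None
    simulate: dict = field(default_factory=dict)  # SimConfig overrides
    r_threshold: float = 0.85
    alpha: float = 0.05
    max_class_fraction: float = 0.75
    min_class_count: int = 4
    class_weights: dict = field(
        default_factory=lambda: {-2: 10.0, -1: 5.0, 0: 1.0, 1: 5.0, 2: 10.0})
    methods: tuple = METHODS
    classify_repetitions: int = 5
    classify_inner_repeats: int = 5
    predict_repetitions: int = 25
    predict_inner_repeats: int = 10
    threshold: str | float = "mean"
    grid: str = "full"
    rf_trees: int = 500
    importance: str = "auc"
    permute: bool = False
    seed: int = 0
    out_dir: str = "hybripred_run"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**d)
        if isinstance(cfg.class_weights, dict):
            cfg.class_weights = {int(k): float(v) for k, v in cfg.class_weights.items()}
        cfg.methods = tuple(cfg.methods)
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig | dict) -> dict:
    """Execute load -> preprocess -> encode -> classify -> rank -> predict.

    Every stage writes its outputs as CSV under the run directory; the
    manifest (JSON) records parameters, seed, per-stage timing and output
    checksums. A stage failure aborts with the stage name while keeping the
    outputs of the completed stages on disk.
    """
    cfg = RunConfig.from_dict(config) if isinstance(config, dict) else config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {k: v for k, v in dataclasses.asdict(cfg).items()
                       if k not in ("simulate",)},
        "stages": {},
    }
    state: dict = {}

    def stage(name: str, fn) -> None:
        t0 = time.time()
        log.info("stage %s ...", name)
        try:
            outputs = fn()
        except Exception as exc:
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        files = {}
        for fname, frame in outputs.items():
            path = out / fname
            frame.to_csv(path, index=False)
            files[fname] = _sha256(path)
        manifest["stages"][name] = {
            "status": "ok", "seconds": round(time.time() - t0, 3), "outputs": files}

    def do_load() -> dict:
        if cfg.profiles is not None:
            design, profiles, pheno = load_panel(cfg.profiles, cfg.phenotypes)
        else:
            sim = SimConfig(**{"seed": cfg.seed, **cfg.simulate})
            design, profiles, pheno, truth = simulate_panel(sim)
            state["truth"] = truth
            (out / "ground_truth.json").write_text(json.dumps({
                "causal_columns": truth.causal_columns,
                "causal_weights": truth.causal_weights,
                "informative_analytes": truth.informative_analytes,
            }, indent=2))
            save_panel(design, profiles, pheno,
                       out / "profiles.csv", out / "phenotypes.csv")
        state.update(design=design, profiles=profiles, pheno=pheno)
        rep_counts = profiles.genotype_of.value_counts()
        manifest["panel"] = {
            "dents": len(design.dents), "flints": len(design.flints),
            "hybrids": len(design), "phenotyped": len(pheno) if pheno is not None else 0,
            "analytes": profiles.n_analytes,
            "replicates_min": int(rep_counts.min()),
            "replicates_max": int(rep_counts.max()),
        }
        if pheno is not None and pheno.trial.nunique() == 2:
            cmp_ = compare_trials(pheno)
            manifest["trial_comparison"] = {
                "t": cmp_.t, "p": cmp_.p, "groups": cmp_.groups}
        return {}

    def do_preprocess() -> dict:
        retained, rlog = redundancy_filter(state["profiles"], cfg.r_threshold)
        X_DF = build_predictor_matrix(state["design"], state["profiles"], retained)
        state.update(retained=retained, X_DF=X_DF)
        manifest["preprocess"] = {
            "retained_analytes": len(retained), "removed": len(rlog),
            "predictor_columns": X_DF.values.shape[1]}
        return {"removal_log.csv": removal_log_frame(rlog),
                "predictor_matrix.csv": X_DF.values.reset_index(names="cross")}

    def do_encode() -> dict:
        contrasts = panel_contrasts(state["design"], state["profiles"],
                                    analytes=state["retained"])
        T0 = encode_panel(contrasts, alpha=cfg.alpha)
        T, decisions = class_balance_filter(
            T0, cfg.max_class_fraction, cfg.min_class_count)
        state.update(T=T, T_raw=T0)
        manifest["encode"] = {
            "encoded_analytes": T.labels.shape[1],
            "excluded_hybrid_events": sum(len(v) for v in T.excluded_hybrids.values())}
        comp = pd.DataFrame(
            [{"analyte": d.analyte, "kept": d.kept, "reason": d.reason,
              **{f"n_{c}": d.counts.get(c, 0) for c in (-2, -1, 0, 1, 2)}}
             for d in decisions])
        return {"labels.csv": T.labels.reset_index(names="cross"),
                "class_composition.csv": comp}

    def do_classify() -> dict:
        if state["T"].labels.shape[1] == 0:
            raise ValueError("no encoded analyte passed the class-balance filter")
        evals = evaluate_classifiers(
            state["X_DF"], state["T"], methods=cfg.methods,
            weights=cfg.class_weights, repetitions=cfg.classify_repetitions,
            permute=cfg.permute, seed=cfg.seed,
            inner_repeats=cfg.classify_inner_repeats, grid=cfg.grid,
            rf_trees=cfg.rf_trees)
        sel = select_ranking_model(evals)
        state.update(evals=evals, selected=sel)
        manifest["classify"] = {"selected_method": sel.method,
                                "evaluations": len(evals)}
        return {"kappa_evaluations.csv": eval_frame(evals).drop(columns=["best_params"]),
                "cv_table.csv": sel.cv_table}

    def do_rank() -> dict:
        method = state["selected"].method if "selected" in state else "SVM-W"
        ranking = rank_parental_analytes(
            state["X_DF"], state["T"], method=method,
            importance=cfg.importance, weights=cfg.class_weights, seed=cfg.seed)
        diag = rank_diagnostics(ranking)
        state["ranking"] = ranking
        manifest["rank"] = {"kendall_tau": diag.kendall_tau,
                            "kendall_p": diag.kendall_p}
        return {"ranking.csv": ranking.table,
                "rank_cumulative.csv": diag.cumulative}

    def do_predict() -> dict:
        if state["pheno"] is None:
            raise ValueError("no phenotypes: cannot predict hybrid performance")
        scen = standard_scenarios(state["X_DF"].values.shape[1])
        reg = predict_hp_regression(
            state["X_DF"], state["pheno"], state["ranking"], scenarios=scen,
            repetitions=cfg.predict_repetitions, seed=cfg.seed,
            inner_repeats=cfg.predict_inner_repeats, grid=cfg.grid)
        clf = predict_hp_classification(
            state["X_DF"], state["pheno"], state["ranking"], scenarios=scen,
            threshold=cfg.threshold, repetitions=cfg.predict_repetitions,
            seed=cfg.seed, inner_repeats=cfg.predict_inner_repeats, grid=cfg.grid)
        state.update(reg_records=reg, clf_records=clf)
        df = record_frame(reg + clf)
        med = (df[df["mode"] == "regression"].groupby("scenario")["r2"]
               .median().to_dict())
        manifest["predict"] = {"median_r2": med}
        return {"hp_evaluations.csv": df}

    for name, fn in zip(STAGES, (do_load, do_preprocess, do_encode,
                                 do_classify, do_rank, do_predict)):
        stage(name, fn)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    state["manifest"] = manifest
    return state
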