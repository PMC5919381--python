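"""Quantitative (SVR) and qualitative (SVM) hybrid-performance prediction
from ranked parental-analyte subsets.

Thirteen scenarios probe how predictive power depends on rank position: the
top/bottom five columns, five drawn at random from sliding top/bottom
windows, five drawn from the whole ranking, all columns, and all columns
with the biomass permuted (the no-signal reference). Predictability is the
squared Pearson correlation between predicted and observed biomass on the
held-out 20%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.metrics import make_scorer, roc_auc_score
from sklearn.model_selection import (
    GridSearchCV,
    KFold,
    RepeatedKFold,
    RepeatedStratifiedKFold,
    train_test_split,
)
from sklearn.svm import SVC, SVR

from .classifiers import AnalyteRanking, kappa_score, median_heuristic_gamma
from .datamodel import PhenotypeTable
from .preprocess import PredictorMatrix


def squared_pearson(y_true, y_pred) -> float:
    """R^2 as the squared Pearson correlation (0 for constant predictions)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        return 0.0
    return float(np.corrcoef(y_true, y_pred)[0, 1] ** 2)


_R2_SCORER = make_scorer(squared_pearson)
_KAPPA_SCORER = make_scorer(kappa_score)


@dataclass
class ScenarioSpec:
    """One feature-subset scenario over the analyte ranking."""

    id: str
    kind: str  # top | bottom | random_top | random_bottom | random_all | all | all_perm
    window: int = 0  # rank window for the random_* kinds
    size: int = 5

    def columns(self, ranking: AnalyteRanking, rng: np.random.Generator) -> list[str]:
        ordered = ranking.ordered_columns
        n = len(ordered)
        if self.kind in ("all", "all_perm"):
            return list(ordered)
        if self.kind == "top":
            return ordered[: self.size]
        if self.kind == "bottom":
            return ordered[-self.size:]
        if self.kind == "random_all":
            pool = ordered
        elif self.kind == "random_top":
            pool = ordered[: self.window]
        elif self.kind == "random_bottom":
            pool = ordered[-self.window:]
        else:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if len(pool) < self.size:
            raise ValueError(
                f"scenario {self.id!r}: window of {len(pool)} columns is smaller "
                f"than the subset size {self.size}")
        return list(rng.choice(pool, size=self.size, replace=False))


def standard_scenarios(n_columns: int, size: int = 5,
                       windows: tuple[int, ...] = (10, 20, 50, 100)) -> list[ScenarioSpec]:
    """The thirteen canonical scenarios; windows wider than the ranking are dropped."""
    windows = tuple(w for w in windows if w <= n_columns)
    specs = [ScenarioSpec("Top5", "top", size=size)]
    specs += [ScenarioSpec(f"5ofTop{w}", "random_top", window=w, size=size) for w in windows]
    specs += [ScenarioSpec(f"5ofBottom{w}", "random_bottom", window=w, size=size)
              for w in reversed(windows)]
    specs += [ScenarioSpec("Bottom5", "bottom", size=size),
              ScenarioSpec("Random5", "random_all", size=size),
              ScenarioSpec("All", "all"),
              ScenarioSpec("All-perm", "all_perm")]
    return specs


@dataclass
class EvaluationRecord:
    scenario: str
    repetition: int
    mode: str  # "regression" | "classification"
    r2: float | None = None
    r2_residual: float | None = None  # 1 - SSE/SST alternative
    accuracy: float | None = None
    kappa: float | None = None
    auc: float | None = None
    threshold: float | None = None
    probabilities: pd.Series | None = field(default=None, repr=False)
    truth: pd.Series | None = field(default=None, repr=False)
    columns: list[str] = field(default_factory=list, repr=False)


def record_frame(records: list[EvaluationRecord]) -> pd.DataFrame:
    keep = ("scenario", "repetition", "mode", "r2", "r2_residual",
            "accuracy", "kappa", "auc", "threshold")
    return pd.DataFrame([{k: getattr(r, k) for k in keep} for r in records])


def _seed(master: int, *parts: int) -> int:
    ss = np.random.SeedSequence([int(master), *[int(p) for p in parts]])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _svr_grid(X: np.ndarray, grid: str) -> dict[str, list]:
    g0 = median_heuristic_gamma(X)
    costs = [2.0 ** k for k in (range(-2, 7, 2) if grid == "small" else range(-2, 7))]
    gammas = [g0 * m for m in ((1.0, 2.0) if grid == "small" else (0.5, 1.0, 2.0))]
    return {"C": costs, "gamma": gammas}


def _aligned(X_DF: PredictorMatrix, pheno: PhenotypeTable) -> tuple[pd.DataFrame, pd.Series]:
    common = [h for h in X_DF.values.index if h in pheno.biomass.index]
    return X_DF.values.loc[common], pheno.biomass[common]


def predict_hp_regression(
    X_DF: PredictorMatrix,
    pheno: PhenotypeTable,
    ranking: AnalyteRanking,
    scenarios: list[ScenarioSpec] | None = None,
    repetitions: int = 25,
    seed: int = 0,
    test_fraction: float = 0.2,
    inner_folds: int = 3,
    inner_repeats: int = 10,
    grid: str = "full",
) -> list[EvaluationRecord]:
    """Support-vector regression of biomass for every scenario x repetition.

    Per repetition: a fresh random 80/20 split, a fresh random draw of the
    scenario's column subset, inner repeated 3-fold tuning maximizing the
    squared-correlation R^2, and the test R^2 of the refit winner. The
    permuted scenario shuffles biomass once per repetition before splitting.
    """
    X_all, y_all = _aligned(X_DF, pheno)
    scenarios = scenarios or standard_scenarios(X_all.shape[1])
    records: list[EvaluationRecord] = []
    for si, spec in enumerate(scenarios):
        for rep in range(repetitions):
            s = _seed(seed, 11, si, rep)
            rng = np.random.default_rng(s)
            cols = spec.columns(ranking, rng)
            X = X_all[cols].to_numpy()
            y = y_all.to_numpy()
            if spec.kind == "all_perm":
                y = rng.permutation(y)
            Xtr, Xte, ytr, yte = train_test_split(
                X, y, test_size=test_fraction, random_state=s)
            cv = (RepeatedKFold(n_splits=inner_folds, n_repeats=inner_repeats,
                                random_state=s)
                  if inner_repeats > 1 else
                  KFold(n_splits=inner_folds, shuffle=True, random_state=s))
            gs = GridSearchCV(SVR(kernel="rbf"), _svr_grid(Xtr, grid),
                              scoring=_R2_SCORER, cv=cv, n_jobs=1)
            gs.fit(Xtr, ytr)
            pred = gs.predict(Xte)
            sst = ((yte - yte.mean()) ** 2).sum()
            records.append(EvaluationRecord(
                scenario=spec.id, repetition=rep, mode="regression",
                r2=squared_pearson(yte, pred),
                r2_residual=float(1.0 - ((yte - pred) ** 2).sum() / sst) if sst > 0 else None,
                columns=cols))
    return records


def resolve_threshold(pheno: PhenotypeTable, threshold: float | str) -> float:
    if isinstance(threshold, str):
        if threshold != "mean":
            raise ValueError("threshold must be a number or 'mean'")
        return float(pheno.biomass.mean())
    t = float(threshold)
    if not pheno.biomass.min() <= t <= pheno.biomass.max():
        raise ValueError(f"threshold {t} outside the observed biomass range")
    return t


def predict_hp_classification(
    X_DF: PredictorMatrix,
    pheno: PhenotypeTable,
    ranking: AnalyteRanking,
    scenarios: list[ScenarioSpec] | None = None,
    threshold: float | str = "mean",
    repetitions: int = 25,
    seed: int = 0,
    test_fraction: float = 0.2,
    inner_folds: int = 3,
    inner_repeats: int = 10,
    grid: str = "full",
) -> list[EvaluationRecord]:
    """Good/bad performer classification (biomass >= threshold is 'good').

    Same partitioning scheme as the regression path but with stratified
    splits; records test accuracy, Kappa, ROC AUC and the good-class
    probabilities used downstream for precision-recall curves.
    """
    X_all, y_cont = _aligned(X_DF, pheno)
    thr = resolve_threshold(pheno, threshold)
    y_bin_all = (y_cont >= thr).astype(int)
    if y_bin_all.nunique() < 2:
        raise ValueError(f"threshold {thr} leaves a single class")
    scenarios = scenarios or standard_scenarios(X_all.shape[1])
    records: list[EvaluationRecord] = []
    for si, spec in enumerate(scenarios):
        for rep in range(repetitions):
            s = _seed(seed, 13, si, rep)
            rng = np.random.default_rng(s)
            cols = spec.columns(ranking, rng)
            X = X_all[cols].to_numpy()
            y = y_bin_all.to_numpy()
            if spec.kind == "all_perm":
                y = rng.permutation(y)
            Xtr, Xte, ytr, yte = train_test_split(
                X, y, test_size=test_fraction, stratify=y, random_state=s)
            cv = RepeatedStratifiedKFold(n_splits=inner_folds,
                                         n_repeats=inner_repeats, random_state=s)
            # radial SVC with Platt-scaled class probabilities
            est = CalibratedClassifierCV(SVC(kernel="rbf"), method="sigmoid",
                                         cv=3, ensemble=False)
            param_grid = {f"estimator__{k}": v
                          for k, v in _svr_grid(Xtr, grid).items()}
            gs = GridSearchCV(est, param_grid, scoring="accuracy", cv=cv, n_jobs=1)
            gs.fit(Xtr, ytr)
            pred = gs.predict(Xte)
            prob = gs.predict_proba(Xte)[:, list(gs.best_estimator_.classes_).index(1)]
            records.append(EvaluationRecord(
                scenario=spec.id, repetition=rep, mode="classification",
                accuracy=float((pred == yte).mean()),
                kappa=kappa_score(yte, pred),
                auc=float(roc_auc_score(yte, prob)) if len(np.unique(yte)) == 2 else None,
                threshold=thr,
                probabilities=pd.Series(prob),
                truth=pd.Series(yte),
                columns=cols))
    return records


def precision_recall(
    probabilities: np.ndarray,
    truth: np.ndarray,
    cutoffs: np.ndarray | None = None,
) -> pd.DataFrame:
    """Precision and recall of the good class over a probability-cutoff grid.

    Predicted good means probability >= cutoff. When no sample is predicted
    good, precision is reported as NaN (absent), not 0.
    """
    prob = np.asarray(probabilities, dtype=float)
    y = np.asarray(truth).astype(int)
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in the truth labels")
    if cutoffs is None:
        cutoffs = np.linspace(0.0, 1.0, 101)
    rows = []
    for c in cutoffs:
        pred = prob >= c
        tp = int(((pred) & (y == 1)).sum())
        fp = int(((pred) & (y == 0)).sum())
        fn = int((~pred & (y == 1)).sum())
        precision = tp / (tp + fp) if (tp + fp) > 0 else np.nan
        recall = tp / (tp + fn)
        rows.append({"cutoff": float(c), "precision": precision, "recall": recall})
    return pd.DataFrame(rows)


def pr_at_cutoff(records: list[EvaluationRecord], scenario: str,
                 cutoff: float = 0.5) -> tuple[float, float]:
    """Pooled precision/recall at one cutoff over a scenario's test folds."""
    prob = np.concatenate([r.probabilities.to_numpy() for r in records
                           if r.scenario == scenario and r.probabilities is not None])
    y = np.concatenate([r.truth.to_numpy() for r in records
                        if r.scenario == scenario and r.truth is not None])
    pr = precision_recall(prob, y, cutoffs=np.array([cutoff]))
    return float(pr["precision"].iloc[0]), float(pr["recall"].iloc[0])


def threshold_sweep(
    X_DF: PredictorMatrix,
    pheno: PhenotypeTable,
    ranking: AnalyteRanking,
    n_thresholds: int = 9,
    scenario: ScenarioSpec | None = None,
    repetitions: int = 10,
    seed: int = 0,
    grid: str = "small",
    inner_repeats: int = 2,
) -> pd.DataFrame:
    """Accuracy and Kappa across evenly-spaced biomass thresholds (mean included).

    Thresholds are centred on the mean and spread symmetrically inside the
    observed biomass range; a threshold that empties a class is reported as
    degenerate rather than evaluated.
    """
    spec = scenario or ScenarioSpec("Top5", "top")
    b = pheno.biomass
    mu = float(b.mean())
    span = 0.9 * min(mu - float(b.min()), float(b.max()) - mu)
    thresholds = mu + np.linspace(-span, span, n_thresholds)
    rows = []
    for ti, thr in enumerate(thresholds):
        y_bin = (b >= thr).astype(int)
        if y_bin.nunique() < 2 or y_bin.value_counts().min() < 4:
            rows.append({"threshold": float(thr), "accuracy": np.nan,
                         "kappa": np.nan, "degenerate": True})
            continue
        recs = predict_hp_classification(
            X_DF, pheno, ranking, scenarios=[spec], threshold=float(thr),
            repetitions=repetitions, seed=_seed(seed, 17, ti), grid=grid,
            inner_repeats=inner_repeats)
        df = record_frame(recs)
        rows.append({"threshold": float(thr),
                     "accuracy": float(df["accuracy"].median()),
                     "kappa": float(df["kappa"].median()),
                     "degenerate": False})
    return pd.DataFrame(rows)
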