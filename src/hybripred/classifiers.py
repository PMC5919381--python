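"""Multi-class classifiers of mIP labels from parental profiles, and the
parental-analyte ranking they induce.

Seven classifier families are compared: PLS-DA, multinomial elastic net
(glmnet-style), PLS-RF, radial SVM with and without class-specific weights,
and random forests with and without class weights. Models are tuned and
compared on Cohen's Kappa; the family with the smallest coefficient of
variation of test Kappa over all encoded analytes supplies the variable
importances from which parental analytes are ranked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import make_scorer
from sklearn.model_selection import (
    GridSearchCV,
    RepeatedStratifiedKFold,
    train_test_split,
)
from sklearn.svm import SVC
from sklearn.utils.multiclass import unique_labels

from .encoding import InheritanceMatrix
from .preprocess import PredictorMatrix

METHODS = ("PLS-DA", "glmnet", "PLS-RF", "SVM", "SVM-W", "RF", "RF-W")

#: symmetric misclassification weights per mIP class (additivity cheapest)
DEFAULT_CLASS_WEIGHTS = {-2: 10.0, -1: 5.0, 0: 1.0, 1: 5.0, 2: 10.0}


def cohen_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement from a k x k confusion-count matrix.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed accuracy and p_e
    the marginal-product expected accuracy. The degenerate single-class case
    (p_e = 1) returns 0.
    """
    c = np.asarray(confusion, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1] or c.size == 0:
        raise ValueError("confusion matrix must be square and non-empty")
    if (c < 0).any():
        raise ValueError("confusion counts must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValueError("confusion matrix has zero total count")
    po = np.trace(c) / total
    pe = float((c.sum(axis=1) / total) @ (c.sum(axis=0) / total))
    if pe >= 1.0:
        return 0.0
    return float((po - pe) / (1.0 - pe))


def kappa_score(y_true, y_pred) -> float:
    """Cohen's Kappa from label vectors (confusion built over the label union)."""
    labels = unique_labels(y_true, y_pred)
    idx = {lab: i for i, lab in enumerate(labels)}
    c = np.zeros((len(labels), len(labels)))
    for t, p in zip(y_true, y_pred):
        c[idx[t], idx[p]] += 1
    return cohen_kappa(c)


_KAPPA_SCORER = make_scorer(kappa_score)


class PLSDAClassifier(ClassifierMixin, BaseEstimator):
    """Linear discriminant analysis on partial-least-squares scores.

    The label vector is one-hot encoded, a PLS regression extracts
    ``n_components`` latent directions, and an LDA is fit on the scores.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.sort(np.unique(y))
        Y = (y[:, None] == self.classes_[None, :]).astype(float)
        k = min(self.n_components, X.shape[1], X.shape[0] - 1)
        self._pls = PLSRegression(n_components=max(1, k), scale=False)
        self._pls.fit(X, Y)
        self._lda = LinearDiscriminantAnalysis()
        self._lda.fit(self._pls.transform(X), y)
        return self

    def predict(self, X):
        return self._lda.predict(self._pls.transform(np.asarray(X, dtype=float)))

    def predict_proba(self, X):
        return self._lda.predict_proba(self._pls.transform(np.asarray(X, dtype=float)))


class PLSRFClassifier(ClassifierMixin, BaseEstimator):
    """Random forest on partial-least-squares scores."""

    def __init__(self, n_components: int = 2, max_features: float = 1.0,
                 n_estimators: int = 500, random_state: int | None = None):
        self.n_components = n_components
        self.max_features = max_features
        self.n_estimators = n_estimators
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.sort(np.unique(y))
        Y = (y[:, None] == self.classes_[None, :]).astype(float)
        k = min(self.n_components, X.shape[1], X.shape[0] - 1)
        self._pls = PLSRegression(n_components=max(1, k), scale=False)
        self._pls.fit(X, Y)
        self._rf = RandomForestClassifier(
            n_estimators=self.n_estimators, max_features=self.max_features,
            random_state=self.random_state)
        self._rf.fit(self._pls.transform(X), y)
        return self

    def predict(self, X):
        return self._rf.predict(self._pls.transform(np.asarray(X, dtype=float)))

    def predict_proba(self, X):
        return self._rf.predict_proba(self._pls.transform(np.asarray(X, dtype=float)))


def median_heuristic_gamma(X: np.ndarray) -> float:
    """RBF kernel width 1 / median squared Euclidean distance."""
    X = np.asarray(X, dtype=float)
    n = min(len(X), 400)
    sq = ((X[:n, None, :] - X[None, :n, :]) ** 2).sum(axis=-1)
    med = np.median(sq[np.triu_indices(n, k=1)])
    return 1.0 / med if med > 0 else 1.0


def _class_weight_dict(weights: dict[int, float], classes: np.ndarray) -> dict:
    return {int(c): float(weights.get(int(c), 1.0)) for c in classes}


def build_classifier(
    method: str,
    X: np.ndarray,
    classes: np.ndarray,
    weights: dict[int, float] | None = None,
    seed: int = 0,
    grid: str = "full",
    rf_trees: int = 500,
) -> tuple[BaseEstimator, dict[str, list]]:
    """Estimator plus hyperparameter grid for one classifier family."""
    weights = weights or DEFAULT_CLASS_WEIGHTS
    p = X.shape[1]
    small = grid == "small"
    gamma0 = median_heuristic_gamma(X)
    gammas = [gamma0 * m for m in ((0.5, 1.0, 2.0) if not small else (1.0, 2.0))]
    costs = [2.0 ** k for k in (range(-2, 7) if not small else (-1, 1, 3, 5))]
    comps = list(range(1, 11) if not small else (2, 4, 6))
    mtry = sorted({max(1, int(round(np.sqrt(p) * m))) for m in (0.5, 1.0, 2.0)})
    cw = _class_weight_dict(weights, classes)

    if method == "PLS-DA":
        return PLSDAClassifier(), {"n_components": comps}
    if method == "glmnet":
        est = LogisticRegression(solver="saga", l1_ratio=0.5,
                                 max_iter=2000, tol=1e-3)
        alphas = [0.1 * k for k in range(1, 11)] if not small else [0.1, 0.55, 1.0]
        cs = list(np.logspace(-2, 1, 6 if not small else 3))
        return est, {"l1_ratio": alphas, "C": cs}
    if method == "PLS-RF":
        est = PLSRFClassifier(n_estimators=rf_trees, random_state=seed)
        return est, {"n_components": comps, "max_features": [0.5, 1.0]}
    if method in ("SVM", "SVM-W"):
        est = SVC(kernel="rbf", class_weight=cw if method == "SVM-W" else None)
        return est, {"C": costs, "gamma": gammas}
    if method in ("RF", "RF-W"):
        est = RandomForestClassifier(
            n_estimators=rf_trees, random_state=seed,
            class_weight=cw if method == "RF-W" else None)
        return est, {"max_features": mtry, "min_samples_leaf": [1, 3]}
    raise ValueError(f"unknown method {method!r}")


@dataclass
class ModelEval:
    method: str
    analyte: str
    repetition: int
    kappa: float
    best_params: dict
    permuted: bool


def _combo_seed(master: int, *parts: int) -> int:
    ss = np.random.SeedSequence([int(master), *[int(p) for p in parts]])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def evaluate_classifiers(
    X_DF: PredictorMatrix,
    T: InheritanceMatrix,
    methods: tuple[str, ...] = METHODS,
    weights: dict[int, float] | None = None,
    repetitions: int = 5,
    permute: bool = False,
    seed: int = 0,
    train_fraction: float = 0.75,
    inner_folds: int = 3,
    inner_repeats: int = 5,
    grid: str = "full",
    rf_trees: int = 500,
) -> list[ModelEval]:
    """Tune and test every (method, encoded analyte, repetition) combination.

    Per combination: a stratified ``train_fraction`` split, a grid search
    maximizing inner cross-validated Kappa (``inner_folds``-fold repeated
    ``inner_repeats`` times), and the test Kappa of the refit winner. With
    ``permute=True`` each analyte's labels are randomly permuted once before
    the whole procedure, giving the no-signal reference distribution.
    Analyte/repetition combinations whose strata cannot fill the folds are
    skipped (the class-balance filter makes this rare).
    """
    results: list[ModelEval] = []
    analytes = list(T.labels.columns)
    for ai, analyte in enumerate(analytes):
        y_full = T.label_vector(analyte)
        X_full = X_DF.values.loc[y_full.index].to_numpy()
        y = y_full.to_numpy()
        if permute:
            rng = np.random.default_rng(_combo_seed(seed, 9999, ai))
            y = rng.permutation(y)
        classes = np.sort(np.unique(y))
        for mi, method in enumerate(methods):
            for rep in range(repetitions):
                s = _combo_seed(seed, mi, ai, rep, int(permute))
                try:
                    Xtr, Xte, ytr, yte = train_test_split(
                        X_full, y, train_size=train_fraction,
                        stratify=y, random_state=s)
                    est, param_grid = build_classifier(
                        method, Xtr, classes, weights, seed=s,
                        grid=grid, rf_trees=rf_trees)
                    cv = RepeatedStratifiedKFold(
                        n_splits=inner_folds, n_repeats=inner_repeats,
                        random_state=s)
                    gs = GridSearchCV(est, param_grid, scoring=_KAPPA_SCORER,
                                      cv=cv, n_jobs=1, refit=True)
                    gs.fit(Xtr, ytr)
                    k = kappa_score(yte, gs.predict(Xte))
                    results.append(ModelEval(method, analyte, rep, k,
                                             dict(gs.best_params_), permute))
                except ValueError as exc:
                    # stratum too small for the folds: skip and log
                    logging.getLogger("hybripred").warning(
                        "skipping %s/%s rep %d: %s", method, analyte, rep, exc)
                    continue
    return results


def eval_frame(evals: list[ModelEval]) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in evals])


@dataclass
class ModelSelection:
    method: str
    cv_table: pd.DataFrame  # per method: mean, sd, cv of Kappa


def select_ranking_model(evals: list[ModelEval]) -> ModelSelection:
    """Pick the family minimizing sd(Kappa)/mean(Kappa) over analytes x reps."""
    df = eval_frame(evals)
    df = df[~df["permuted"]]
    if df.empty:
        raise ValueError("no unpermuted evaluations")
    rows = []
    for method, grp in df.groupby("method"):
        k = grp["kappa"].to_numpy()
        if len(k) < 2:
            continue
        mean, sd = float(k.mean()), float(k.std(ddof=1))
        cv = sd / mean if mean > 0 else np.nan
        rows.append({"method": method, "n": len(k), "mean_kappa": mean,
                     "sd_kappa": sd, "cv": cv})
    table = pd.DataFrame(rows).sort_values("cv").reset_index(drop=True)
    usable = table.dropna(subset=["cv"])
    if usable.empty:
        raise ValueError("no method has positive mean Kappa; CV undefined for all")
    return ModelSelection(method=str(usable.iloc[0]["method"]), cv_table=table)


@dataclass
class AnalyteRanking:
    """Parental predictor columns ordered by decreasing median importance."""

    table: pd.DataFrame  # columns: column, analyte, origin, median_importance, sd_importance, rank

    @property
    def ordered_columns(self) -> list[str]:
        return list(self.table["column"])

    def top(self, k: int) -> list[str]:
        return self.ordered_columns[:k]

    def bottom(self, k: int) -> list[str]:
        return self.ordered_columns[-k:]


def _auc_importance(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-column filter importance: one-vs-rest AUC averaged over classes.

    The AUC per (column, class) is the Mann-Whitney statistic, symmetrized as
    max(auc, 1 - auc) so that separation in either direction counts.
    """
    n, p = X.shape
    ranks = np.apply_along_axis(sps.rankdata, 0, X)
    classes = np.unique(y)
    imps = np.zeros((len(classes), p))
    for ci, c in enumerate(classes):
        pos = y == c
        n1 = int(pos.sum())
        n0 = n - n1
        if n1 == 0 or n0 == 0:
            continue
        r1 = ranks[pos].sum(axis=0)
        auc = (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0)
        imps[ci] = np.maximum(auc, 1.0 - auc)
    return imps.mean(axis=0)


def rank_parental_analytes(
    X_DF: PredictorMatrix,
    T: InheritanceMatrix,
    method: str = "SVM-W",
    importance: str = "auc",
    weights: dict[int, float] | None = None,
    seed: int = 0,
    permutation_repeats: int = 5,
    grid: str = "small",
    rf_trees: int = 500,
) -> AnalyteRanking:
    """Rank parental predictor columns by median scaled importance.

    One importance profile is computed per encoded analyte on the full
    sample. The default measure is model-agnostic (per-class one-vs-rest AUC
    averaged over classes) — the standard filter importance for non-linear
    kernels; ``importance="permutation"`` instead fits the selected model and
    scores each column by the Kappa drop under permutation. Profiles are
    scaled so the best column of each analyte model is 100, and the final
    score is the median over analyte models. Ties break by column id.
    """
    cols = list(X_DF.values.columns)
    profiles = []
    for ai, analyte in enumerate(T.labels.columns):
        y_full = T.label_vector(analyte)
        X = X_DF.values.loc[y_full.index].to_numpy()
        y = y_full.to_numpy()
        if importance == "auc":
            imp = _auc_importance(X, y)
        elif importance == "permutation":
            from sklearn.inspection import permutation_importance

            s = _combo_seed(seed, 7, ai)
            est, param_grid = build_classifier(method, X, np.sort(np.unique(y)),
                                               weights, seed=s, grid=grid,
                                               rf_trees=rf_trees)
            mid = {k: v[len(v) // 2] for k, v in param_grid.items()}
            est = clone(est).set_params(**mid)
            est.fit(X, y)
            res = permutation_importance(est, X, y, scoring=_KAPPA_SCORER,
                                         n_repeats=permutation_repeats,
                                         random_state=s)
            imp = np.maximum(res.importances_mean, 0.0)
        else:
            raise ValueError("importance must be 'auc' or 'permutation'")
        top = imp.max()
        profiles.append(imp * (100.0 / top) if top > 0 else imp)
    mat = np.vstack(profiles)
    median = np.median(mat, axis=0)
    sd = mat.std(axis=0, ddof=1) if mat.shape[0] > 1 else np.zeros(mat.shape[1])
    table = pd.DataFrame({
        "column": cols,
        "analyte": [X_DF.analyte_of[c] for c in cols],
        "origin": [X_DF.origin[c] for c in cols],
        "median_importance": median,
        "sd_importance": sd,
    })
    table = table.sort_values(
        ["median_importance", "column"], ascending=[False, True]
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return AnalyteRanking(table=table)


@dataclass
class RankDiagnostics:
    kendall_tau: float
    kendall_p: float
    cumulative: pd.DataFrame  # rank, cum_dent, cum_flint (relative frequencies)


def rank_diagnostics(ranking: AnalyteRanking) -> RankDiagnostics:
    """Concordance of the maternal and paternal rank orders, plus cumulative curves.

    Kendall's tau compares, over the analyte identities present in both
    parental blocks, the position of each analyte within the Dent-only
    ranking against its position within the Flint-only ranking.
    """
    t = ranking.table
    dent = t[t["origin"] == "dent"].reset_index(drop=True)
    flint = t[t["origin"] == "flint"].reset_index(drop=True)
    if dent.empty or flint.empty:
        raise ValueError("both parental blocks must be non-empty")
    pos_d = {a: i for i, a in enumerate(dent["analyte"])}
    pos_f = {a: i for i, a in enumerate(flint["analyte"])}
    shared = [a for a in pos_d if a in pos_f]
    tau, p = sps.kendalltau([pos_d[a] for a in shared], [pos_f[a] for a in shared])
    is_dent = (t["origin"] == "dent").to_numpy()
    cum = pd.DataFrame({
        "rank": t["rank"].to_numpy(),
        "cum_dent": np.cumsum(is_dent) / max(1, is_dent.sum()),
        "cum_flint": np.cumsum(~is_dent) / max(1, (~is_dent).sum()),
    })
    return RankDiagnostics(kendall_tau=float(tau), kendall_p=float(p), cumulative=cum)
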