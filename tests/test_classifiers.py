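"""Cohen's Kappa, the classifier comparison machinery and the analyte ranking."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score

from hybripred import (
    InheritanceMatrix,
    cohen_kappa,
    evaluate_classifiers,
    kappa_score,
    rank_diagnostics,
    rank_parental_analytes,
    select_ranking_model,
)
from hybripred.classifiers import AnalyteRanking, ModelEval, _auc_importance
from hybripred.preprocess import PredictorMatrix


def test_kappa_perfect_and_chance_agreement():
    assert cohen_kappa(np.diag([5, 3, 7])) == pytest.approx(1.0)
    marg = np.outer([0.5, 0.3, 0.2], [0.4, 0.4, 0.2]) * 100
    assert cohen_kappa(marg) == pytest.approx(0.0, abs=1e-12)


def test_kappa_example_matches_hand_arithmetic():
    c = np.array([[10, 2, 0], [1, 8, 1], [0, 3, 5]])
    total = c.sum()
    po = (10 + 8 + 5) / total
    pe = sum(c[i].sum() * c[:, i].sum() for i in range(3)) / total**2
    assert cohen_kappa(c) == pytest.approx((po - pe) / (1 - pe))


def test_kappa_degenerate_single_class_returns_zero():
    assert cohen_kappa(np.array([[7, 0], [0, 0]])) == 0.0


def test_kappa_invariant_to_simultaneous_permutation():
    rng = np.random.default_rng(0)
    c = rng.integers(0, 20, size=(4, 4)).astype(float)
    perm = rng.permutation(4)
    assert cohen_kappa(c[np.ix_(perm, perm)]) == pytest.approx(cohen_kappa(c))


def test_kappa_errors():
    with pytest.raises(ValueError):
        cohen_kappa(np.empty((0, 0)))
    with pytest.raises(ValueError):
        cohen_kappa(np.array([[1, -2], [0, 3]]))


def test_kappa_score_agrees_with_sklearn():
    rng = np.random.default_rng(1)
    y_true = rng.choice([-2, -1, 0, 1, 2], 200)
    y_pred = np.where(rng.random(200) < 0.6, y_true, rng.choice([-2, 0, 2], 200))
    assert kappa_score(y_true, y_pred) == pytest.approx(
        cohen_kappa_score(y_true, y_pred))


def _toy_predictor(n=400, p=16, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    cols = [f"D:A{j:03d}" for j in range(p // 2)] + \
           [f"F:A{j:03d}" for j in range(p // 2)]
    idx = [f"D{i}×F{i}" for i in range(n)]
    values = pd.DataFrame(X, index=idx, columns=cols)
    origin = pd.Series(["dent"] * (p // 2) + ["flint"] * (p // 2), index=cols)
    analyte_of = pd.Series([c.split(":")[1] for c in cols], index=cols)
    return PredictorMatrix(values, origin, analyte_of), rng


def _labels_from_columns(X: PredictorMatrix, cols: list[str],
                         props=(0.1, 0.2, 0.4, 0.2, 0.1)) -> pd.Series:
    u = X.values[cols].sum(axis=1)
    q = np.quantile(u, np.cumsum(props)[:-1])
    return pd.Series(np.searchsorted(q, u) - 2, index=X.values.index)


def test_planted_deterministic_labels_give_high_svm_kappa():
    """Labels a deterministic function of 4 parental columns are learnable.

    The five classes are bands of the 4-column score with a margin around
    the cut points, so a capable classifier can separate them cleanly.
    """
    rng = np.random.default_rng(0)
    p, need = 16, 400
    raw = rng.normal(size=(3000, p))
    u = raw[:, :4].sum(axis=1)
    cuts = np.array([-2.6, -1.0, 1.0, 2.6])
    ok = (np.abs(u[:, None] - cuts[None, :]) > 0.45).all(axis=1)
    Xk, uk = raw[ok][:need], u[ok][:need]
    y = np.searchsorted(cuts, uk) - 2
    Xs = (Xk - Xk.mean(0)) / Xk.std(0, ddof=1)
    cols = [f"D:A{j:03d}" for j in range(p // 2)] + \
           [f"F:A{j:03d}" for j in range(p // 2)]
    idx = [f"D{i}×F{i}" for i in range(need)]
    X = PredictorMatrix(
        pd.DataFrame(Xs, index=idx, columns=cols),
        pd.Series(["dent"] * (p // 2) + ["flint"] * (p // 2), index=cols),
        pd.Series([c.split(":")[1] for c in cols], index=cols))
    T = InheritanceMatrix(labels=pd.Series(y, index=idx).to_frame("enc"))
    evals = evaluate_classifiers(X, T, methods=("SVM",), repetitions=2, seed=5,
                                 inner_repeats=2, grid="full")
    assert np.median([e.kappa for e in evals]) > 0.9


def test_noise_labels_give_near_zero_kappa():
    X, rng = _toy_predictor(n=250, seed=2)
    y = pd.Series(rng.choice([-1, 0, 1], 250, p=[0.25, 0.5, 0.25]),
                  index=X.values.index)
    T = InheritanceMatrix(labels=y.to_frame("enc"))
    evals = evaluate_classifiers(X, T, methods=("SVM",), repetitions=3, seed=6,
                                 inner_repeats=1, grid="small")
    assert abs(np.median([e.kappa for e in evals])) < 0.1


def test_evaluate_classifiers_bit_reproducible():
    X, _ = _toy_predictor(n=150, seed=3)
    y = _labels_from_columns(X, ["D:A002", "F:A003"], props=(0, 0.3, 0.4, 0.3, 0))
    T = InheritanceMatrix(labels=y.to_frame("enc"))
    kw = dict(methods=("SVM-W",), repetitions=2, seed=42, inner_repeats=1,
              grid="small")
    k1 = [e.kappa for e in evaluate_classifiers(X, T, **kw)]
    k2 = [e.kappa for e in evaluate_classifiers(X, T, **kw)]
    assert k1 == k2


def _evals(method: str, kappas: list[float]) -> list[ModelEval]:
    return [ModelEval(method, "a", i, k, {}, False) for i, k in enumerate(kappas)]


def test_select_ranking_model_arithmetic_oracle():
    a = [0.5, 0.6, 0.4]
    b = [0.3, 0.31, 0.29]
    sel = select_ranking_model(_evals("A", a) + _evals("B", b))
    cv = {m: np.std(k, ddof=1) / np.mean(k) for m, k in (("A", a), ("B", b))}
    assert sel.method == min(cv, key=cv.get) == "B"
    row = sel.cv_table.set_index("method").loc["A"]
    assert row["cv"] == pytest.approx(cv["A"])


def test_select_ranking_model_constant_kappa_and_undefined_cv():
    sel = select_ranking_model(_evals("const", [0.4, 0.4, 0.4])
                               + _evals("neg", [-0.1, -0.2, 0.05]))
    assert sel.method == "const"
    table = sel.cv_table.set_index("method")
    assert table.loc["const", "cv"] == pytest.approx(0.0)
    assert np.isnan(table.loc["neg", "cv"])  # mean <= 0: CV undefined


def test_auc_importance_identifies_informative_column():
    rng = np.random.default_rng(9)
    n = 300
    y = rng.choice([0, 1, 2], n)
    X = rng.normal(size=(n, 3))
    X[:, 0] += y  # informative
    imp = _auc_importance(X, y)
    assert imp[0] > imp[1] and imp[0] > imp[2]


def test_ranking_recovers_planted_columns_and_is_deterministic():
    X, _ = _toy_predictor(n=300, seed=4)
    planted = ["D:A000", "D:A004", "F:A002"]
    labels = pd.DataFrame({
        f"enc{i}": _labels_from_columns(X, planted) for i in range(3)})
    T = InheritanceMatrix(labels=labels)
    rk = rank_parental_analytes(X, T)
    assert set(planted) <= set(rk.top(6))
    rk2 = rank_parental_analytes(X, T)
    assert rk.ordered_columns == rk2.ordered_columns
    assert rk.table["median_importance"].max() == pytest.approx(100.0)


def test_no_column_persistently_top_ranked_under_pure_noise():
    tops = []
    for seed in range(20):
        X, rng = _toy_predictor(n=80, p=10, seed=100 + seed)
        y = pd.Series(rng.choice([-1, 0, 1], 80), index=X.values.index)
        rk = rank_parental_analytes(
            X, InheritanceMatrix(labels=y.to_frame("enc")))
        tops.append(rk.ordered_columns[0])
    assert max(tops.count(c) for c in set(tops)) <= 8


def _ranking_from_order(cols_origin: list[tuple[str, str, str]]) -> AnalyteRanking:
    n = len(cols_origin)
    table = pd.DataFrame({
        "column": [c for c, _, _ in cols_origin],
        "analyte": [a for _, a, _ in cols_origin],
        "origin": [o for _, _, o in cols_origin],
        "median_importance": np.linspace(100, 10, n),
        "sd_importance": np.zeros(n),
        "rank": np.arange(1, n + 1)})
    return AnalyteRanking(table=table)


def test_rank_diagnostics_tau_limits_and_pair_oracle():
    analytes = [f"A{i}" for i in range(6)]
    same = _ranking_from_order(
        [(f"D:{a}", a, "dent") for a in analytes]
        + [(f"F:{a}", a, "flint") for a in analytes])
    assert rank_diagnostics(same).kendall_tau == pytest.approx(1.0)
    reverse = _ranking_from_order(
        [(f"D:{a}", a, "dent") for a in analytes]
        + [(f"F:{a}", a, "flint") for a in reversed(analytes)])
    assert rank_diagnostics(reverse).kendall_tau == pytest.approx(-1.0)

    rng = np.random.default_rng(12)
    flint_order = [analytes[i] for i in rng.permutation(6)]
    mixed = _ranking_from_order(
        [(f"D:{a}", a, "dent") for a in analytes]
        + [(f"F:{a}", a, "flint") for a in flint_order])
    tau = rank_diagnostics(mixed).kendall_tau
    pos_d = {a: i for i, a in enumerate(analytes)}
    pos_f = {a: i for i, a in enumerate(flint_order)}
    conc = disc = 0
    for i in range(6):
        for j in range(i + 1, 6):
            a, b = analytes[i], analytes[j]
            s = (pos_d[a] - pos_d[b]) * (pos_f[a] - pos_f[b])
            conc += s > 0
            disc += s < 0
    assert tau == pytest.approx((conc - disc) / (conc + disc))


def test_cumulative_curves_end_at_one():
    analytes = [f"A{i}" for i in range(4)]
    rk = _ranking_from_order(
        [(f"D:{a}", a, "dent") for a in analytes]
        + [(f"F:{a}", a, "flint") for a in analytes])
    cum = rank_diagnostics(rk).cumulative
    assert cum["cum_dent"].iloc[-1] == pytest.approx(1.0)
    assert cum["cum_flint"].iloc[-1] == pytest.approx(1.0)
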