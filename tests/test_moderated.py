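"""Empirical-Bayes variance prior and moderated contrasts."""

import shutil
import subprocess
import textwrap

import numpy as np
import pytest
from scipy import optimize, special, stats

from hybripred.moderated import (
    estimate_variance_prior,
    moderated_contrasts,
    trigamma_inverse,
)


def test_trigamma_inverse_round_trip():
    y = np.array([1e-5, 0.01, 0.1, 1.0, 10.0, 1e4])
    x = trigamma_inverse(y)
    np.testing.assert_allclose(special.polygamma(1, x), y, rtol=1e-6)


def test_identical_variances_give_infinite_prior_df():
    d0, s0 = estimate_variance_prior(np.full(20, 0.7), 6)
    assert np.isinf(d0)
    assert s0 == pytest.approx(0.7)


def test_two_variance_fit_matches_root_finding_oracle():
    """{1, e^2} with df 4: solve the method-of-moments equations independently."""
    s2 = np.array([1.0, np.e**2])
    df = 4.0
    e = np.log(s2) - special.digamma(df / 2) + np.log(df / 2)
    evar = ((e - e.mean()) ** 2).sum() / 1 - special.polygamma(1, df / 2)
    assert evar > 0
    half_d0 = optimize.brentq(lambda x: special.polygamma(1, x) - evar, 1e-6, 1e6,
                              xtol=1e-12)
    d0_oracle = 2 * half_d0
    s0_oracle = np.exp(e.mean() + special.digamma(half_d0) - np.log(half_d0))
    d0, s0 = estimate_variance_prior(s2, 4)
    assert d0 == pytest.approx(d0_oracle, abs=1e-8)
    assert s0 == pytest.approx(s0_oracle, abs=1e-8)


def test_all_zero_variances_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        estimate_variance_prior(np.zeros(5), 4)


def test_prior_parameter_recovery():
    """Variances simulated from the scaled-F model recover (d0, s0^2)."""
    rng = np.random.default_rng(2)
    d0_true, s0_true, df, n = 4.0, 1.0, 4, 5000
    s2 = s0_true * (rng.chisquare(df, n) / df) / (rng.chisquare(d0_true, n) / d0_true)
    d0, s0 = estimate_variance_prior(s2, df)
    assert abs(d0 - d0_true) / d0_true < 0.15
    assert abs(s0 - s0_true) / s0_true < 0.05


def _toy_groups(seed=0, m=12, reps=4, shift=0.0, heterogeneous=False):
    rng = np.random.default_rng(seed)
    mu = rng.normal(5, 1, size=m)
    sd = 0.3 * np.exp(rng.normal(0, 0.6, size=m)) if heterogeneous else 0.3
    d = mu + rng.normal(0, 1, size=(reps, m)) * sd
    f = mu + rng.normal(0, 1, size=(reps, m)) * sd
    h = mu + shift + rng.normal(0, 1, size=(reps, m)) * sd
    return d, f, h


def test_zero_prior_df_reduces_to_ordinary_pooled_t():
    d, f, h = _toy_groups(seed=1, shift=0.4)
    names = [f"A{i}" for i in range(d.shape[1])]
    s2 = sum(((g - g.mean(axis=0)) ** 2).sum(axis=0) for g in (d, f, h)) / (3 * 4 - 3)
    res = moderated_contrasts(d, f, h, names, prior=(0.0, 1.0))
    m_b = np.maximum(d.mean(axis=0), f.mean(axis=0))
    se = np.sqrt(s2 * (1 / 4 + 1 / 4))
    t_ref = (h.mean(axis=0) - m_b) / se
    np.testing.assert_allclose(res.t_hb, t_ref, atol=1e-10)


def test_infinite_prior_df_pins_variance_at_s0():
    d, f, h = _toy_groups(seed=2)
    res = moderated_contrasts(d, f, h, [f"A{i}" for i in range(d.shape[1])],
                              prior=(np.inf, 0.09))
    np.testing.assert_allclose(res.s2_moderated, 0.09)


def test_identical_groups_give_null_contrasts():
    reps = np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]])
    res = moderated_contrasts(reps, reps, reps, ["a", "b"])
    np.testing.assert_allclose(res.t_hb, 0.0, atol=1e-12)
    np.testing.assert_allclose(res.p_hb, 1.0)
    np.testing.assert_allclose(res.t_hw, 0.0, atol=1e-12)


def test_shrinkage_direction_and_bounds():
    d, f, h = _toy_groups(seed=3, m=40, heterogeneous=True)
    res = moderated_contrasts(d, f, h, [f"A{i}" for i in range(40)])
    assert np.isfinite(res.d0)
    lo = np.minimum(res.s2, res.s0sq)
    hi = np.maximum(res.s2, res.s0sq)
    assert ((res.s2_moderated >= lo - 1e-12) & (res.s2_moderated <= hi + 1e-12)).all()
    below = res.s2 < res.s0sq
    assert (res.s2_moderated[below] > res.s2[below]).all()
    assert (res.s2_moderated[~below] < res.s2[~below]).all()


def test_moderated_t_monotone_in_contrast_estimate():
    d, f, h = _toy_groups(seed=4)
    names = [f"A{i}" for i in range(d.shape[1])]
    base = moderated_contrasts(d, f, h, names, prior=(4.0, 0.1))
    shifted = moderated_contrasts(d, f, h + 0.5, names, prior=(4.0, 0.1))
    # same variances, larger estimates -> larger t, ordered consistently
    assert (shifted.t_hw > base.t_hw).all()


def test_group_with_single_replicate_rejected():
    d, f, h = _toy_groups()
    with pytest.raises(ValueError, match="flint"):
        moderated_contrasts(d, f[:1], h, [f"A{i}" for i in range(d.shape[1])])


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
def test_agreement_with_limma_oracle(tmp_path):
    """Independent oracle: limma's eBayes on the same three-group layout."""
    rng = np.random.default_rng(42)
    nrep, m = 4, 30
    mu = rng.normal(5, 1, size=(3, m))
    X = np.concatenate([mu[g] + rng.normal(0, 0.4 * np.exp(rng.normal(0, 0.3)),
                                           size=(nrep, m)) for g in range(3)])
    np.savetxt(tmp_path / "expr.csv", X.T, delimiter=",")
    script = textwrap.dedent("""
        suppressMessages(library(limma))
        X <- as.matrix(read.csv("expr.csv", header=FALSE))
        groups <- factor(rep(c("d","f","h"), each=4), levels=c("d","f","h"))
        design <- model.matrix(~0+groups); colnames(design) <- levels(groups)
        fit <- eBayes(contrasts.fit(lmFit(X, design),
                      makeContrasts(h-d, h-f, levels=design)))
        write.csv(data.frame(t_hd=fit$t[,1], t_hf=fit$t[,2],
                             p_hd=fit$p.value[,1]), "out.csv", row.names=FALSE)
    """)
    (tmp_path / "oracle.R").write_text(script)
    subprocess.run(["Rscript", "oracle.R"], cwd=tmp_path, check=True,
                   capture_output=True)
    lim = np.genfromtxt(tmp_path / "out.csv", delimiter=",", names=True)
    res = moderated_contrasts(X[:4], X[4:8], X[8:12], [f"A{i}" for i in range(m)])
    t_hd = np.where(res.better_is_dent, res.t_hb, res.t_hw)
    p_hd = np.where(res.better_is_dent, res.p_hb, res.p_hw)
    np.testing.assert_allclose(t_hd, lim["t_hd"], atol=1e-8)
    np.testing.assert_allclose(p_hd, lim["p_hd"], atol=1e-8)
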