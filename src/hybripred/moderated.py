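"""Empirical-Bayes moderated t-statistics for per-cross three-group contrasts.

For every cross, the replicate profiles of the Dent parent, Flint parent and
hybrid form a one-way three-group layout per analyte. Residual variances are
pooled across the three groups and shrunk towards a prior variance ``s0^2``
with prior degrees of freedom ``d0`` estimated from all analytes of the
subset by the classical method-of-moments fit on log variances: if
``s^2 ~ s0^2 * F(d, d0)`` then ``log s^2`` has known mean and variance in
terms of digamma/trigamma functions, which are inverted numerically. The
moderated variance

    s~^2 = (d0 * s0^2 + d * s^2) / (d0 + d)

replaces the per-analyte residual variance in the contrast t-statistics,
which gain ``d0`` degrees of freedom. Two contrasts are formed per analyte:
hybrid minus better parent (b, the parent with the larger mean level of that
analyte) and hybrid minus worse parent (w).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .datamodel import ROLE_HYBRID, MatingDesign, ProfileMatrix


def _trigamma(x: np.ndarray | float) -> np.ndarray | float:
    return special.polygamma(1, x)


def trigamma_inverse(y: np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Uses the asymptotic starting value x ~ 0.5 + 1/y and the update on the
    scale of 1/trigamma, which is close to linear in x.
    """
    y = np.asarray(y, dtype=float)
    out = np.empty_like(y)
    small = y > 1e7  # trigamma(x) ~ 1/x^2 for tiny x
    out[small] = 1.0 / np.sqrt(y[small])
    big = y < 1e-6  # trigamma(x) ~ 1/x for large x
    out[big] = 1.0 / y[big]
    mid = ~(small | big)
    x = 0.5 + 1.0 / y[mid]
    for _ in range(50):
        tri = _trigamma(x)
        dif = tri * (1.0 - tri / y[mid]) / special.polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif / x) < 1e-10):
            break
    out[mid] = x
    return out


def estimate_variance_prior(
    sample_variances: np.ndarray, dfs: np.ndarray | int
) -> tuple[float, float]:
    """Fit the scaled-F prior (d0, s0^2) to observed residual variances.

    Returns ``d0 = inf`` (complete shrinkage to a common value) when the
    spread of log variances does not exceed its expected sampling floor.
    Zero variances are excluded from the fit; all-zero input is degenerate.
    """
    s2 = np.asarray(sample_variances, dtype=float)
    df = np.broadcast_to(np.asarray(dfs, dtype=float), s2.shape)
    ok = s2 > 0
    if not ok.any():
        raise ValueError("degenerate variances: all sample variances are zero")
    s2, df = s2[ok], df[ok]
    if s2.size < 2:
        return float("inf"), float(s2[0])
    # e_g = log s2_g corrected for the chi^2_d sampling bias
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    n = e.size
    evar = ((e - emean) ** 2).sum() / (n - 1) - _trigamma(df / 2.0).mean()
    if evar <= 0:
        # no excess dispersion beyond chi^2 sampling: complete shrinkage
        return float("inf"), float(s2.mean())
    d0 = 2.0 * float(trigamma_inverse(np.array([evar]))[0])
    s0sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0sq


@dataclass
class ContrastResult:
    """Per-analyte moderated contrasts for one cross (hybrid vs b/w parents)."""

    cross: str
    analytes: list[str]
    mean_dent: np.ndarray
    mean_flint: np.ndarray
    mean_hybrid: np.ndarray
    s2: np.ndarray  # pooled residual variance per analyte
    df_residual: float
    d0: float
    s0sq: float
    s2_moderated: np.ndarray
    better_is_dent: np.ndarray  # bool per analyte: b parent is the Dent
    t_hb: np.ndarray  # hybrid minus better parent
    p_hb: np.ndarray
    t_hw: np.ndarray  # hybrid minus worse parent
    p_hw: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cross": self.cross, "analyte": self.analytes,
             "mean_d": self.mean_dent, "mean_f": self.mean_flint,
             "mean_h": self.mean_hybrid, "t_hb": self.t_hb, "p_hb": self.p_hb,
             "t_hw": self.t_hw, "p_hw": self.p_hw,
             "d0": self.d0, "s0sq": self.s0sq}
        )


def _moderate(s2: np.ndarray, df: float, d0: float, s0sq: float) -> np.ndarray:
    if np.isinf(d0):
        return np.full_like(s2, s0sq)
    return (d0 * s0sq + df * s2) / (d0 + df)


def moderated_contrasts(
    dent_reps: np.ndarray,
    flint_reps: np.ndarray,
    hybrid_reps: np.ndarray,
    analytes: list[str],
    cross: str = "",
    prior: tuple[float, float] | None = None,
) -> ContrastResult:
    """Three-group moderated contrasts for one cross.

    Arrays are replicate x analyte. The residual variance is pooled across
    the three groups (one-way fit); the prior is estimated across this
    subset's analytes unless supplied. P-values are two-sided from the t
    distribution with ``d0 + d`` degrees of freedom, unadjusted.
    """
    groups = [np.asarray(g, dtype=float) for g in (dent_reps, flint_reps, hybrid_reps)]
    names = ("dent", "flint", "hybrid")
    for g, name in zip(groups, names):
        if g.shape[0] < 2:
            raise ValueError(f"group {name!r} has fewer than 2 replicates")
    ns = np.array([g.shape[0] for g in groups], dtype=float)
    means = [g.mean(axis=0) for g in groups]
    sse = sum(((g - m) ** 2).sum(axis=0) for g, m in zip(groups, means))
    df = float(ns.sum() - 3)
    s2 = sse / df
    if prior is None:
        prior = estimate_variance_prior(s2, df)
    d0, s0sq = prior
    s2_mod = _moderate(s2, df, d0, s0sq)

    m_d, m_f, m_h = means
    better_is_dent = m_d >= m_f
    m_b = np.where(better_is_dent, m_d, m_f)
    m_w = np.where(better_is_dent, m_f, m_d)
    n_b = np.where(better_is_dent, ns[0], ns[1])
    n_w = np.where(better_is_dent, ns[1], ns[0])
    # total df capped at the pooled residual df over all analytes
    df_total = min(d0 + df, df * len(analytes))

    def tstat(est: np.ndarray, n_other: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        se = np.sqrt(s2_mod * (1.0 / ns[2] + 1.0 / n_other))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, est / se, 0.0)
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
        return t, p

    t_hb, p_hb = tstat(m_h - m_b, n_b)
    t_hw, p_hw = tstat(m_h - m_w, n_w)
    return ContrastResult(
        cross=cross, analytes=list(analytes),
        mean_dent=m_d, mean_flint=m_f, mean_hybrid=m_h,
        s2=s2, df_residual=df, d0=d0, s0sq=s0sq, s2_moderated=s2_mod,
        better_is_dent=better_is_dent,
        t_hb=t_hb, p_hb=p_hb, t_hw=t_hw, p_hw=p_hw,
    )


def panel_contrasts(
    design: MatingDesign,
    profiles: ProfileMatrix,
    analytes: list[str] | None = None,
    prior_scope: str = "subset",
) -> list[ContrastResult]:
    """Moderated contrasts for every cross in the design.

    ``prior_scope="subset"`` estimates (d0, s0^2) within each cross's subset
    of analytes (the default); ``"panel"`` pools residual variances over all
    crosses first and applies one shared prior.
    """
    if analytes is not None:
        profiles = profiles.subset_analytes(analytes)
    names = profiles.analyte_ids
    triples = []
    for d, f in design.crosses:
        h = f"{d}{design.sep}{f}"
        triples.append((h, profiles.replicates(d).to_numpy(),
                        profiles.replicates(f).to_numpy(),
                        profiles.replicates(h).to_numpy()))
    shared: tuple[float, float] | None = None
    if prior_scope == "panel":
        all_s2, all_df = [], []
        for _, dr, fr, hr in triples:
            groups = [dr, fr, hr]
            df = float(sum(g.shape[0] for g in groups) - 3)
            sse = sum(((g - g.mean(axis=0)) ** 2).sum(axis=0) for g in groups)
            all_s2.append(sse / df)
            all_df.append(np.full(len(names), df))
        shared = estimate_variance_prior(np.concatenate(all_s2), np.concatenate(all_df))
    elif prior_scope != "subset":
        raise ValueError("prior_scope must be 'subset' or 'panel'")
    return [
        moderated_contrasts(dr, fr, hr, names, cross=h, prior=shared)
        for h, dr, fr, hr in triples
    ]
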