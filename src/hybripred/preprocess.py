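"""Analyte redundancy filtering and the concatenated parental predictor matrix."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import MatingDesign, PanelConsistencyError, ProfileMatrix


@dataclass
class RemovalRecord:
    pair: tuple[str, str]
    r: float
    dropped: str
    mean_r: dict[str, float]
    reason: str = "redundant"


def _mean_offdiag_r(corr: pd.DataFrame, analyte: str) -> float:
    row = corr[analyte].drop(index=analyte)
    return float(row.mean())


def redundancy_filter(
    profiles: ProfileMatrix,
    r_threshold: float = 0.85,
    iterative: bool = False,
) -> tuple[list[str], list[RemovalRecord]]:
    """Remove one analyte of every over-correlated pair (Pearson r > threshold).

    Correlations are computed over genotype-mean profiles (parents and hybrids
    pooled) to avoid replicate pseudo-replication. Pairs are resolved greedily
    in descending r; within a pair the member with the larger mean signed r to
    all other analytes is dropped. Zero-variance analytes (correlation
    undefined) are dropped first and logged. With ``iterative=True``,
    correlations and pair lists are recomputed after every removal.

    Returns the retained analyte ids (input order) and the removal log.
    """
    if not 0 < r_threshold <= 1:
        raise ValueError("r_threshold must be in (0, 1]")
    if profiles.n_analytes < 2:
        raise ValueError("need at least 2 analytes")
    means = profiles.genotype_means()
    log: list[RemovalRecord] = []

    variances = means.var(axis=0, ddof=1)
    constant = [a for a in means.columns if variances[a] == 0]
    for a in constant:
        log.append(RemovalRecord(pair=(a, a), r=float("nan"), dropped=a,
                                 mean_r={a: float("nan")}, reason="zero variance"))
    live = [a for a in means.columns if a not in set(constant)]

    def one_pass(cols: list[str]) -> str | None:
        """Resolve pairs over `cols`; return first dropped id (iterative) or None."""
        corr = means[cols].corr()
        iu = np.triu_indices(len(cols), k=1)
        rs = corr.to_numpy()[iu]
        order = np.argsort(-rs, kind="stable")
        removed: set[str] = set()
        for k in order:
            r = float(rs[k])
            if r <= r_threshold:
                break
            a, b = cols[iu[0][k]], cols[iu[1][k]]
            if a in removed or b in removed:
                continue  # pair already resolved by an earlier removal
            ma, mb = _mean_offdiag_r(corr, a), _mean_offdiag_r(corr, b)
            if ma > mb:
                drop = a
            elif mb > ma:
                drop = b
            else:
                drop = max(a, b)  # deterministic tie-break: lexicographically later
            removed.add(drop)
            log.append(RemovalRecord(pair=(a, b), r=r, dropped=drop,
                                     mean_r={a: ma, b: mb}))
            if iterative:
                return drop
        for d in removed:
            cols.remove(d)
        return None

    if iterative:
        while len(live) > 1:
            dropped = one_pass(live)
            if dropped is None:
                break
            live.remove(dropped)
    else:
        one_pass(live)
    return live, log


def removal_log_frame(log: list[RemovalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"analyte_a": a, "analyte_b": b, "r": rec.r, "dropped": rec.dropped,
          "reason": rec.reason} for rec in log for a, b in [rec.pair]]
    )


@dataclass
class PredictorMatrix:
    """Hybrids x (Dent-block + Flint-block) standardized parental profiles.

    Each parent's analyte value is the mean over that line's replicates; the
    Dent (maternal) block precedes the Flint (paternal) block and every column
    is z-scored over the hybrids.
    """

    values: pd.DataFrame  # index: cross ids, columns: tagged analyte ids
    origin: pd.Series  # column -> "dent" | "flint"
    analyte_of: pd.Series  # column -> untagged analyte id

    @property
    def dent_columns(self) -> list[str]:
        return [c for c in self.values.columns if self.origin[c] == "dent"]

    @property
    def flint_columns(self) -> list[str]:
        return [c for c in self.values.columns if self.origin[c] == "flint"]


def build_predictor_matrix(
    design: MatingDesign,
    profiles: ProfileMatrix,
    retained: list[str] | None = None,
) -> PredictorMatrix:
    """Assemble and column-standardize X_DF from parental replicate means."""
    analytes = list(retained) if retained is not None else profiles.analyte_ids
    means = profiles.genotype_means()[analytes]
    rows = []
    for d, f in design.crosses:
        for parent in (d, f):
            if parent not in means.index:
                raise PanelConsistencyError(
                    f"cross {d}{design.sep}{f}: no profiles for parent {parent!r}"
                )
        rows.append(np.concatenate([means.loc[d].to_numpy(), means.loc[f].to_numpy()]))
    cols = [f"D:{a}" for a in analytes] + [f"F:{a}" for a in analytes]
    values = pd.DataFrame(rows, index=design.cross_ids, columns=cols, dtype=float)
    mu = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    sd = sd.replace(0.0, 1.0)  # constant columns stay centred at 0
    values = (values - mu) / sd
    origin = pd.Series(["dent"] * len(analytes) + ["flint"] * len(analytes), index=cols)
    analyte_of = pd.Series(analytes + analytes, index=cols)
    return PredictorMatrix(values=values, origin=origin, analyte_of=analyte_of)
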