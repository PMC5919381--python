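"""Five-class metabolic inheritance pattern (mIP) encoding and class-balance filters.

Each hybrid x analyte combination receives a label in {-2, -1, 0, +1, +2}:
+/-2 positive/negative overdominance (hybrid significantly outside the
parental range), +/-1 positive/negative dominance (significantly different
from one parent only), 0 additivity. Significance comes from the moderated
contrasts against the better (b) and worse (w) parent; "equal" means not
significant at alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import PhenotypeTable
from .moderated import ContrastResult

#: (state vs b, state vs w) -> label; states are -1 (sig below), 0 (ns), +1 (sig above).
#: The three combinations impossible under equal replication (state_b > state_w)
#: are completed antisymmetrically so the mapping is total.
TRUTH_TABLE: dict[tuple[int, int], int] = {
    (1, 1): 2,
    (0, 1): 1,
    (0, 0): 0,
    (-1, 1): 0,
    (-1, 0): -1,
    (-1, -1): -2,
    (1, 0): 1,
    (1, -1): 0,
    (0, -1): -1,
}


def _state(t: np.ndarray, p: np.ndarray, alpha: float) -> np.ndarray:
    return np.where(p < alpha, np.sign(t).astype(int), 0)


def encode_mip(contrast: ContrastResult, alpha: float = 0.05) -> np.ndarray:
    """Labels for one cross, all analytes, from its moderated contrasts."""
    sb = _state(contrast.t_hb, contrast.p_hb, alpha)
    sw = _state(contrast.t_hw, contrast.p_hw, alpha)
    return np.array([TRUTH_TABLE[(int(a), int(b))] for a, b in zip(sb, sw)])


@dataclass
class InheritanceMatrix:
    """Hybrid x analyte mIP label matrix with per-analyte hybrid exclusions."""

    labels: pd.DataFrame  # index: cross ids, columns: analyte ids, int in -2..2
    excluded_hybrids: dict[str, list[str]] = field(default_factory=dict)

    def class_counts(self, analyte: str) -> dict[int, int]:
        col = self.labels[analyte]
        keep = ~col.index.isin(self.excluded_hybrids.get(analyte, []))
        vc = col[keep].value_counts()
        return {int(k): int(v) for k, v in vc.items()}

    def label_vector(self, analyte: str) -> pd.Series:
        """Labels for one analyte with that analyte's excluded hybrids dropped."""
        col = self.labels[analyte]
        excl = self.excluded_hybrids.get(analyte, [])
        return col[~col.index.isin(excl)]


def encode_panel(contrasts: list[ContrastResult], alpha: float = 0.05) -> InheritanceMatrix:
    rows = {c.cross: encode_mip(c, alpha) for c in contrasts}
    analytes = contrasts[0].analytes
    labels = pd.DataFrame.from_dict(rows, orient="index", columns=analytes).astype(int)
    return InheritanceMatrix(labels=labels)


@dataclass
class BalanceDecision:
    analyte: str
    kept: bool
    reason: str
    counts: dict[int, int]
    excluded_hybrid: str | None = None


def class_balance_filter(
    T: InheritanceMatrix,
    max_class_fraction: float = 0.75,
    min_class_count: int = 4,
    strict_absent: bool = False,
) -> tuple[InheritanceMatrix, list[BalanceDecision]]:
    """Drop encoded analytes with degenerate class distributions.

    An analyte is dropped when (i) any realized class covers more than
    ``max_class_fraction`` of the hybrids, or (ii) any realized class has
    between 2 and ``min_class_count``-1 occurrences. If the only offence is a
    single class realized exactly once, the analyte is kept and that one
    hybrid is excluded for this analyte only. Multiple singleton classes, or
    a singleton alongside a 2-3-count class, drop the analyte (ambiguous
    case, logged). Absent classes (count 0) do not offend unless
    ``strict_absent`` is set.
    """
    if T.labels.shape[1] < 1:
        raise ValueError("need at least one encoded analyte")
    kept_cols: list[str] = []
    exclusions: dict[str, list[str]] = {}
    decisions: list[BalanceDecision] = []
    n_hybrids = T.labels.shape[0]
    for analyte in T.labels.columns:
        counts = {int(k): int(v) for k, v in T.labels[analyte].value_counts().items()}
        if strict_absent:
            counts = {c: counts.get(c, 0) for c in (-2, -1, 0, 1, 2)}
        frac_bad = any(v / n_hybrids > max_class_fraction for v in counts.values())
        low = {c: v for c, v in counts.items() if v < min_class_count}
        if frac_bad:
            decisions.append(BalanceDecision(analyte, False, "class fraction above threshold", counts))
            continue
        if not low:
            kept_cols.append(analyte)
            decisions.append(BalanceDecision(analyte, True, "balanced", counts))
            continue
        singletons = [c for c, v in low.items() if v == 1]
        few = {c: v for c, v in low.items() if v >= 2}
        if len(singletons) == 1 and not few:
            cls = singletons[0]
            hybrid = T.labels.index[T.labels[analyte] == cls][0]
            kept_cols.append(analyte)
            exclusions[analyte] = [hybrid]
            decisions.append(BalanceDecision(analyte, True, "single singleton class: hybrid excluded",
                                             counts, excluded_hybrid=hybrid))
        elif few:
            decisions.append(BalanceDecision(analyte, False, "class with 2-3 occurrences", counts))
        else:
            decisions.append(BalanceDecision(analyte, False, "multiple singleton classes (ambiguous)", counts))
    filtered = InheritanceMatrix(labels=T.labels[kept_cols].copy(), excluded_hybrids=exclusions)
    return filtered, decisions


@dataclass
class NonAdditivityReport:
    fraction: pd.Series  # per-hybrid share of non-additive labels
    pooled: tuple[float, float] | None  # (r, p) or None when undefined
    per_trial: dict[str, tuple[float, float] | None]


def nonadditivity_vs_hp(T: InheritanceMatrix, pheno: PhenotypeTable) -> NonAdditivityReport:
    """Correlate each hybrid's non-additive label share with its biomass."""
    common = [h for h in T.labels.index if h in pheno.biomass.index]
    if len(common) < 3:
        raise ValueError("need at least 3 phenotyped hybrids")
    frac = (T.labels.loc[common] != 0).mean(axis=1)

    def corr(x: pd.Series, y: pd.Series) -> tuple[float, float] | None:
        if x.nunique() < 2 or y.nunique() < 2:
            return None
        r, p = stats.pearsonr(x, y)
        return float(r), float(p)

    biomass = pheno.biomass[common]
    pooled = corr(frac, biomass)
    per_trial: dict[str, tuple[float, float] | None] = {}
    for lab in sorted(pheno.trial[common].dropna().unique()):
        idx = [h for h in common if pheno.trial[h] == lab]
        if len(idx) >= 3:
            per_trial[lab] = corr(frac[idx], biomass[idx])
    return NonAdditivityReport(fraction=frac, pooled=pooled, per_trial=per_trial)
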