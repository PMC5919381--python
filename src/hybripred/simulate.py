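"""Synthetic Dent x Flint panels with planted inheritance and biomass structure.

The generator emulates the study design end to end: parental inbred lines
with correlated log10 analyte profiles, a partial-factorial set of crosses,
per-hybrid mIP class labels that determine the hybrid's analyte level
relative to its parents (mid-parent for additivity, one parent's level for
dominance, outside the parental range by ``delta`` for overdominance),
replicate-level Gaussian noise, and field biomass driven linearly by a small
set of causal maternal analytes plus a between-trial mean offset.

Two label mechanisms coexist: "informative" analytes derive their labels
from a thresholded linear score of the causal maternal analyte levels (so
the labels are learnable from the parental predictor matrix and the causal
analytes carry the ranking signal), while the remaining analytes draw labels
iid from an additivity-heavy propensity vector (and are meant to fall to the
class-balance filter). Every planted quantity is returned as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    ROLE_DENT,
    ROLE_FLINT,
    ROLE_HYBRID,
    MatingDesign,
    PhenotypeTable,
    ProfileMatrix,
    cross_id,
)

CLASSES = (-2, -1, 0, 1, 2)


@dataclass
class SimConfig:
    """Study-scale defaults: 24 x 25 lines, ~332 crosses, 269 analytes."""

    n_dents: int = 24
    n_flints: int = 25
    cross_fraction: float = 332 / 600
    n_analytes: int = 269
    n_replicates: int = 5
    # label structure
    informative_fraction: float = 0.3
    informative_propensities: tuple[float, ...] = (0.10, 0.20, 0.40, 0.20, 0.10)
    background_propensities: tuple[float, ...] = (0.02, 0.05, 0.86, 0.05, 0.02)
    label_noise_sd: float = 0.25  # noise on the causal score before thresholding
    # profile geometry (log10 intensity units)
    baseline_mean: float = 5.0
    line_sd: float = 2.0  # between-line spread per analyte
    factor_strength: float = 0.4  # share of line variance from shared latent factors
    n_factors: int = 5
    redundant_fraction: float = 0.5  # analytes that are noisy clones of another
    delta: float = 1.0  # overdominance offset beyond the parental range
    noise_sd: float = 0.5  # replicate-level noise
    # biomass model (dt/ha)
    n_causal: int = 5
    biomass_baseline: float = 560.0
    biomass_signal_sd: float = 45.0
    biomass_noise_sd: float = 30.0
    phenotyped_fraction: float = 328 / 332
    trial_labels: tuple[str, str] = ("2010", "2012")
    trial_fraction_second: float = 180 / 328
    trial_offset: float = 60.0  # added to the second trial's biomass
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.cross_fraction <= 1:
            raise ValueError("cross_fraction must be in (0, 1]")
        for name in ("line_sd", "noise_sd", "biomass_noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for p in (self.informative_propensities, self.background_propensities):
            if len(p) != 5 or abs(sum(p) - 1.0) > 1e-9 or min(p) < 0:
                raise ValueError("propensities must be 5 non-negative values summing to 1")
        if self.delta <= 0 and (self.informative_propensities[0] > 0
                                or self.informative_propensities[4] > 0):
            raise ValueError("delta must be > 0 when overdominance classes are planted")
        if self.n_causal > self.n_analytes:
            raise ValueError("causal set larger than the analyte set")


@dataclass
class GroundTruth:
    labels: pd.DataFrame  # hybrid x analyte planted mIP labels
    causal_analytes: list[str]  # untagged analyte ids (maternal copies are causal)
    causal_columns: list[str]  # "D:<analyte>" predictor column ids
    causal_weights: dict[str, float]
    informative_analytes: list[str]
    redundant_pairs: list[tuple[str, str]]  # (source, clone)
    trial_offset: float
    config: SimConfig = field(repr=False, default=None)


def _assign_labels_from_score(u: np.ndarray, props: np.ndarray,
                              rng: np.random.Generator) -> np.ndarray:
    """Cut a continuous score into the five classes at its empirical quantiles."""
    n = len(u)
    order = np.argsort(u, kind="stable")
    bounds = np.floor(np.cumsum(props) * n + 1e-9).astype(int)
    labels = np.empty(n, dtype=int)
    start = 0
    for cls, stop in zip(CLASSES, bounds):
        labels[order[start:stop]] = cls
        start = stop
    labels[order[start:]] = CLASSES[-1]
    return labels


def simulate_panel(config: SimConfig | None = None) -> tuple[
        MatingDesign, ProfileMatrix, PhenotypeTable, GroundTruth]:
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)

    dents = [f"D{i+1:02d}" for i in range(cfg.n_dents)]
    flints = [f"F{i+1:02d}" for i in range(cfg.n_flints)]
    analytes = [f"A{j+1:03d}" for j in range(cfg.n_analytes)]

    all_pairs = [(d, f) for d in dents for f in flints]
    n_crosses = max(1, int(round(cfg.cross_fraction * len(all_pairs))))
    idx = rng.choice(len(all_pairs), size=n_crosses, replace=False)
    crosses = [all_pairs[i] for i in sorted(idx)]
    hybrids = [cross_id(d, f) for d, f in crosses]

    # causal / informative / redundant analyte roles
    n_info = max(1, int(round(cfg.informative_fraction * cfg.n_analytes)))
    info_idx = rng.choice(cfg.n_analytes, size=n_info, replace=False)
    informative = sorted(analytes[i] for i in info_idx)
    causal = sorted(str(a) for a in rng.choice(
        informative, size=min(cfg.n_causal, n_info), replace=False))
    non_info = [a for a in analytes if a not in set(informative)]
    n_red = min(len(non_info) // 2, int(round(cfg.redundant_fraction * cfg.n_analytes)))
    clones = (sorted(str(a) for a in rng.choice(non_info, size=n_red, replace=False))
              if n_red > 0 else [])
    sources = [a for a in non_info if a not in set(clones)]
    clone_src = {c: str(rng.choice(sources)) for c in clones}

    # parental line values with a low-rank shared component
    lines = dents + flints
    mu = rng.normal(cfg.baseline_mean, 0.5, size=cfg.n_analytes)
    G = rng.normal(size=(len(lines), cfg.n_factors))
    L = rng.normal(size=(cfg.n_analytes, cfg.n_factors)) / np.sqrt(cfg.n_factors)
    shared = G @ L.T
    eps = rng.normal(size=(len(lines), cfg.n_analytes))
    cf = cfg.factor_strength
    line_vals = mu + cfg.line_sd * (cf * shared + np.sqrt(1 - cf**2) * eps)
    line_vals = pd.DataFrame(line_vals, index=lines, columns=analytes)
    for c, src in clone_src.items():
        line_vals[c] = line_vals[src] + rng.normal(
            0, 0.15 * cfg.line_sd, size=len(lines))

    # causal maternal z-scores per hybrid
    dent_vals = line_vals.loc[dents, causal]
    z_by_dent = (dent_vals - dent_vals.mean()) / dent_vals.std(ddof=1)
    Z = np.array([z_by_dent.loc[d].to_numpy() for d, _ in crosses])  # |H| x n_causal

    # planted labels
    props_info = np.array(cfg.informative_propensities)
    props_bg = np.array(cfg.background_propensities)
    labels = pd.DataFrame(0, index=hybrids, columns=analytes, dtype=int)
    info_weights = {}
    for a in analytes:
        if a in set(informative):
            w = rng.normal(size=Z.shape[1])
            w /= np.linalg.norm(w)
            info_weights[a] = w
            u = Z @ w + rng.normal(0, cfg.label_noise_sd, size=len(hybrids))
            labels[a] = _assign_labels_from_score(u, props_info, rng)
        elif a not in clone_src:
            labels[a] = rng.choice(CLASSES, size=len(hybrids), p=props_bg)
    for c, src in clone_src.items():
        labels[c] = labels[src]  # a redundant analyte inherits like its source

    # genotype means: parents from line values, hybrids from planted labels
    geno_means = {g: line_vals.loc[g].to_numpy() for g in lines}
    pa = line_vals.to_numpy()
    col_pos = {a: j for j, a in enumerate(analytes)}
    for (d, f), h in zip(crosses, hybrids):
        pd_, pf_ = line_vals.loc[d].to_numpy(), line_vals.loc[f].to_numpy()
        hi, lo = np.maximum(pd_, pf_), np.minimum(pd_, pf_)
        mid = 0.5 * (pd_ + pf_)
        lab = labels.loc[h].to_numpy()
        m = mid.copy()
        # dominance: the high (low) parent's level, at least delta from the other
        m[lab == 1] = np.maximum(hi, lo + cfg.delta)[lab == 1]
        m[lab == -1] = np.minimum(lo, hi - cfg.delta)[lab == -1]
        m[lab == 2] = hi[lab == 2] + cfg.delta
        m[lab == -2] = lo[lab == -2] - cfg.delta
        geno_means[h] = m

    genotypes = lines + hybrids
    n_rows = len(genotypes) * cfg.n_replicates
    values = np.empty((n_rows, cfg.n_analytes))
    rep_ids, geno_col = [], []
    for gi, g in enumerate(genotypes):
        block = slice(gi * cfg.n_replicates, (gi + 1) * cfg.n_replicates)
        values[block] = geno_means[g] + rng.normal(
            0, cfg.noise_sd, size=(cfg.n_replicates, cfg.n_analytes))
        rep_ids += [f"{g}_r{r+1}" for r in range(cfg.n_replicates)]
        geno_col += [g] * cfg.n_replicates
    role_of = {g: ROLE_DENT for g in dents}
    role_of |= {g: ROLE_FLINT for g in flints}
    role_of |= {g: ROLE_HYBRID for g in hybrids}
    profiles = ProfileMatrix(
        pd.DataFrame(values, index=pd.Index(rep_ids), columns=analytes),
        pd.Series(geno_col, index=pd.Index(rep_ids)),
        role_of,
    )

    # biomass: linear in causal maternal z-levels, plus trial offset and noise
    v = rng.normal(size=len(causal))
    v *= cfg.biomass_signal_sd / max(np.linalg.norm(v), 1e-12)
    n_pheno = max(4, int(round(cfg.phenotyped_fraction * len(hybrids))))
    pheno_idx = sorted(rng.choice(len(hybrids), size=min(n_pheno, len(hybrids)),
                                  replace=False))
    pheno_hybrids = [hybrids[i] for i in pheno_idx]
    n_second = int(round(cfg.trial_fraction_second * len(pheno_hybrids)))
    second = set(rng.choice(pheno_hybrids, size=n_second, replace=False))
    trial = pd.Series(
        [cfg.trial_labels[1] if h in second else cfg.trial_labels[0]
         for h in pheno_hybrids], index=pheno_hybrids)
    signal = Z[pheno_idx] @ v
    biomass = (cfg.biomass_baseline + signal
               + np.where(trial.to_numpy() == cfg.trial_labels[1], cfg.trial_offset, 0.0)
               + rng.normal(0, cfg.biomass_noise_sd, size=len(pheno_hybrids)))
    biomass = np.maximum(biomass, 1.0)
    pheno = PhenotypeTable(pd.Series(biomass, index=pheno_hybrids), trial)

    design = MatingDesign(dents, flints, crosses, trial_of=trial.to_dict())
    truth = GroundTruth(
        labels=labels,
        causal_analytes=list(causal),
        causal_columns=[f"D:{a}" for a in causal],
        causal_weights={a: float(x) for a, x in zip(causal, v)},
        informative_analytes=informative,
        redundant_pairs=[(s, c) for c, s in clone_src.items()],
        trial_offset=cfg.trial_offset,
        config=cfg,
    )
    return design, profiles, pheno, truth


@dataclass
class RecoveryReport:
    label_accuracy: dict[int, float]  # per planted class
    label_accuracy_overall: float | None
    causal_top_k: int
    causal_recovered: float | None  # fraction of causal columns in the top k
    r2_by_scenario: dict[str, float]
    ordering_ok: bool | None  # Top5 >= Random5 >= Bottom5 when all present
    passed: bool


def recovery_report(
    truth: GroundTruth,
    encoded=None,
    ranking=None,
    hp_records=None,
    top_k: int = 10,
    min_class_accuracy: float = 0.8,
    max_null_r2: float = 0.05,
    min_causal_fraction: float = 0.8,
) -> RecoveryReport:
    """Score pipeline outputs against the planted ground truth.

    Any of the three pipeline artefacts may be omitted; the corresponding
    checks are then skipped (reported as None) and do not fail the scorecard.
    """
    checks: list[bool] = []

    per_class: dict[int, float] = {}
    overall = None
    if encoded is not None:
        common = [a for a in encoded.labels.columns if a in truth.labels.columns]
        est = encoded.labels[common]
        ref = truth.labels.loc[est.index, common]
        agree = (est.to_numpy() == ref.to_numpy())
        overall = float(agree.mean())
        for cls in CLASSES:
            mask = ref.to_numpy() == cls
            if mask.any():
                per_class[cls] = float(agree[mask].mean())
        checks += [acc >= min_class_accuracy for acc in per_class.values()]

    recovered = None
    if ranking is not None:
        top = set(ranking.top(top_k))
        recovered = sum(c in top for c in truth.causal_columns) / len(truth.causal_columns)
        checks.append(recovered >= min_causal_fraction)

    r2s: dict[str, float] = {}
    ordering = None
    if hp_records is not None:
        from .performance import record_frame

        df = record_frame(hp_records)
        df = df[df["mode"] == "regression"]
        r2s = {s: float(g["r2"].median()) for s, g in df.groupby("scenario")}
        if all(k in r2s for k in ("Top5", "Random5", "Bottom5")):
            ordering = r2s["Top5"] >= r2s["Random5"] >= r2s["Bottom5"]
            checks.append(ordering)
        if "All-perm" in r2s:
            checks.append(r2s["All-perm"] < max_null_r2)

    return RecoveryReport(
        label_accuracy=per_class,
        label_accuracy_overall=overall,
        causal_top_k=top_k,
        causal_recovered=recovered,
        r2_by_scenario=r2s,
        ordering_ok=ordering,
        passed=all(checks) if checks else False,
    )
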