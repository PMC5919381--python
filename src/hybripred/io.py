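"""Readers/writers for panel tables and the between-trial comparison.

The on-disk layout mirrors the supplementary-data shape the framework was
designed around: a profile table with one row per biological replicate
(columns ``replicate``, ``genotype``, ``role`` followed by one column per
analyte, values log10 intensities) and a phenotype table with columns
``cross``, ``biomass``, ``trial``. CSV, TSV and XLSX dialects are accepted.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    CROSS_SEP,
    ROLE_DENT,
    ROLE_FLINT,
    ROLE_HYBRID,
    MatingDesign,
    PanelConsistencyError,
    PanelFormatError,
    PhenotypeTable,
    ProfileMatrix,
    cross_id,
)

_META_COLS = ("replicate", "genotype", "role")


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".xlsx", ".xls"):
        return pd.read_excel(path)
    sep = "\t" if suffix in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep)


def load_panel(
    profile_path: str | Path,
    phenotype_path: str | Path | None = None,
    sep: str = CROSS_SEP,
) -> tuple[MatingDesign, ProfileMatrix, PhenotypeTable | None]:
    """Load a panel from disk and cross-validate design, profiles, phenotypes.

    Hybrids without a phenotype are retained in the design (flagged by their
    absence from the returned :class:`PhenotypeTable`). A hybrid whose parents
    lack profiles is a consistency error naming the offending parent.
    """
    prof = _read_table(profile_path)
    missing = [c for c in _META_COLS if c not in prof.columns]
    if missing:
        raise PanelFormatError(f"profile table lacks column(s) {missing}")
    analyte_cols = [c for c in prof.columns if c not in _META_COLS]
    if not analyte_cols:
        raise PanelFormatError("profile table has no analyte columns")
    values = prof[analyte_cols].apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & prof[analyte_cols].notna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise PanelFormatError(
            f"non-numeric intensity at row {r}, column {analyte_cols[c]!r}"
        )
    values.index = prof["replicate"].astype(str)
    genotype_of = pd.Series(prof["genotype"].astype(str).to_numpy(), index=values.index)
    roles = prof.groupby(prof["genotype"].astype(str))["role"].agg(
        lambda s: s.astype(str).str.lower().iloc[0]
    )
    role_of = roles.to_dict()
    for g, r in role_of.items():
        if r not in (ROLE_DENT, ROLE_FLINT, ROLE_HYBRID):
            raise PanelFormatError(f"unknown role {r!r} for genotype {g!r}")
    profiles = ProfileMatrix(values, genotype_of, role_of)

    dents = sorted(g for g, r in role_of.items() if r == ROLE_DENT)
    flints = sorted(g for g, r in role_of.items() if r == ROLE_FLINT)
    hybrids = sorted(g for g, r in role_of.items() if r == ROLE_HYBRID)
    crosses = []
    for h in hybrids:
        if sep not in h:
            raise PanelFormatError(
                f"hybrid id {h!r} is not of the form <dent>{sep}<flint>"
            )
        d, f = h.split(sep, 1)
        if d not in role_of:
            raise PanelConsistencyError(f"hybrid {h!r}: no profiles for parent {d!r}")
        if f not in role_of:
            raise PanelConsistencyError(f"hybrid {h!r}: no profiles for parent {f!r}")
        crosses.append((d, f))

    pheno = None
    trial_of: dict[str, str] = {}
    if phenotype_path is not None:
        ptab = _read_table(phenotype_path)
        need = [c for c in ("cross", "biomass", "trial") if c not in ptab.columns]
        if need:
            raise PanelFormatError(f"phenotype table lacks column(s) {need}")
        cid = ptab["cross"].astype(str)
        if cid.duplicated().any():
            raise PanelFormatError(f"duplicated phenotype row {cid[cid.duplicated()].iloc[0]!r}")
        biomass = pd.to_numeric(ptab["biomass"], errors="coerce")
        if biomass.isna().any():
            raise PanelFormatError("non-numeric biomass value")
        known = set(hybrids)
        unknown = [c for c in cid if c not in known]
        if unknown:
            raise PanelConsistencyError(
                f"phenotyped cross {unknown[0]!r} absent from the profile panel"
            )
        pheno = PhenotypeTable(
            pd.Series(biomass.to_numpy(), index=cid),
            pd.Series(ptab["trial"].astype(str).to_numpy(), index=cid),
        )
        trial_of = pheno.trial.to_dict()

    design = MatingDesign(dents, flints, crosses, trial_of=trial_of, sep=sep)
    return design, profiles, pheno


def save_panel(
    design: MatingDesign,
    profiles: ProfileMatrix,
    pheno: PhenotypeTable | None,
    profile_path: str | Path,
    phenotype_path: str | Path | None = None,
) -> None:
    """Write a panel in the dialect :func:`load_panel` reads (round-trip safe)."""
    out = profiles.values.copy()
    out.insert(0, "role", [profiles.role_of[g] for g in profiles.genotype_of])
    out.insert(0, "genotype", profiles.genotype_of.to_numpy())
    out.insert(0, "replicate", out.index)
    out.to_csv(profile_path, index=False)
    if pheno is not None and phenotype_path is not None:
        pd.DataFrame(
            {"cross": pheno.cross_ids, "biomass": pheno.biomass.to_numpy(),
             "trial": pheno.trial.to_numpy()}
        ).to_csv(phenotype_path, index=False)


@dataclasses.dataclass
class TrialComparison:
    groups: dict[str, dict[str, float]]  # trial -> {"n": ..., "mean": ...}
    t: float
    p: float
    welch: bool


def compare_trials(pheno: PhenotypeTable, welch: bool = False) -> TrialComparison:
    """Two-sample t-test of hybrid biomass between the two field trials.

    Pooled-variance by default (the classic two-tailed t-test); Welch by flag.
    """
    labels = sorted(pheno.trial.dropna().unique())
    if len(labels) < 2:
        raise ValueError("nothing to compare: fewer than two trial labels")
    if len(labels) > 2:
        raise ValueError(f"expected two trials, found {labels}")
    a = pheno.biomass[pheno.trial == labels[0]]
    b = pheno.biomass[pheno.trial == labels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each trial needs at least 2 hybrids")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    groups = {
        lab: {"n": int(len(x)), "mean": float(x.mean())}
        for lab, x in ((labels[0], a), (labels[1], b))
    }
    return TrialComparison(groups=groups, t=float(t), p=float(p), welch=welch)
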