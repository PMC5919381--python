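"""Typed containers for a Dent x Flint partial-factorial metabolomics panel.

The panel couples three tables: the mating design (which crosses were made),
replicate-level metabolic profiles of parents and hybrids, and field
phenotypes (whole-plant biomass, dt/ha) of the hybrids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ROLE_DENT = "dent"
ROLE_FLINT = "flint"
ROLE_HYBRID = "hybrid"

#: separator used in canonical cross identifiers "<dent>x<flint>"
CROSS_SEP = "×"


class PanelFormatError(ValueError):
    """Malformed input table (duplicated ids, non-numeric cells, ...)."""


class PanelConsistencyError(ValueError):
    """Tables that are individually well-formed but mutually inconsistent."""


def cross_id(dent: str, flint: str, sep: str = CROSS_SEP) -> str:
    return f"{dent}{sep}{flint}"


@dataclass
class MatingDesign:
    """Partial-factorial Dent (maternal) x Flint (paternal) mating design.

    ``crosses`` may be any subset of the full factorial ``dents x flints``.
    """

    dents: list[str]
    flints: list[str]
    crosses: list[tuple[str, str]]
    trial_of: dict[str, str] = field(default_factory=dict)
    sep: str = CROSS_SEP

    def __post_init__(self) -> None:
        dset, fset = set(self.dents), set(self.flints)
        seen: set[tuple[str, str]] = set()
        for d, f in self.crosses:
            if d not in dset:
                raise PanelConsistencyError(f"cross references unknown dent {d!r}")
            if f not in fset:
                raise PanelConsistencyError(f"cross references unknown flint {f!r}")
            if (d, f) in seen:
                raise PanelFormatError(f"duplicated cross {d!r} x {f!r}")
            seen.add((d, f))

    @property
    def cross_ids(self) -> list[str]:
        return [cross_id(d, f, self.sep) for d, f in self.crosses]

    def parents_of(self, cid: str) -> tuple[str, str]:
        d, f = cid.split(self.sep, 1)
        return d, f

    def __len__(self) -> int:
        return len(self.crosses)


@dataclass
class ProfileMatrix:
    """Replicate x analyte matrix of log10 intensities with genotype labels.

    ``values`` has one row per biological replicate; ``genotype_of`` maps row
    position to genotype id and ``role_of`` maps genotype id to its role in
    the design (dent / flint / hybrid).
    """

    values: pd.DataFrame  # index: replicate id, columns: analyte ids
    genotype_of: pd.Series  # index aligned with values.index
    role_of: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise PanelFormatError(f"duplicated replicate id {dup!r}")
        if pd.Index(self.analyte_ids).has_duplicates:
            raise PanelFormatError("duplicated analyte ids")
        if self.values.isna().any().any():
            r, c = np.argwhere(self.values.isna().to_numpy())[0]
            raise PanelFormatError(
                f"missing intensity at replicate {self.values.index[r]!r}, "
                f"analyte {self.values.columns[c]!r}"
            )
        counts = self.genotype_of.value_counts()
        thin = counts[counts < 2]
        if len(thin):
            raise PanelConsistencyError(
                f"genotype {thin.index[0]!r} has {thin.iloc[0]} replicate(s); "
                "at least 2 are required for contrasts"
            )

    @property
    def analyte_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_analytes(self) -> int:
        return self.values.shape[1]

    def replicates(self, genotype: str) -> pd.DataFrame:
        """Replicate rows of one genotype."""
        mask = (self.genotype_of == genotype).to_numpy()
        if not mask.any():
            raise KeyError(f"no replicates for genotype {genotype!r}")
        return self.values.loc[mask]

    def genotype_means(self) -> pd.DataFrame:
        """Genotype x analyte matrix of replicate means."""
        return self.values.groupby(self.genotype_of.to_numpy()).mean()

    def subset_analytes(self, analytes: list[str]) -> "ProfileMatrix":
        return ProfileMatrix(self.values[list(analytes)], self.genotype_of, self.role_of)


@dataclass
class PhenotypeTable:
    """Field performance (biomass, dt/ha) of phenotyped hybrids with trial labels."""

    biomass: pd.Series  # index: cross id
    trial: pd.Series  # index: cross id

    def __post_init__(self) -> None:
        if (self.biomass <= 0).any():
            bad = self.biomass[self.biomass <= 0].index[0]
            raise PanelFormatError(f"non-positive biomass for cross {bad!r}")
        if not self.biomass.index.equals(self.trial.index):
            self.trial = self.trial.reindex(self.biomass.index)

    @property
    def cross_ids(self) -> list[str]:
        return list(self.biomass.index)

    def __len__(self) -> int:
        return len(self.biomass)
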