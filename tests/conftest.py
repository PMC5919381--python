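import numpy as np
import pandas as pd
import pytest

from hybripred import (
    InheritanceMatrix,
    build_predictor_matrix,
    class_balance_filter,
    encode_panel,
    panel_contrasts,
    redundancy_filter,
)
from hybripred.simulate import SimConfig, simulate_panel


@pytest.fixture(scope="session")
def small_panel():
    """A ~200-hybrid planted-signal panel shared by the model-level tests."""
    cfg = SimConfig(n_dents=16, n_flints=16, cross_fraction=0.8, n_analytes=40,
                    n_replicates=5, seed=7)
    design, profiles, pheno, truth = simulate_panel(cfg)
    return design, profiles, pheno, truth


@pytest.fixture(scope="session")
def small_pipeline(small_panel):
    """The small panel taken through filtering, predictors and encoding."""
    design, profiles, pheno, truth = small_panel
    retained, _ = redundancy_filter(profiles)
    X_DF = build_predictor_matrix(design, profiles, retained)
    contrasts = panel_contrasts(design, profiles, analytes=retained)
    T, _ = class_balance_filter(encode_panel(contrasts))
    return design, profiles, pheno, truth, X_DF, T


def toy_profile_frame():
    """1 dent x 1 flint x 1 hybrid, 3 replicates each, 2 analytes."""
    rows = []
    rng = np.random.default_rng(0)
    for g, role in (("D1", "dent"), ("F1", "flint"), ("D1×F1", "hybrid")):
        for r in range(3):
            rows.append({"replicate": f"{g}_r{r+1}", "genotype": g, "role": role,
                         "m1": round(5 + rng.normal(0, 0.1), 4),
                         "m2": round(6 + rng.normal(0, 0.1), 4)})
    return pd.DataFrame(rows)
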