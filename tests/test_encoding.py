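"""mIP label encoding, class-balance filtering and the non-additivity check."""

import numpy as np
import pandas as pd
import pytest

from hybripred import (
    InheritanceMatrix,
    class_balance_filter,
    encode_mip,
    encode_panel,
    nonadditivity_vs_hp,
    panel_contrasts,
)
from hybripred.datamodel import PhenotypeTable
from hybripred.moderated import ContrastResult


def _stub_contrast(states):
    """ContrastResult whose significance states vs (b, w) are forced."""
    sb = np.array([s[0] for s in states])
    sw = np.array([s[1] for s in states])
    n = len(states)

    def t_p(sig_state):
        t = sig_state * 5.0  # |t|=5 when significant, 0 when not
        p = np.where(sig_state == 0, 0.9, 1e-4)
        return t.astype(float), p

    t_hb, p_hb = t_p(sb)
    t_hw, p_hw = t_p(sw)
    z = np.zeros(n)
    return ContrastResult(
        cross="h", analytes=[f"A{i}" for i in range(n)],
        mean_dent=z, mean_flint=z, mean_hybrid=z, s2=np.ones(n),
        df_residual=6.0, d0=4.0, s0sq=1.0, s2_moderated=np.ones(n),
        better_is_dent=np.ones(n, bool), t_hb=t_hb, p_hb=p_hb,
        t_hw=t_hw, p_hw=p_hw)


def hand_truth_table(sb: int, sw: int) -> int:
    """Independent rule-by-rule oracle for the five-way conditionals.

    '>' / '<' mean significantly above / below; '=' means not significant.
    The conditionals are stated for the six combinations consistent with the
    b >= w ordering; the remaining three mirror them under sign flip.
    """
    above_b, above_w = sb == 1, sw == 1
    below_b, below_w = sb == -1, sw == -1
    eq_b, eq_w = sb == 0, sw == 0
    if above_b and above_w:
        return 2
    if eq_b and above_w:
        return 1
    if (eq_b and eq_w) or (below_b and above_w) or (above_b and below_w):
        return 0
    if below_b and eq_w:
        return -1
    if below_b and below_w:
        return -2
    if above_b and eq_w:  # mirror of (eq_b, below_w)
        return 1
    if eq_b and below_w:
        return -1
    raise AssertionError("unreachable")


def test_truth_table_matches_hand_oracle_for_all_states():
    states = [(sb, sw) for sb in (-1, 0, 1) for sw in (-1, 0, 1)]
    labels = encode_mip(_stub_contrast(states), alpha=0.05)
    expected = [hand_truth_table(sb, sw) for sb, sw in states]
    assert list(labels) == expected


def test_encoding_antisymmetry_under_intensity_negation(small_panel):
    design, profiles, _, _ = small_panel
    sub = profiles.subset_analytes(profiles.analyte_ids[:8])
    neg = type(sub)(-sub.values, sub.genotype_of, sub.role_of)
    T_pos = encode_panel(panel_contrasts(design, sub))
    T_neg = encode_panel(panel_contrasts(design, neg))
    pd.testing.assert_frame_equal(T_neg.labels, -T_pos.labels)


def test_encoding_invariant_to_parent_storage_order(small_panel):
    """Swapping the dent/flint argument order leaves labels unchanged.

    Only the better/worse parent ordering matters for the encoding, not
    which parent is passed as maternal or paternal.
    """
    from hybripred.moderated import moderated_contrasts

    design, profiles, _, _ = small_panel
    analytes = profiles.analyte_ids[:6]
    sub = profiles.subset_analytes(analytes)
    for d, f in design.crosses[:5]:
        h = f"{d}{design.sep}{f}"
        dr, fr, hr = (sub.replicates(g).to_numpy() for g in (d, f, h))
        lab1 = encode_mip(moderated_contrasts(dr, fr, hr, analytes, cross=h))
        lab2 = encode_mip(moderated_contrasts(fr, dr, hr, analytes, cross=h))
        np.testing.assert_array_equal(lab1, lab2)


def _label_matrix(counts_per_analyte: dict[str, dict[int, int]]) -> InheritanceMatrix:
    n = sum(next(iter(counts_per_analyte.values())).values())
    cols = {}
    for analyte, counts in counts_per_analyte.items():
        col = np.concatenate([np.full(v, c) for c, v in counts.items()])
        assert len(col) == n
        cols[analyte] = col
    labels = pd.DataFrame(cols, index=[f"D{i}×F{i}" for i in range(n)])
    return InheritanceMatrix(labels=labels.astype(int))


def test_balance_filter_spec_toys():
    T = _label_matrix({
        "keep_singleton": {0: 14, 1: 5, 2: 1},   # kept, one hybrid excluded
        "drop_pair": {0: 14, 1: 4, 2: 2},        # class with 2 occurrences
        "all_additive": {0: 20},                 # fraction 1.0 > 0.75
        "balanced": {-1: 5, 0: 10, 1: 5},
    })
    out, decisions = class_balance_filter(T)
    kept = set(out.labels.columns)
    assert kept == {"keep_singleton", "balanced"}
    assert len(out.excluded_hybrids["keep_singleton"]) == 1
    reasons = {d.analyte: d.reason for d in decisions}
    assert "fraction" in reasons["all_additive"]
    assert "2-3" in reasons["drop_pair"]


def test_balance_filter_rule_by_rule_hand_evaluation():
    """Every decision agrees with a direct evaluation of the stated rules."""
    cases = {
        "a_75pct_exact": {0: 15, 1: 5},          # 0.75 is not > 0.75: kept
        "b_over_75": {0: 16, 1: 4},              # 0.8 > 0.75: dropped
        "c_two_singletons": {0: 10, 1: 8, 2: 1, -1: 1},  # ambiguous: dropped
        "d_singleton_plus_pair": {0: 12, 1: 5, 2: 2, -1: 1},  # rule ii fires
        "e_absent_class_ok": {-1: 6, 0: 8, 1: 6},
    }
    out, _ = class_balance_filter(_label_matrix(cases))
    assert set(out.labels.columns) == {"a_75pct_exact", "e_absent_class_ok"}


def test_balance_filter_order_independent():
    T = _label_matrix({
        "x": {0: 14, 1: 5, 2: 1}, "y": {0: 16, 1: 4}, "z": {-1: 5, 0: 10, 1: 5}})
    rev = InheritanceMatrix(labels=T.labels[["z", "y", "x"]].copy())
    out1, _ = class_balance_filter(T)
    out2, _ = class_balance_filter(rev)
    assert set(out1.labels.columns) == set(out2.labels.columns)
    assert out1.excluded_hybrids == out2.excluded_hybrids


def test_label_vector_drops_excluded_hybrid():
    T = _label_matrix({"k": {0: 14, 1: 5, 2: 1}})
    out, _ = class_balance_filter(T)
    vec = out.label_vector("k")
    assert len(vec) == 19 and (vec == 2).sum() == 0


def _pheno(biomass: np.ndarray) -> PhenotypeTable:
    idx = [f"D{i}×F{i}" for i in range(len(biomass))]
    return PhenotypeTable(pd.Series(biomass, index=idx),
                          pd.Series(["t1"] * len(biomass), index=idx))


def test_nonadditivity_null_and_planted_sign():
    rng = np.random.default_rng(8)
    n = 300
    labels = pd.DataFrame(rng.choice([-1, 0, 1], size=(n, 20), p=[0.2, 0.6, 0.2]),
                          index=[f"D{i}×F{i}" for i in range(n)])
    T = InheritanceMatrix(labels=labels)
    null = nonadditivity_vs_hp(T, _pheno(rng.normal(600, 30, n)))
    r, p = null.pooled
    assert abs(r) < 0.15 and p > 0.01
    frac = (labels != 0).mean(axis=1).to_numpy()
    planted = nonadditivity_vs_hp(
        T, _pheno(500 + 200 * frac + rng.normal(0, 5, n)))
    r2, p2 = planted.pooled
    assert r2 > 0.5 and p2 < 1e-6


def test_nonadditivity_constant_fraction_undefined():
    labels = pd.DataFrame(np.zeros((10, 4), dtype=int),
                          index=[f"D{i}×F{i}" for i in range(10)])
    rep = nonadditivity_vs_hp(InheritanceMatrix(labels=labels),
                              _pheno(np.linspace(500, 600, 10)))
    assert rep.pooled is None
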