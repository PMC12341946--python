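"""Memory/strain/interaction classification against literal-rule oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from memorytc import (
    assign_direction,
    classify_effect,
    classify_interaction,
    classify_strain,
    overlap_summary,
    proportion_test,
)


def _literal_effect_rule(bt, bi):
    """Independent transcription of the stated comparison rules."""
    s = bt + bi
    if s == 0:
        return "dampened"
    if (s > 0) != (bt > 0):
        return "reversed"
    if abs(s) > abs(bt):
        return "enhanced"
    if abs(s) < abs(bt):
        return "dampened"
    return "no_change"


def _literal_interaction_rule(bt, btm, bts, btms):
    additive = bt + btm + bts
    net = additive + btms
    if net == 0:
        return "dampened"
    if (net > 0) != (bt > 0):
        return "reversed"
    if abs(net) > abs(additive):
        return "enhanced"
    if abs(net) < abs(additive):
        return "dampened"
    return "no_change"


@pytest.mark.parametrize(
    "bt,bi,label",
    [
        (2.0, -1.0, "dampened"),
        (2.0, -5.0, "reversed"),
        (1.0, 0.5, "enhanced"),
        (-2.0, 1.0, "dampened"),
        (-1.0, -0.5, "enhanced"),
        (-2.0, 5.0, "reversed"),
        (2.0, -2.0, "dampened"),  # exact cancellation: total suppression
        (2.0, 0.0, "no_change"),
    ],
)
def test_effect_rule_forced_cases(bt, bi, label):
    assert classify_effect(bt, bi) == label
    assert classify_strain(bt, bi) == label


def test_not_significant_is_no_change_regardless_of_magnitudes():
    assert classify_effect(2.0, -5.0, significant=False) == "no_change"
    assert classify_interaction(2.0, -0.5, -0.5, -3.0, significant=False) == "no_change"


@pytest.mark.parametrize(
    "coeffs,label",
    [
        ((2.0, -0.5, -0.5, -0.5), "dampened"),  # net 0.5 < additive 1
        ((2.0, -0.5, -0.5, 1.0), "enhanced"),   # net 2 > additive 1
        ((2.0, -0.5, -0.5, -1.5), "reversed"),  # net -0.5, sign flip vs bt
        ((2.0, -0.5, -0.5, 0.0), "no_change"),
    ],
)
def test_interaction_rule_forced_cases(coeffs, label):
    bt, btm, bts, btms = coeffs
    sig = btms != 0.0
    assert classify_interaction(bt, btm, bts, btms, significant=sig) == label


def test_classifier_agrees_with_literal_rules_on_random_vectors():
    rng = np.random.default_rng(2024)
    for _ in range(1000):
        bt, btm, bts, btms = rng.normal(0, 1, 4)
        if bt == 0:
            continue
        assert classify_effect(bt, btm) == _literal_effect_rule(bt, btm)
        assert classify_strain(bt, bts) == _literal_effect_rule(bt, bts)
        assert classify_interaction(bt, btm, bts, btms) == _literal_interaction_rule(
            bt, btm, bts, btms
        )


def test_scale_equivariance_of_labels():
    rng = np.random.default_rng(7)
    for _ in range(200):
        bt, bi = rng.normal(0, 1, 2)
        c = rng.uniform(0.01, 100)
        assert classify_effect(bt, bi) == classify_effect(c * bt, c * bi)


from hypothesis import given, settings, strategies as st

_coef = st.floats(min_value=-10, max_value=10, allow_nan=False)


@settings(derandomize=True, max_examples=200)
@given(bt=_coef.filter(lambda x: abs(x) > 1e-6), bi=_coef)
def test_effect_label_is_exhaustive_and_matches_literal_rule(bt, bi):
    label = classify_effect(bt, bi)
    assert label in {"enhanced", "dampened", "reversed", "no_change"}
    assert label == _literal_effect_rule(bt, bi) or abs(abs(bt + bi) - abs(bt)) < 1e-8


@settings(derandomize=True, max_examples=200)
@given(bt=_coef.filter(lambda x: abs(x) > 1e-6), btm=_coef, bts=_coef, btms=_coef)
def test_interaction_label_is_exhaustive(bt, btm, bts, btms):
    label = classify_interaction(bt, btm, bts, btms)
    assert label in {"enhanced", "dampened", "reversed", "no_change"}


@pytest.mark.parametrize(
    "bt,bt2,lin,quad,expected",
    [
        (1.0, 0.0, True, False, "induced"),
        (-1.0, 0.0, True, False, "repressed"),
        (0.0, 0.01, False, True, "induced"),   # net change 0.01*400 > 0
        (0.0, -0.01, False, True, "repressed"),
        (0.0, 0.0, False, False, "flat"),
    ],
)
def test_direction_assignment(bt, bt2, lin, quad, expected):
    assert assign_direction(bt, bt2, lin, quad, 0.0, 20.0) == expected


def _classes_frame(rows):
    df = pd.DataFrame(
        rows, columns=["memory_effect", "strain_effect", "interaction_effect"]
    )
    df.index = [f"g{i}" for i in range(len(df))]
    df.index.name = "gene_id"
    return df


def test_overlap_summary_single_group():
    df = _classes_frame([("dampened", "no_change", "no_change")] * 5)
    tab = overlap_summary(df)
    assert tab.loc[tab["combination"] == "memory", "n_genes"].item() == 5
    assert tab["n_genes"].sum() == 5


def test_overlap_summary_matches_hand_enumeration():
    rng = np.random.default_rng(3)
    labels = ["enhanced", "dampened", "reversed", "no_change"]
    rows = [tuple(rng.choice(labels, 3)) for _ in range(30)]
    df = _classes_frame(rows)
    tab = overlap_summary(df).set_index("combination")["n_genes"]
    affected = {"enhanced", "dampened", "reversed"}
    counts = {}
    for m, s, i in rows:
        key_parts = [n for n, v in (("memory", m), ("strain", s), ("interaction", i))
                     if v in affected]
        key = "+".join(key_parts) if key_parts else "none"
        counts[key] = counts.get(key, 0) + 1
    for key, n in counts.items():
        assert tab[key] == n
    assert tab.sum() == 30


def test_proportion_test_subset_equals_background():
    df = _classes_frame([("dampened", "no_change", "dampened")] * 10
                        + [("enhanced", "no_change", "no_change")] * 10)
    res = proportion_test(df.index, df, factor="interaction_effect")
    assert np.allclose(res["diff"], 0.0)
    assert (res["pvalue"] > 0.99).all()


def test_proportion_test_matches_hand_computed_z():
    # subset: 8/10 dampened; background: 20/100 dampened
    rows = [("no_change", "no_change", "dampened")] * 20 + [
        ("no_change", "no_change", "no_change")
    ] * 80
    df = _classes_frame(rows)
    subset = df.index[:10]  # first 10 rows: 10 dampened? no - first 20 are dampened
    res = proportion_test(subset, df, factor="interaction_effect")
    row = res.set_index("category").loc["dampened"]
    p1, p0, n1, n0 = 1.0, 0.2, 10, 100
    pooled = (10 + 20) / 110
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n0))
    z = (p1 - p0) / se
    assert row["z"] == pytest.approx(z)
    assert row["diff"] == pytest.approx(0.8)


def test_proportion_test_null_calibration():
    rng = np.random.default_rng(11)
    labels = rng.choice(["dampened", "no_change"], size=400, p=[0.3, 0.7])
    df = _classes_frame([(l, "no_change", l) for l in labels])
    rejections = 0
    n_draws = 200
    for _ in range(n_draws):
        subset = rng.choice(df.index, size=60, replace=False)
        res = proportion_test(subset, df, factor="interaction_effect")
        rejections += (res.set_index("category").loc["dampened", "pvalue"] < 0.05)
    # drawing the subset from the background itself: ~5% rejections
    assert rejections / n_draws <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_draws) + 0.02
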