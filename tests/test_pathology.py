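"""Histopathology classification, disease-table parsing, and incidence."""

import math

import numpy as np
import pandas as pd
import pytest

from epidmr import (
    abnormality_density,
    consensus_disease_call,
    control_threshold,
    fisher_exact_2x2,
    incidence_summary,
    load_f3_disease_table,
    parse_disease_table,
)
from epidmr.errors import InputError, InsufficientDataError, ParseError
from epidmr.pathology import classify_animals, compare_incidence


@pytest.mark.parametrize(
    "count,area,expected",
    [(10, 2.0, 5.0), (0, 3.0, 0.0), (7, 3.5, 2.0)],
)
def test_abnormality_density(count, area, expected):
    assert abnormality_density(count, area) == expected


def test_abnormality_density_rejects_bad_area():
    with pytest.raises(InputError):
        abnormality_density(1, 0.0)


@pytest.mark.parametrize(
    "densities,expected",
    [
        ([1, 2, 3], 4.0),
        ([5, 5, 5], 5.0),
        ([0, 10], 5 + 2 * math.sqrt(50)),  # n-1 sd = 7.0711
    ],
)
def test_control_threshold(densities, expected):
    assert control_threshold(densities) == pytest.approx(expected, abs=1e-9)


def test_control_threshold_needs_two_values():
    with pytest.raises(InsufficientDataError):
        control_threshold([1.0])


def test_control_threshold_dominates_mean():
    rng = np.random.default_rng(0)
    for _ in range(20):
        vals = rng.gamma(2.0, 1.0, size=rng.integers(2, 12))
        cutoff = control_threshold(vals)
        assert cutoff >= vals.mean() - 1e-12
    assert control_threshold([3, 3, 3]) == 3.0  # equality iff sd = 0


@pytest.mark.parametrize(
    "calls,expected",
    [
        ((True, True), True),
        ((True, False, False), False),
        ((True, False, True), True),  # two-of-three rule
        ((False, False), False),
    ],
)
def test_consensus_disease_call(calls, expected):
    assert consensus_disease_call(calls) is expected


def test_consensus_is_monotone_in_diseased_votes():
    # adding a diseased vote never flips diseased -> not diseased
    for base in [(False,), (True, False), (False, False), (True, True)]:
        if consensus_disease_call(base) and len(base) < 3:
            assert consensus_disease_call(tuple(base) + (True,))


def test_consensus_rejects_empty():
    with pytest.raises(InputError):
        consensus_disease_call([])


def _row(animal, flags):
    cols = ["late_puberty", "testis", "prostate", "kidney", "obesity", "tumor"]
    return {"animal_id": animal, **dict(zip(cols, flags))}


def test_parse_disease_table_derives_totals_and_multiple():
    df = pd.DataFrame(
        [
            _row("PS20", ["-", "+", "+", "+", "+", "-"]),
            _row("PS1", ["-", "-", "-", "-", "-", "-"]),
            _row("PS17", ["-", "n/a", "+", "-", "-", "-"]),
        ]
    )
    parsed = parse_disease_table(df)
    assert parsed.loc[0, "total_disease"] == 4
    assert bool(parsed.loc[0, "multiple_disease"])
    assert parsed.loc[1, "total_disease"] == 0
    assert not bool(parsed.loc[1, "multiple_disease"])
    assert pd.isna(parsed.loc[2, "testis"])  # excluded from denominators
    assert parsed.loc[2, "total_disease"] == 1


def test_parse_disease_table_rejects_unknown_symbol():
    df = pd.DataFrame([_row("PSX", ["-", "?", "-", "-", "-", "-"])])
    with pytest.raises(ParseError, match="PSX.*testis"):
        parse_disease_table(df)


def test_packaged_table_totals_row():
    """The transcribed 41-animal table reproduces its printed Totals row."""
    table = load_f3_disease_table()
    inc = incidence_summary(table).set_index("pathology")
    expected = {
        "late_puberty": (4, 37, 11),
        "testis": (14, 40, 35),
        "prostate": (8, 41, 20),
        "kidney": (14, 41, 34),
        "obesity": (3, 41, 7),
        "tumor": (1, 41, 2),
        "multiple_disease": (12, 41, 29),
    }
    for pathology, (pos, tot, pct) in expected.items():
        row = inc.loc[pathology]
        assert (row["n_positive"], row["n_evaluable"], row["percentage"]) == (
            pos, tot, pct
        )


def test_incidence_zero_positive():
    df = pd.DataFrame([_row(f"A{i}", ["-"] * 6) for i in range(5)])
    inc = incidence_summary(parse_disease_table(df)).set_index("pathology")
    assert inc.loc["testis", "n_positive"] == 0
    assert inc.loc["testis", "n_evaluable"] == 5
    assert inc.loc["testis", "percentage"] == 0


def _fisher_oracle(a, b, c, d):
    """Full hypergeometric enumeration with fixed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    denom = math.comb(r1 + r2, c1)
    probs = [
        math.comb(r1, x) * math.comb(r2, c1 - x) / denom
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
    ]
    p_obs = math.comb(r1, a) * math.comb(r2, c1 - a) / denom
    return sum(p for p in probs if p <= p_obs * (1 + 1e-9))


def test_fisher_exact_examples():
    assert fisher_exact_2x2(5, 5, 5, 5) == 1.0
    assert fisher_exact_2x2(0, 5, 5, 0) == pytest.approx(2 / 252, rel=1e-9)
    assert fisher_exact_2x2(3, 7, 9, 1) == pytest.approx(
        _fisher_oracle(3, 7, 9, 1), rel=1e-9
    )


def test_fisher_matches_enumeration_oracle():
    rng = np.random.default_rng(7)
    for _ in range(50):
        a, b, c, d = rng.integers(0, 12, size=4)
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            continue
        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
            _fisher_oracle(a, b, c, d), rel=1e-9
        )


def test_fisher_transposition_invariance():
    rng = np.random.default_rng(8)
    for _ in range(20):
        a, b, c, d = rng.integers(1, 15, size=4)
        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
            fisher_exact_2x2(a, c, b, d), rel=1e-12
        )


def test_fisher_rejects_negative():
    with pytest.raises(InputError):
        fisher_exact_2x2(-1, 2, 3, 4)


def test_compare_incidence_wraps_fisher():
    # 14/40 vs 1/40 should be clearly significant
    assert compare_incidence(14, 40, 1, 40) < 0.001


def test_classify_animals_two_sd_consensus():
    rows = []
    # controls C1..C4 low density; case A1 high; case A2 borderline-low
    for obs in ["o1", "o2"]:
        for animal, count in [("C1", 2), ("C2", 3), ("C3", 2), ("C4", 3)]:
            rows.append((animal, "testis", obs, count, 1.0))
        rows.append(("A1", "testis", obs, 30, 1.0))
        rows.append(("A2", "testis", obs, 3, 1.0))
    df = pd.DataFrame(
        rows,
        columns=["animal_id", "tissue", "observer_id",
                 "abnormality_count", "area_mm2"],
    )
    calls = classify_animals(df, ["C1", "C2", "C3", "C4"]).set_index(
        "animal_id"
    )
    assert bool(calls.loc["A1", "diseased"])
    assert not bool(calls.loc["A2", "diseased"])
    assert not bool(calls.loc["C1", "diseased"])
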