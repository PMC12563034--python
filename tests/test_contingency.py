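"""Contingency tables, margin-product expectations, indexed residuals, summaries."""

import numpy as np
import pandas as pd
import pytest

from oacsafety.contingency import (
    ContingencyTable,
    build_table,
    indexed_residuals,
    round_half_up,
    summarize,
)
from oacsafety.records import FilterSpec, apply_filters
from oacsafety.vocab import soc_codes
from oacsafety import synthetic


def test_round_half_up_is_half_away_from_zero():
    assert round_half_up(0.25, 1) == 0.3  # banker's rounding would give 0.2
    assert round_half_up(-16.666666, 1) == -16.7
    assert round_half_up(-0.05, 1) == -0.1
    assert round_half_up(0.04, 1) == 0.0


def test_build_table_uniform_and_degenerate(tiny_line_list):
    frame = tiny_line_list[tiny_line_list["soc"] != "Soc"]
    table = build_table(frame, drugs=("warfarin", "rivaroxaban"),
                        socs=("Gastr", "Nerv", "Inv"))
    assert table.n == 5
    assert table.to_frame().loc["Gastr", "warfarin"] == 1
    np.testing.assert_array_equal(table.col_totals, [2, 3])
    # single-column table: the drug margin is the grand total
    solo = build_table(frame[frame["drug"] == "warfarin"],
                       drugs=("warfarin",), socs=("Gastr", "Inv"))
    assert solo.col_totals[0] == solo.n == 2


def test_build_table_rejects_empty_and_foreign_labels(tiny_line_list):
    with pytest.raises(ValueError):
        build_table(tiny_line_list.iloc[0:0])
    with pytest.raises(ValueError):
        build_table(tiny_line_list, drugs=("warfarin",))  # rivaroxaban missing


def test_build_table_margins_match_brute_force(default_line_list):
    _, records, _ = default_line_list
    table = build_table(records, socs=soc_codes(include_social=True))
    by_drug = records.groupby("drug").size()
    for j, drug in enumerate(table.drugs):
        assert table.col_totals[j] == by_drug.get(drug, 0)
    by_soc = records.groupby("soc").size()
    for i, soc in enumerate(table.socs):
        assert table.row_totals[i] == by_soc.get(soc, 0)


def test_residuals_vanish_under_independence():
    table = ContingencyTable(("A", "B"), ("x", "y"), np.array([[2, 4], [3, 6]]))
    res = indexed_residuals(table)
    np.testing.assert_allclose(res.residual_pct, 0.0, atol=1e-12)


def test_residuals_zero_cell_is_exactly_minus_100():
    table = ContingencyTable(("A", "B", "C"), ("x", "y"),
                             np.array([[0, 5], [3, 6], [2, 1]]))
    res = indexed_residuals(table)
    assert res.residual_pct[0, 0] == -100.0  # exact, not approximate
    assert (res.residual_pct >= -100.0).all()
    assert ((res.residual_pct == -100.0) == (res.observed == 0)).all()


def test_residuals_hand_computed_example():
    # E = R*C/n cell by cell: row sums (40, 60), col sums (30, 70), n = 100
    table = ContingencyTable(("A", "B"), ("x", "y"), np.array([[10, 30], [20, 40]]))
    res = indexed_residuals(table)
    expected = np.array([[40 * 30, 40 * 70], [60 * 30, 60 * 70]]) / 100
    np.testing.assert_allclose(res.expected, expected)
    assert res.expected[0, 0] == 12.0
    assert round_half_up(res.residual_pct[0, 0], 1) == -16.7
    np.testing.assert_allclose(res.expected.sum(axis=0), table.col_totals)


def test_residual_conservation_and_row_consistency(rng):
    for _ in range(25):
        counts = rng.integers(0, 30, size=(7, 4))
        counts[0] += 1  # avoid empty table
        table = ContingencyTable(tuple(f"S{i}" for i in range(7)),
                                 tuple(f"d{j}" for j in range(4)), counts)
        try:
            res = indexed_residuals(table)
        except ValueError:
            continue
        n = res.observed.sum()
        assert res.expected.sum() == pytest.approx(n, rel=1e-9)
        # sum_i (C_j/n) R_i (1 + r_ij/100) == C_j for every drug j
        R = res.observed.sum(axis=1)
        C = res.observed.sum(axis=0)
        lhs = ((C / n) * R[:, None] * (1 + res.residual_pct / 100)).sum(axis=0)
        np.testing.assert_allclose(lhs, C, rtol=1e-9)


def test_residuals_drop_zero_margins_then_error_if_empty():
    table = ContingencyTable(("A", "B"), ("x", "y"), np.array([[0, 0], [3, 6]]))
    res = indexed_residuals(table)  # zero row dropped, one row remains
    assert res.socs == ("B",)
    with pytest.raises(ValueError):
        indexed_residuals(ContingencyTable(("A",), ("x",), np.array([[0]])))


def test_summarize_icsr_unit_collapses_cases(tiny_line_list):
    table = summarize(tiny_line_list, "sex", unit="icsr")
    # C1 has two reactions but counts once
    assert table.counts.loc["F", "warfarin"] == 1
    assert table.counts["Total"].sum() == tiny_line_list["icsr_id"].nunique()
    outcome = summarize(tiny_line_list, "outcome", unit="icsr")
    # C1's worst outcome is fatal
    assert outcome.counts.loc["fatal", "warfarin"] == 1


def test_summarize_adr_totals_match_contingency(default_line_list):
    _, records, _ = default_line_list
    table = summarize(records, "seriousness", unit="adr")
    counts = build_table(records, socs=soc_codes(include_social=True))
    for j, drug in enumerate(counts.drugs):
        assert table.counts[drug].sum() == counts.col_totals[j]


def test_summarize_recovers_planted_seriousness_rate():
    # Bernoulli(0.9) at n=10,000 per drug: the share is within 1% of 90%
    config = synthetic.default_config(seed=5)
    config = synthetic.scaled_config(
        config,
        drugs={"warfarin": 10_000, "rivaroxaban": 10_000},
        seriousness_prob={d: 0.9 for d in config.drugs},
    )
    records, _ = synthetic.generate(config)
    table = summarize(records, "seriousness", unit="adr")
    for drug in ("warfarin", "rivaroxaban"):
        share = table.counts.loc["serious", drug] / table.counts[drug].sum()
        assert abs(share - 0.9) < 0.01
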