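"""Reporting odds ratios (ROR) with Woolf confidence intervals.

For a drug–event pair, the 2×2 report-count table contrasts the target event
under the target drug (a), other events under the target drug (b), the target
event under all other drugs (c), and other events under other drugs (d):

    ROR = (a/b) / (c/d)
    CI  = exp( ln ROR ± z_{1-alpha/2} * sqrt(1/a + 1/b + 1/c + 1/d) )

Zero cells get the Haldane–Anscombe continuity correction (+0.5 on every
cell), flagged in the result. The comparator is always "all other drugs in
the analysis set", so profiles are within-dataset contrasts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .contingency import ContingencyTable


@dataclass(frozen=True)
class TwoByTwo:
    """Report counts: (a, b) target drug, (c, d) comparator; (a, c) target event."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("2x2 cells must be non-negative")


@dataclass(frozen=True)
class RORResult:
    ror: float
    ci_low: float
    ci_high: float
    corrected: bool
    alpha: float = 0.05


def ror(cell: TwoByTwo, alpha: float = 0.05) -> RORResult:
    """Cross-product ROR with a Woolf (log-normal) confidence interval."""
    a, b, c, d = cell.a, cell.b, cell.c, cell.d
    if a + b == 0 or c + d == 0:
        raise ValueError("a margin of the 2x2 table is zero")
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    estimate = (a / b) / (c / d)
    z = stats.norm.ppf(1 - alpha / 2)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(estimate)
    return RORResult(
        ror=estimate,
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        corrected=corrected,
        alpha=alpha,
    )


def ror_profile(
    table: ContingencyTable,
    drug: str,
    alpha: float = 0.05,
    sort: bool = False,
) -> pd.DataFrame:
    """ROR of every SOC for one drug against all other drugs pooled.

    Returns a frame with columns soc, a, b, c, d, ror, ci_low, ci_high,
    corrected (one row per SOC), optionally sorted by descending ROR.
    """
    if drug not in table.drugs:
        raise ValueError(f"drug {drug!r} not in table")
    j = table.drugs.index(drug)
    col_total = int(table.col_totals[j])
    n = table.n
    rows = []
    for i, soc in enumerate(table.socs):
        a = int(table.counts[i, j])
        b = col_total - a
        c = int(table.row_totals[i]) - a
        d = n - int(table.row_totals[i]) - col_total + a
        res = ror(TwoByTwo(a, b, c, d), alpha=alpha)
        rows.append(
            dict(soc=soc, a=a, b=b, c=c, d=d, ror=res.ror,
                 ci_low=res.ci_low, ci_high=res.ci_high, corrected=res.corrected)
        )
    frame = pd.DataFrame(rows)
    if sort:
        frame = frame.sort_values("ror", ascending=False, ignore_index=True)
    return frame


def outcome_or(
    records: pd.DataFrame,
    drug: str,
    predicate: str,
    alpha: float = 0.05,
    not_specified_serious: bool = False,
) -> RORResult:
    """Drug-level odds ratio of a serious or fatal reaction vs all other drugs.

    ``predicate`` is ``"serious"`` or ``"fatal"``. Reactions with seriousness
    "not specified" count as non-serious unless ``not_specified_serious``.
    """
    if predicate == "serious":
        positive = records["seriousness"] == "serious"
        if not_specified_serious:
            positive |= records["seriousness"] == "not_specified"
    elif predicate == "fatal":
        positive = records["outcome"] == "fatal"
    else:
        raise ValueError("predicate must be 'serious' or 'fatal'")
    if drug not in set(records["drug"]):
        raise ValueError(f"drug {drug!r} not present")
    target = records["drug"] == drug
    cell = TwoByTwo(
        a=int((target & positive).sum()),
        b=int((target & ~positive).sum()),
        c=int((~target & positive).sum()),
        d=int((~target & ~positive).sum()),
    )
    return ror(cell, alpha=alpha)


def outcome_or_from_counts(
    positive: pd.Series, totals: pd.Series, drug: str, alpha: float = 0.05
) -> RORResult:
    """Same contrast computed from per-drug aggregated counts.

    ``positive``: predicate-positive reactions per drug; ``totals``: all
    reactions per drug. Used with published aggregate tables.
    """
    a = float(positive[drug])
    b = float(totals[drug]) - a
    c = float(positive.drop(drug).sum())
    d = float(totals.drop(drug).sum()) - c
    return ror(TwoByTwo(a, b, c, d), alpha=alpha)
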