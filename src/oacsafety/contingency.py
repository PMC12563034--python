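"""Drug × SOC contingency tables, margin-product expectations and indexed residuals.

The indexed residual of a cell is its relative deviation from the
independence expectation, expressed as a signed percentage:

    E_ij = R_i * C_j / n
    r_ij = 100 * (O_ij - E_ij) / E_ij

so a cell observed exactly never (O = 0) with positive margins prints
-100.0%, and a table satisfying row/column independence prints 0.0%
everywhere. SOCs are rows, drugs are columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .vocab import DEFAULT_DRUGS, soc_codes

log = logging.getLogger(__name__)


def round_half_up(values, decimals: int = 1):
    """Round half away from zero (printed tables use this, not banker's)."""
    arr = np.asarray(values, dtype=float)
    factor = 10.0**decimals
    out = np.sign(arr) * np.floor(np.abs(arr) * factor + 0.5) / factor
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ContingencyTable:
    """Observed counts O[soc, drug] with margins and grand total."""

    socs: tuple[str, ...]
    drugs: tuple[str, ...]
    counts: np.ndarray  # shape (len(socs), len(drugs)), non-negative ints

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.socs), len(self.drugs)):
            raise ValueError("counts shape does not match soc/drug labels")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(np.int64))
        object.__setattr__(self, "socs", tuple(self.socs))
        object.__setattr__(self, "drugs", tuple(self.drugs))

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.socs), columns=list(self.drugs))

    def drop_zero_margins(self) -> "ContingencyTable":
        """Return a table without all-zero rows/columns (logged if any)."""
        rows = self.row_totals > 0
        cols = self.col_totals > 0
        if not rows.all():
            log.warning("dropping zero-margin SOC rows: %s",
                        [s for s, k in zip(self.socs, rows) if not k])
        if not cols.all():
            log.warning("dropping zero-margin drug columns: %s",
                        [d for d, k in zip(self.drugs, cols) if not k])
        return ContingencyTable(
            tuple(s for s, k in zip(self.socs, rows) if k),
            tuple(d for d, k in zip(self.drugs, cols) if k),
            self.counts[np.ix_(rows, cols)],
        )

    def restrict(self, socs=None, drugs=None) -> "ContingencyTable":
        """Sub-table on the given SOC/drug labels (order preserved)."""
        socs = tuple(socs) if socs is not None else self.socs
        drugs = tuple(drugs) if drugs is not None else self.drugs
        ri = [self.socs.index(s) for s in socs]
        ci = [self.drugs.index(d) for d in drugs]
        return ContingencyTable(socs, drugs, self.counts[np.ix_(ri, ci)])


def build_table(records: pd.DataFrame, drugs=None, socs=None) -> ContingencyTable:
    """Tally a line-list frame into a SOC × drug contingency table.

    Every record's drug and SOC must belong to the supplied label sets;
    labels with zero records keep their (all-zero) row/column.
    """
    if len(records) == 0:
        raise ValueError("cannot build a contingency table from zero records")
    drugs = tuple(drugs) if drugs is not None else DEFAULT_DRUGS
    socs = tuple(socs) if socs is not None else soc_codes()
    bad = sorted(set(records["drug"]) - set(drugs))
    if bad:
        raise ValueError(f"records contain drugs outside the analysis set: {bad}")
    bad = sorted(set(records["soc"]) - set(socs))
    if bad:
        raise ValueError(f"records contain SOCs outside the analysis set: {bad}")
    soc_idx = pd.Categorical(records["soc"], categories=socs)
    drug_idx = pd.Categorical(records["drug"], categories=drugs)
    counts = pd.crosstab(soc_idx, drug_idx, dropna=False).reindex(
        index=socs, columns=drugs, fill_value=0
    )
    return ContingencyTable(socs, drugs, counts.to_numpy())


@dataclass(frozen=True)
class ResidualMatrix:
    """Expected counts and indexed residuals for a contingency table."""

    socs: tuple[str, ...]
    drugs: tuple[str, ...]
    observed: np.ndarray
    expected: np.ndarray
    residual_pct: np.ndarray  # signed percentage, exact -100.0 at O == 0

    def to_frame(self, rounded: bool = True) -> pd.DataFrame:
        values = round_half_up(self.residual_pct, 1) if rounded else self.residual_pct
        return pd.DataFrame(values, index=list(self.socs), columns=list(self.drugs))


def indexed_residuals(table: ContingencyTable) -> ResidualMatrix:
    """Margin-product expectations and indexed residuals per drug–SOC cell.

    Rows/columns with a zero margin are dropped (with a warning) first; an
    empty table afterwards is an error.
    """
    table = table.drop_zero_margins()
    if table.n == 0 or len(table.socs) == 0 or len(table.drugs) == 0:
        raise ValueError("no cells with positive margins")
    observed = table.counts.astype(float)
    expected = np.outer(table.row_totals, table.col_totals) / table.n
    residual = 100.0 * (observed - expected) / expected
    return ResidualMatrix(table.socs, table.drugs, observed, expected, residual)


# --- descriptive summaries (per-drug counts and percentages) -----------------

_AXIS_COLUMN = {
    "sex": "sex",
    "age": "age_band",
    "seriousness": "seriousness",
    "outcome": "outcome",
    "country": "country",
}

#: Precedence used to collapse reaction-level attributes to case level: a case
#: is summarised by its worst reaction (fatal > not recovered > ...).
_OUTCOME_PRECEDENCE = (
    "fatal",
    "not_recovered",
    "recovered_with_sequelae",
    "recovering",
    "recovered",
    "unknown",
    "not_specified",
)
_SERIOUSNESS_PRECEDENCE = ("serious", "non_serious", "not_specified")


@dataclass(frozen=True)
class SummaryTable:
    """Per-drug counts and one-decimal percentages for one categorical axis.

    Percentages use each drug's own total as denominator; the ``Total``
    column pools all drugs.
    """

    axis: str
    unit: str
    counts: pd.DataFrame      # levels × (drugs + Total)
    percentages: pd.DataFrame  # same shape, rounded half-up to 1 decimal


def _collapse_to_cases(records: pd.DataFrame) -> pd.DataFrame:
    frame = records.copy()
    frame["seriousness"] = pd.Categorical(
        frame["seriousness"], categories=_SERIOUSNESS_PRECEDENCE, ordered=True
    )
    frame["outcome"] = pd.Categorical(
        frame["outcome"], categories=_OUTCOME_PRECEDENCE, ordered=True
    )
    grouped = frame.groupby(["icsr_id", "drug"], sort=False, observed=True)
    cases = grouped.agg(
        seriousness=("seriousness", "min"),
        outcome=("outcome", "min"),
        age_band=("age_band", "first"),
        sex=("sex", "first"),
        country=("country", "first"),
    ).reset_index()
    cases["seriousness"] = cases["seriousness"].astype(str)
    cases["outcome"] = cases["outcome"].astype(str)
    return cases


def summarize(
    records: pd.DataFrame,
    axis: str,
    unit: str = "adr",
    drugs=None,
) -> SummaryTable:
    """Per-drug breakdown of one categorical axis, at reaction or case level.

    ``unit="icsr"`` collapses to one row per case first, using the case's
    demographics and worst seriousness/outcome.
    """
    if axis not in _AXIS_COLUMN:
        raise ValueError(f"axis must be one of {sorted(_AXIS_COLUMN)}")
    if unit not in ("adr", "icsr"):
        raise ValueError("unit must be 'adr' or 'icsr'")
    frame = _collapse_to_cases(records) if unit == "icsr" else records
    drugs = list(drugs) if drugs is not None else [
        d for d in DEFAULT_DRUGS if d in set(frame["drug"])
    ]
    column = _AXIS_COLUMN[axis]
    counts = pd.crosstab(frame[column], frame["drug"]).reindex(columns=drugs, fill_value=0)
    counts["Total"] = counts.sum(axis=1)
    return _finish_summary(axis, unit, counts)


def summary_from_counts(tidy: pd.DataFrame, axis: str, drugs=None) -> SummaryTable:
    """Summary table from pre-aggregated counts (columns axis, level, drug, count).

    The tidy frame must contain a ``total`` axis giving each drug's
    denominator; this is how published aggregate views (counts per category
    with per-drug totals) are summarised without a line list.
    """
    totals = tidy[tidy["axis"] == "total"].set_index("drug")["count"]
    sub = tidy[tidy["axis"] == axis]
    if sub.empty:
        raise ValueError(f"axis {axis!r} not present in the aggregated counts")
    drugs = list(drugs) if drugs is not None else [
        d for d in DEFAULT_DRUGS if d in set(tidy["drug"])
    ]
    counts = sub.pivot(index="level", columns="drug", values="count").reindex(
        columns=drugs, fill_value=0
    )
    counts["Total"] = counts.sum(axis=1)
    unit = str(tidy.loc[tidy["axis"] == "total", "level"].iloc[0])
    denominators = totals.reindex(drugs)
    denominators["Total"] = denominators.sum()
    return _finish_summary(axis, unit, counts, denominators)


def _finish_summary(axis, unit, counts, denominators=None) -> SummaryTable:
    if denominators is None:
        denominators = counts.sum(axis=0)
    pct = counts.div(denominators, axis=1).mul(100.0)
    pct = pct.apply(lambda col: round_half_up(col.to_numpy(), 1))
    return SummaryTable(axis=axis, unit=unit, counts=counts, percentages=pct)
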