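"""Packaged aggregate fixtures from the public EudraVigilance dashboard.

Two tidy count tables (columns ``axis, level, drug, count``) reproduce the
published oral-anticoagulant aggregates up to March 2019: case-level
population characteristics (sex and age per drug) and reaction-level
seriousness/outcome breakdowns. They serve as the reproduction surface for
the descriptive-summary stage and as inputs to drug-level odds ratios.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .contingency import SummaryTable, summary_from_counts


def _load(name: str) -> pd.DataFrame:
    path = resources.files("oacsafety.data").joinpath(name)
    with path.open("r", encoding="utf-8") as fh:
        frame = pd.read_csv(fh)
    frame["count"] = frame["count"].astype(int)
    return frame


def icsr_population_fixture() -> pd.DataFrame:
    """Per-drug case (ICSR) totals plus sex and age-band counts."""
    return _load("ev_icsr_population.csv")


def adr_outcomes_fixture() -> pd.DataFrame:
    """Per-drug reaction (ADR) totals plus seriousness and outcome counts."""
    return _load("ev_adr_outcomes.csv")


def fixture_totals() -> dict[str, int]:
    """Grand totals of the packaged fixtures (cases and reactions)."""
    icsr = icsr_population_fixture()
    adr = adr_outcomes_fixture()
    return {
        "icsrs": int(icsr.loc[icsr["axis"] == "total", "count"].sum()),
        "adrs": int(adr.loc[adr["axis"] == "total", "count"].sum()),
    }


def fixture_summary(axis: str) -> SummaryTable:
    """Summary table (counts + one-decimal percentages) for a fixture axis.

    ``axis`` in {"sex", "age"} uses the case-level fixture; {"seriousness",
    "outcome"} the reaction-level one.
    """
    if axis in ("sex", "age"):
        return summary_from_counts(icsr_population_fixture(), axis)
    if axis in ("seriousness", "outcome"):
        return summary_from_counts(adr_outcomes_fixture(), axis)
    raise ValueError(f"no fixture axis {axis!r}")


def drug_share(unit: str = "icsr") -> pd.Series:
    """Each drug's share (%) of all cases or reactions, one decimal."""
    from .contingency import round_half_up

    frame = icsr_population_fixture() if unit == "icsr" else adr_outcomes_fixture()
    totals = frame[frame["axis"] == "total"].set_index("drug")["count"]
    return pd.Series(
        round_half_up((100.0 * totals / totals.sum()).to_numpy(), 1),
        index=totals.index, name="share_pct",
    )
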