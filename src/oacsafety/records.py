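"""ICSR line-list data model, readers/writers and exclusion filters.

The canonical in-memory container for a line list is a :class:`pandas.DataFrame`
with one row per suspected adverse reaction (ADR) and the columns in
:data:`COLUMNS`. One individual case safety report (ICSR) may own several
reactions; rows of one case share an ``icsr_id``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .vocab import (
    AGE_BANDS,
    DEFAULT_DRUGS,
    OUTCOME_LEVELS,
    SERIOUSNESS_LEVELS,
    SEX_LEVELS,
    SOCIAL_CIRCUMSTANCES,
    soc_codes,
)

log = logging.getLogger(__name__)

#: Canonical line-list columns, in CSV order.
COLUMNS = (
    "icsr_id",
    "drug",
    "soc",
    "seriousness",
    "outcome",
    "age_band",
    "sex",
    "country",
)

_ENUM_COLUMNS = {
    "seriousness": SERIOUSNESS_LEVELS,
    "outcome": OUTCOME_LEVELS,
    "age_band": AGE_BANDS,
    "sex": SEX_LEVELS,
}


class SchemaError(ValueError):
    """A mandatory line-list column is missing or unresolvable."""


class ValidationError(ValueError):
    """Row values violate the controlled vocabularies."""


@dataclass(frozen=True)
class ADRRecord:
    """One suspected adverse reaction within an ICSR."""

    icsr_id: str
    drug: str
    soc: str
    seriousness: str = "not_specified"
    outcome: str = "not_specified"
    age_band: str = "not_specified"
    sex: str = "not_specified"
    country: str = ""


@dataclass(frozen=True)
class FilterSpec:
    """Exclusion sets applied before analysis.

    ``excluded_socs_overall`` is dropped from every analysis (social
    circumstances are not adverse reactions). ``excluded_socs_fatal``
    additionally drops, from the fatal-only analyses, fatal reports in SOCs
    where a fatal outcome is implausible or explained by other conditions
    (ear/eye disorders, investigations, surgical procedures, product issues).
    """

    excluded_socs_overall: frozenset[str] = frozenset({SOCIAL_CIRCUMSTANCES})
    excluded_socs_fatal: frozenset[str] = frozenset(
        {"Ear", "Eye", "Inv", "Surg", "Product"}
    )

    def __post_init__(self) -> None:
        known = set(soc_codes(include_social=True))
        for name in ("excluded_socs_overall", "excluded_socs_fatal"):
            bad = set(getattr(self, name)) - known
            if bad:
                raise ValidationError(f"{name} contains unknown SOC codes: {sorted(bad)}")
            object.__setattr__(self, name, frozenset(getattr(self, name)))


def records_to_frame(records) -> pd.DataFrame:
    """Build a line-list frame from an iterable of :class:`ADRRecord`."""
    return pd.DataFrame([vars(r) for r in records], columns=list(COLUMNS))


def frame_to_records(frame: pd.DataFrame) -> list[ADRRecord]:
    return [ADRRecord(**row) for row in frame[list(COLUMNS)].to_dict("records")]


def read_line_list(
    path,
    schema: dict[str, str] | None = None,
    drugs=DEFAULT_DRUGS,
) -> pd.DataFrame:
    """Read an ICSR line list CSV into the canonical frame.

    Parameters
    ----------
    path
        CSV file with a header row.
    schema
        Optional map from canonical column name to the file's column name,
        for files using different headers.
    drugs
        Allowed drug identifiers; rows with other drugs are rejected
        (the drug set defines the analysis columns).

    Unknown values in the closed categorical columns (seriousness, outcome,
    age band, sex) are coerced to ``not_specified`` with a warning; unknown
    SOC codes or drugs raise :class:`ValidationError`.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    schema = schema or {}
    rename = {schema.get(col, col): col for col in COLUMNS}
    missing = [schema.get(col, col) for col in COLUMNS if schema.get(col, col) not in raw.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    frame = raw.rename(columns=rename)[list(COLUMNS)].copy()

    if (frame["icsr_id"] == "").any():
        raise ValidationError("icsr_id must be non-empty")

    bad_drugs = sorted(set(frame["drug"]) - set(drugs))
    if bad_drugs:
        raise ValidationError(f"unknown drug name(s): {bad_drugs}")
    known_socs = set(soc_codes(include_social=True))
    bad_socs = sorted(set(frame["soc"]) - known_socs)
    if bad_socs:
        raise ValidationError(f"unknown SOC code(s): {bad_socs}")

    for col, levels in _ENUM_COLUMNS.items():
        unknown = ~frame[col].isin(levels)
        if unknown.any():
            values = sorted(set(frame.loc[unknown, col]))
            log.warning(
                "%d value(s) in %r outside the vocabulary %s mapped to not_specified",
                int(unknown.sum()), col, values,
            )
            frame.loc[unknown, col] = "not_specified"
    return frame


def write_line_list(frame: pd.DataFrame, path) -> None:
    """Write the canonical columns as CSV (UTF-8, header row)."""
    frame[list(COLUMNS)].to_csv(path, index=False)


def apply_filters(
    frame: pd.DataFrame,
    spec: FilterSpec | None = None,
    fatal_only: bool = False,
) -> pd.DataFrame:
    """Apply the analysis exclusion filters, preserving row order.

    With ``fatal_only=False``, rows in the overall exclusion SOCs are removed.
    With ``fatal_only=True``, only fatal-outcome rows are kept and both
    exclusion sets apply.
    """
    spec = spec or FilterSpec()
    excluded = set(spec.excluded_socs_overall)
    mask = ~frame["soc"].isin(excluded)
    if fatal_only:
        excluded |= set(spec.excluded_socs_fatal)
        mask = (frame["outcome"] == "fatal") & ~frame["soc"].isin(excluded)
    kept = frame[mask]
    log.info(
        "filter (fatal_only=%s): kept %d of %d reactions", fatal_only, len(kept), len(frame)
    )
    return kept
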