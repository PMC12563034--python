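"""Controlled vocabularies: MedDRA system organ classes, drugs, categorical levels.

Reaction terms are handled at the system-organ-class (SOC) level only — the top
tier of the MedDRA hierarchy, 26 classes after excluding social circumstances.
Each SOC carries a short code (e.g. ``Gastr``) used throughout tables and plots
and a full MedDRA name.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from functools import lru_cache


@dataclass(frozen=True)
class SOCCategory:
    """A MedDRA system organ class: short code + full name."""

    code: str
    name: str


#: Drugs in the analysis set. The first two are vitamin K antagonists (VKAs),
#: the rest direct ("novel") oral anticoagulants (NOACs).
DEFAULT_DRUGS = (
    "warfarin",
    "acenocumarol",
    "dabigatran",
    "rivaroxaban",
    "apixaban",
    "edoxaban",
)
VKA_DRUGS = ("warfarin", "acenocumarol")
NOAC_DRUGS = ("dabigatran", "rivaroxaban", "apixaban", "edoxaban")

#: SOC code for social circumstances — recorded in reports but excluded from
#: every analysis (conditions such as 'elderly' or 'economic problem' are not
#: adverse reactions).
SOCIAL_CIRCUMSTANCES = "Soc"

SERIOUSNESS_LEVELS = ("serious", "non_serious", "not_specified")
OUTCOME_LEVELS = (
    "fatal",
    "not_recovered",
    "not_specified",
    "recovered",
    "recovered_with_sequelae",
    "recovering",
    "unknown",
)
AGE_BANDS = ("under_18", "18_64", "65_85", "over_85", "not_specified")
SEX_LEVELS = ("F", "M", "not_specified")


@lru_cache(maxsize=1)
def load_soc_vocabulary() -> tuple[SOCCategory, ...]:
    """Load the packaged SOC vocabulary (27 entries: 26 analysis SOCs + Soc).

    The code→name mapping is validated to be bijective.
    """
    path = resources.files("oacsafety.data").joinpath("soc_vocabulary.csv")
    with path.open("r", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    socs = tuple(SOCCategory(r["code"], r["name"]) for r in rows)
    codes = [s.code for s in socs]
    names = [s.name for s in socs]
    if len(set(codes)) != len(codes) or len(set(names)) != len(names):
        raise ValueError("SOC vocabulary is not bijective")
    return socs


def soc_codes(include_social: bool = False) -> tuple[str, ...]:
    """Ordered SOC codes; the 26 analysis classes, optionally plus ``Soc``."""
    codes = tuple(
        s.code for s in load_soc_vocabulary() if s.code != SOCIAL_CIRCUMSTANCES
    )
    if include_social:
        codes = codes + (SOCIAL_CIRCUMSTANCES,)
    return codes


def soc_name(code: str) -> str:
    for s in load_soc_vocabulary():
        if s.code == code:
            return s.name
    raise KeyError(f"unknown SOC code: {code!r}")
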