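"""Descriptive summary tables from the packaged EudraVigilance aggregates.

Reproduces the per-drug population and seriousness/outcome breakdowns
(counts with one-decimal percentages) and prints the headline shares.
"""

from pathlib import Path

import pandas as pd

from oacsafety.fixtures import drug_share, fixture_summary, fixture_totals

OUT = Path("results/descriptives")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    totals = fixture_totals()
    print(f"{totals['icsrs']:,} cases, {totals['adrs']:,} reactions")
    print("case share by drug (%):")
    print(drug_share("icsr").to_string())

    for axis in ("sex", "age", "seriousness", "outcome"):
        table = fixture_summary(axis)
        merged = pd.concat({"count": table.counts, "pct": table.percentages}, axis=1)
        merged.to_csv(OUT / f"summary_{axis}.csv")

    seriousness = fixture_summary("seriousness").percentages
    outcome = fixture_summary("outcome").percentages
    print(f"serious reactions: rivaroxaban {seriousness.loc['serious', 'rivaroxaban']}%"
          f" (highest), edoxaban {seriousness.loc['serious', 'edoxaban']}% (lowest)")
    print(f"fatal reactions: overall {outcome.loc['fatal', 'Total']}%,"
          f" dabigatran {outcome.loc['fatal', 'dabigatran']}% (highest)")


if __name__ == "__main__":
    main()
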