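"""Reporting odds ratios: per-SOC profiles on the synthetic extract, plus
drug-level serious/fatal odds ratios from the published aggregates."""

from pathlib import Path

import pandas as pd

from oacsafety import apply_filters, build_table
from oacsafety.disproportionality import outcome_or_from_counts, ror_profile
from oacsafety.fixtures import adr_outcomes_fixture
from oacsafety.records import read_line_list
from oacsafety.vocab import DEFAULT_DRUGS, soc_codes

LINE_LIST = Path("results/synthetic/line_list.csv")
OUT = Path("results/ror")


def load_records():
    if LINE_LIST.exists():
        return read_line_list(LINE_LIST)
    from oacsafety import synthetic

    return synthetic.generate(synthetic.default_config(seed=0))[0]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    records = load_records()
    table = build_table(apply_filters(records), socs=soc_codes()).drop_zero_margins()
    frames = []
    for drug in table.drugs:
        frame = ror_profile(table, drug, sort=True)
        frame.insert(0, "drug", drug)
        frames.append(frame)
        top = frame.iloc[0]
        print(f"{drug}: top signal {top['soc']} "
              f"ROR {top['ror']:.2f} ({top['ci_low']:.2f}-{top['ci_high']:.2f})")
    pd.concat(frames, ignore_index=True).to_csv(OUT / "ror_profiles.csv", index=False)

    fixture = adr_outcomes_fixture()
    totals = fixture[fixture["axis"] == "total"].set_index("drug")["count"]
    serious = fixture[(fixture["axis"] == "seriousness") & (fixture["level"] == "serious")
                      ].set_index("drug")["count"]
    fatal = fixture[(fixture["axis"] == "outcome") & (fixture["level"] == "fatal")
                    ].set_index("drug")["count"]
    rows = []
    for drug in DEFAULT_DRUGS:
        for label, counts in (("serious", serious), ("fatal", fatal)):
            res = outcome_or_from_counts(counts, totals, drug)
            rows.append(dict(drug=drug, predicate=label, ror=res.ror,
                             ci_low=res.ci_low, ci_high=res.ci_high))
    aggregate = pd.DataFrame(rows)
    aggregate.to_csv(OUT / "aggregate_outcome_or.csv", index=False)
    print("\ndrug-level ORs from the published aggregates:")
    print(aggregate.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
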