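"""Indexed residuals (% deviation from margin-product expectation) per drug-SOC pair.

Runs the overall and fatal-only passes on the synthetic extract and reports
the largest positive deviations per drug.
"""

from pathlib import Path

from oacsafety import apply_filters, build_table, indexed_residuals
from oacsafety.records import read_line_list
from oacsafety.vocab import soc_codes

LINE_LIST = Path("results/synthetic/line_list.csv")
OUT = Path("results/residuals")


def load_records():
    if LINE_LIST.exists():
        return read_line_list(LINE_LIST)
    from oacsafety import synthetic

    return synthetic.generate(synthetic.default_config(seed=0))[0]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    records = load_records()
    for fatal_only, name in ((False, "overall"), (True, "fatal")):
        kept = apply_filters(records, fatal_only=fatal_only)
        table = build_table(kept, socs=soc_codes())
        frame = indexed_residuals(table).to_frame()
        frame.to_csv(OUT / f"residuals_{name}.csv")
        print(f"[{name}] top positive deviations:")
        for drug in frame.columns:
            soc = frame[drug].idxmax()
            print(f"  {drug}: {soc} {frame.loc[soc, drug]:+.1f}%")


if __name__ == "__main__":
    main()
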