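"""Generate the default synthetic ICSR extract used by the downstream analyses.

Two planted archetypes (VKA-like: investigations/pregnancy-heavy reporting;
NOAC-like: gastrointestinal/nervous-system-heavy) over six oral
anticoagulants at the published scale divided by 100.
"""

import json
from pathlib import Path

from oacsafety import synthetic
from oacsafety.records import write_line_list

OUT = Path("results/synthetic")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = synthetic.default_config(seed=0)
    records, truth = synthetic.generate(config)
    write_line_list(records, OUT / "line_list.csv")
    (OUT / "ground_truth.json").write_text(
        json.dumps(
            {
                "assignment": truth.assignment,
                "realized_seriousness": truth.realized_seriousness,
                "realized_fatal": truth.realized_fatal,
            },
            indent=2,
        )
    )
    print(f"wrote {len(records)} reactions in {records['icsr_id'].nunique()} cases")
    print("per-drug volumes:", dict(config.drugs))


if __name__ == "__main__":
    main()
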