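"""Correspondence analysis with contribution biplots: overall, fatal-only and
the investigations-excluded sensitivity refit."""

from pathlib import Path

from oacsafety import apply_filters, build_table, fit_ca, select_variables
from oacsafety.ca import coordinates_frame, inertia_frame, profile_distance_ranking
from oacsafety.records import read_line_list
from oacsafety.vocab import soc_codes

LINE_LIST = Path("results/synthetic/line_list.csv")
OUT = Path("results/ca")


def load_records():
    if LINE_LIST.exists():
        return read_line_list(LINE_LIST)
    from oacsafety import synthetic

    return synthetic.generate(synthetic.default_config(seed=0))[0]


def analyse(table, name: str) -> None:
    result = fit_ca(table)
    coordinates_frame(result).to_csv(OUT / f"{name}_coordinates.csv", index=False)
    inertia_frame(result).to_csv(OUT / f"{name}_inertia.csv", index=False)
    ranking = profile_distance_ranking(result)
    ranking.to_csv(OUT / f"{name}_drug_distances.csv", index=False)
    selection = select_variables(result)
    share = 100 * result.inertia_share[: result.retained_dims].sum()
    print(f"[{name}] {result.retained_dims} dims retained, {share:.1f}% of inertia; "
          f"top contributors: {', '.join(selection.top)}")
    closest = ranking.iloc[0]
    print(f"  closest profiles: {closest['drug_a']} ~ {closest['drug_b']} "
          f"(distance {closest['distance']:.3f})")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    records = load_records()
    overall = build_table(apply_filters(records), socs=soc_codes()).drop_zero_margins()
    analyse(overall, "overall")
    analyse(overall.restrict(socs=[s for s in overall.socs if s != "Inv"]), "overall_noinv")
    fatal = build_table(
        apply_filters(records, fatal_only=True), socs=soc_codes()
    ).drop_zero_margins()
    analyse(fatal, "fatal")


if __name__ == "__main__":
    main()
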