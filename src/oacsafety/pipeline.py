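"""End-to-end orchestration: read → filter → summarize → residuals → ROR → CA.

``run`` executes the two analysis passes (overall reactions and fatal-only
reactions, each with its own exclusion set) and writes every artifact as CSV
under an output directory, returning a manifest of content hashes so that
identical inputs and config provably yield identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import ca as ca_mod
from .contingency import build_table, indexed_residuals, summarize
from .disproportionality import ror_profile
from .records import FilterSpec, apply_filters, read_line_list
from .vocab import DEFAULT_DRUGS, soc_codes

log = logging.getLogger(__name__)

SUMMARY_AXES = ("sex", "age", "seriousness", "outcome")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    input_path: str | Path | None = None
    output_dir: str | Path = "results"
    unit: str = "adr"
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    overall: bool = True
    fatal: bool = True
    exclude_inv: bool = False   # sensitivity re-analysis without 'Inv'
    drugs: tuple[str, ...] = DEFAULT_DRUGS
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.unit not in ("adr", "icsr"):
            raise ValueError("unit must be 'adr' or 'icsr'")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(frame: pd.DataFrame, path: Path, manifest: dict, index: bool) -> None:
    frame.to_csv(path, index=index)
    manifest[path.name] = _sha256(path)


def _ca_exports(table, prefix: str, outdir: Path, manifest: dict) -> None:
    result = ca_mod.fit_ca(table.drop_zero_margins())
    _write(ca_mod.coordinates_frame(result), outdir / f"{prefix}_coordinates.csv",
           manifest, index=False)
    _write(ca_mod.inertia_frame(result), outdir / f"{prefix}_inertia.csv",
           manifest, index=False)
    _write(ca_mod.profile_distance_ranking(result),
           outdir / f"{prefix}_drug_distances.csv", manifest, index=False)


def run(config: RunConfig, records: pd.DataFrame | None = None) -> dict[str, str]:
    """Execute the pipeline; returns {artifact filename: sha256}.

    ``records`` may be passed directly (e.g. from the synthetic generator);
    otherwise ``config.input_path`` is read. Summaries are computed before
    the exclusion filters (so their totals match the raw extract); all
    contingency/ROR/CA stages run on filtered reactions.
    """
    logging.basicConfig(level=config.log_level)
    if records is None:
        if config.input_path is None:
            raise ValueError("either records or config.input_path is required")
        records = read_line_list(config.input_path, drugs=config.drugs)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    stage = "summarize"
    try:
        for axis in SUMMARY_AXES:
            table = summarize(records, axis, unit=config.unit, drugs=config.drugs)
            merged = pd.concat(
                {"count": table.counts, "pct": table.percentages}, axis=1
            )
            _write(merged, outdir / f"summary_{axis}.csv", manifest, index=True)

        socs = soc_codes()
        if config.overall:
            stage = "overall analysis"
            kept = apply_filters(records, config.filter_spec, fatal_only=False)
            table = build_table(kept, drugs=config.drugs, socs=socs)
            _write(table.to_frame(), outdir / "contingency_overall.csv",
                   manifest, index=True)
            _write(indexed_residuals(table).to_frame(),
                   outdir / "residuals_overall.csv", manifest, index=True)
            profiles = []
            for drug in config.drugs:
                frame = ror_profile(table.drop_zero_margins(), drug)
                frame.insert(0, "drug", drug)
                profiles.append(frame)
            _write(pd.concat(profiles, ignore_index=True),
                   outdir / "ror_profiles.csv", manifest, index=False)
            _ca_exports(table, "ca_overall", outdir, manifest)
            if config.exclude_inv:
                reduced = table.restrict(socs=[s for s in table.socs if s != "Inv"])
                _ca_exports(reduced, "ca_overall_noinv", outdir, manifest)

        if config.fatal:
            stage = "fatal-only analysis"
            kept = apply_filters(records, config.filter_spec, fatal_only=True)
            if len(kept) == 0:
                log.warning("no fatal reactions after filtering; fatal pass skipped")
            else:
                table = build_table(kept, drugs=config.drugs, socs=socs)
                _write(indexed_residuals(table).to_frame(),
                       outdir / "residuals_fatal.csv", manifest, index=True)
                _ca_exports(table, "ca_fatal", outdir, manifest)
    except Exception as exc:  # annotate with the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("wrote %d artifacts to %s", len(manifest), outdir)
    return manifest
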