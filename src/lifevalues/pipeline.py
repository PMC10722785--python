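"""End-to-end pipeline: adjust → convert → compare → sensitivity, with report
writers. This is the library surface behind the command-line interface."""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .comparison import (ComparisonRow, ConvertedEstimate, build_comparison,
                         counts_summary, write_comparison)
from .conversion import convert
from .price_adjust import adjust, series_for
from .registry import (CountryParams, VoLEstimate, default_params,
                       default_registry, load_params, load_registry,
                       validate_registry)
from .sensitivity import SensitivityGrid, SensitivityResult, run_sensitivity

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "convert_registry"]

log = logging.getLogger("lifevalues")


@dataclass(frozen=True)
class RunConfig:
    registry_path: Optional[Union[str, Path]] = None   # None -> packaged fixture
    params_path: Optional[Union[str, Path]] = None     # None -> packaged config
    out_dir: Optional[Union[str, Path]] = None         # None -> no files written
    strict_conversion: bool = False
    run_sensitivity_scan: bool = True
    grid: SensitivityGrid = field(default_factory=SensitivityGrid)
    log_level: str = "WARNING"
    seed: int = 0                                      # reserved for synthetic stages


@dataclass
class PipelineResult:
    converted: list[ConvertedEstimate]
    comparison_rows: list[ComparisonRow]
    counts: dict[str, int]
    sensitivity: Optional[SensitivityResult]
    validation_findings: int


def convert_registry(
    records: Sequence[VoLEstimate],
    params: Mapping[str, CountryParams],
    strict: bool = False,
) -> list[ConvertedEstimate]:
    """Adjust every record to base-year prices and convert onto all measures."""
    out = []
    for i, r in enumerate(records, start=1):
        try:
            p = params[r.country]
            adjusted = adjust(r.stated, r.stated_year, series_for(p), r.needs_update)
            out.append(ConvertedEstimate(
                r.with_adjusted(adjusted),
                convert(adjusted, r.measure, p, strict=strict),
            ))
        except Exception as exc:
            raise RuntimeError(
                f"conversion stage failed at record {i} ({r.country} row {r.row}): {exc}"
            ) from exc
    return out


def _country_table(converted: Sequence[ConvertedEstimate], country: str) -> pd.DataFrame:
    rows = []
    for ce in converted:
        r, t = ce.record, ce.triple
        if r.country != country:
            continue
        rows.append({
            "row": r.row,
            "sector": r.sector.value,
            "source": r.source,
            "relevance": r.relevance,
            "measure": r.measure.value,
            "stated_lower": r.stated.lower,
            "stated_upper": r.stated.upper,
            "stated_year": r.stated_year,
            "adjusted_lower": r.adjusted.lower,
            "adjusted_upper": r.adjusted.upper,
            "voly_lower": t.voly.lower, "voly_upper": t.voly.upper,
            "vsl_lower": t.vsl.lower, "vsl_upper": t.vsl.upper,
            "voq_lower": t.voq.lower, "voq_upper": t.voq.upper,
        })
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig = RunConfig()) -> PipelineResult:
    """Execute the full pipeline; optionally write the artifact bundle.

    On any stage failure, partially written outputs are removed before the
    error propagates (with the failing stage and record named).
    """
    logging.basicConfig()
    log.setLevel(config.log_level.upper())
    records = (load_registry(config.registry_path) if config.registry_path
               else default_registry())
    params = (load_params(config.params_path) if config.params_path
              else default_params())
    report = validate_registry(records, params)
    if not report.ok:
        log.warning("registry validation: %s", report)
    if not records:
        log.warning("registry is empty; reports will be empty")

    converted = convert_registry(records, params, strict=config.strict_conversion)
    comparison_rows = build_comparison(converted) if any(r.in_comparison_set for r in records) else []
    counts = counts_summary(comparison_rows)
    sens = None
    if config.run_sensitivity_scan and comparison_rows:
        sens = run_sensitivity(records, params, config.grid)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        fresh = not out.exists()
        out.mkdir(parents=True, exist_ok=True)
        try:
            _write_bundle(out, records, params, converted, comparison_rows, counts, sens, config)
        except Exception:
            if fresh:
                shutil.rmtree(out, ignore_errors=True)
            raise
    return PipelineResult(
        converted=converted,
        comparison_rows=comparison_rows,
        counts=counts,
        sensitivity=sens,
        validation_findings=len(report.findings),
    )


def _write_bundle(out, records, params, converted, comparison_rows, counts, sens, config):
    for country in dict.fromkeys(r.country for r in records):
        _country_table(converted, country).to_csv(
            out / f"converted_{country}.csv", index=False)
    if comparison_rows:
        write_comparison(comparison_rows, out)
    else:
        with open(out / "counts.json", "w", encoding="utf-8") as fh:
            json.dump(counts, fh, indent=2)
            fh.write("\n")
    if sens is not None:
        sens.to_frame().to_csv(out / "sensitivity_grid.csv", index=False)
        with open(out / "sensitivity_verdict.json", "w", encoding="utf-8") as fh:
            json.dump({"robust": sens.robust,
                       "majority_threshold": sens.majority_threshold}, fh, indent=2)
            fh.write("\n")
    provenance = {
        c: {
            "annuity_factor": params[c].annuity,
            "annuity_source": ("closed-form from (r, LE, age)"
                               if params[c].annuity_override is None
                               else "derived from published value pairs"),
            "rho": params[c].rho,
            "voq_per_voly": params[c].voq_per_voly,
        }
        for c in sorted({r.country for r in records})
    }
    with open(out / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump({"strict_conversion": config.strict_conversion,
                   "parameters": provenance}, fh, indent=2)
        fh.write("\n")
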