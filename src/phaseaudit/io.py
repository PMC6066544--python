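"""Readers, writers, and report rendering.

Phenotype tables travel as CSV/TSV with a header row plus a sidecar
YAML/JSON file mapping each trait to its {domain, timescale} annotation.
Audit reports serialize to canonical JSON (stable key order, shortest
round-trip floats) or human-readable markdown carrying the warning
catalogue text.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import pandas as pd
import yaml

from .design import WARNING_CATALOGUE, AuditReport
from .phenotypes import PhenotypeError, PhenotypeTable, TraitMeta

logger = logging.getLogger(__name__)


def read_trait_meta(path: str | Path) -> dict[str, TraitMeta]:
    """Read a trait-metadata sidecar (YAML or JSON by extension)."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise PhenotypeError(f"trait metadata in {path} is not a mapping")
    meta: dict[str, TraitMeta] = {}
    for name, entry in raw.items():
        try:
            meta[name] = TraitMeta(domain=entry["domain"], timescale=entry["timescale"])
        except (KeyError, TypeError) as exc:
            raise PhenotypeError(f"trait {name!r}: bad metadata entry {entry!r}") from exc
    return meta


def read_phenotype_table(
    path: str | Path,
    meta_path: str | Path,
    outcome: str = "phase",
    strain: str | None = None,
    stadium: str | None = None,
    delimiter: str | None = None,
) -> PhenotypeTable:
    """Read and validate a phenotype table from CSV/TSV plus its sidecar.

    Delimiter is auto-detected from the extension (``.tsv`` -> tab) unless
    given.  Trait cells that fail to parse as numbers are treated as
    missing and the affected rows dropped under the complete-case policy,
    with the count logged.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    if outcome not in df.columns:
        raise PhenotypeError(f"outcome column {outcome!r} not found in {path.name}")
    meta = read_trait_meta(meta_path)
    missing = [t for t in meta if t not in df.columns]
    if missing:
        raise PhenotypeError(f"trait(s) in metadata but not in {path.name}: {missing}")
    for t in meta:
        df[t] = pd.to_numeric(df[t], errors="coerce")
    table = PhenotypeTable(
        data=df, environment=outcome, trait_meta=meta, strain=strain, stadium=stadium
    )
    table, dropped = table.complete_cases([outcome, *meta])
    if dropped:
        logger.info("dropped %d row(s) with missing/unparseable values", dropped)
    levels = table.environment_levels()
    if len(levels) < 2:
        raise PhenotypeError(
            f"outcome column {outcome!r} has {len(levels)} level(s) after filtering"
        )
    return table


def write_phenotype_table(
    table: PhenotypeTable, path: str | Path, meta_path: str | Path | None = None
) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    # shortest round-trip decimal representation, full precision preserved
    table.data.to_csv(path, index=False, sep=sep, float_format=lambda v: repr(float(v)))
    if meta_path is not None:
        payload = {
            name: {"domain": m.domain, "timescale": m.timescale}
            for name, m in table.trait_meta.items()
        }
        Path(meta_path).write_text(yaml.safe_dump(payload, sort_keys=True))


# ---------------------------------------------------------------------------
# report serialization


def _sanitize(obj):
    """Replace non-finite floats so the JSON stays standard-compliant."""
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    return obj


def report_to_json(report: AuditReport) -> str:
    """Canonical JSON: insertion-ordered keys, shortest round-trip floats."""
    return json.dumps(_sanitize(report.to_dict()), indent=2, allow_nan=False) + "\n"


def report_to_markdown(report: AuditReport) -> str:
    d = report.to_dict()
    lines: list[str] = ["# Model audit report", ""]
    lines.append(f"Completed stages: {', '.join(d['completed_stages']) or 'none'}")
    if d["fatal_error"]:
        lines += ["", f"**Fatal error:** {d['fatal_error']}"]
    lines += ["", "## Warnings", ""]
    if d["warnings"]:
        for w in d["warnings"]:
            lines.append(f"- **{w['code']}** — {WARNING_CATALOGUE[w['code']]}")
            if w["detail"]:
                lines.append(f"  - {w['detail']}")
    else:
        lines.append("- none")
    if d["design_audit"]:
        da = d["design_audit"]
        lines += [
            "",
            "## Design",
            "",
            f"- events: {da['n_event']}, non-events: {da['n_nonevent']}, "
            f"predictor terms: {da['k']}",
            f"- events per variable: {da['epv']:.2f} (verdict: {da['verdict']})",
        ]
    if d["fit"]:
        f = d["fit"]
        lines += ["", "## Fit", ""]
        lines.append(
            f"- converged: {f['converged']} in {f['n_iterations']} iterations; "
            f"deviance {f['deviance']:.4g}"
        )
        lines.append(
            f"- separation: {f['separation']['kind']} "
            f"(extreme fraction {f['separation']['extreme_fraction']:.3f})"
        )
        lines.append("")
        lines.append("| term | coefficient | SE |")
        lines.append("|---|---|---|")
        for t in f["terms"]:
            lines.append(
                f"| {t} | {f['coefficients'][t]:.4g} | {f['standard_errors'][t]:.4g} |"
            )
    if d["validation"]:
        v = d["validation"]
        lines += [
            "",
            "## Internal validation (optimism bootstrap)",
            "",
            f"- Somers' Dxy: apparent {v['dxy_apparent']:.3f}, "
            f"corrected {v['dxy_corrected']:.3f}",
            f"- calibration intercept: corrected {v['cal_intercept_corrected']:.3f} "
            "(0 is ideal)",
            f"- calibration slope: corrected {v['cal_slope_corrected']:.3f} "
            "(1 is ideal; well below 1 = overfitting)",
            f"- failed replicates: {v['B_failed']} / {v['B_requested']} "
            f"({v['failure_fraction']:.0%})",
        ]
    return "\n".join(lines) + "\n"


def write_report(report: AuditReport, path: str | Path, format: str = "json") -> Path:
    """Write an audit report as canonical JSON or rendered markdown."""
    path = Path(path)
    if format == "json":
        path.write_text(report_to_json(report))
    elif format == "markdown":
        path.write_text(report_to_markdown(report))
    else:
        raise PhenotypeError(f"unknown report format {format!r}")
    return path
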