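"""End-to-end audit orchestration: ingest → scope → geolocate → stats.

``run_audit`` executes the whole pipeline from a validated configuration,
writes the report CSVs, and records a JSON manifest with per-stage record
counts (conservation reconciles exactly), the parameters used, and checksums
of every reference table so a published audit is reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import pandas as pd

from . import ingest, stats, synthetic
from .geo import WorldTable, attribute_geography
from .records import GeoStatus
from .resources import packaged_path
from .scope import BodySiteTable, HostLexicon, scope_records

logger = logging.getLogger(__name__)


class AuditError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class AuditConfig:
    """Inputs, reference tables and thresholds for one audit run."""

    xml_paths: list[str] = field(default_factory=list)
    runinfo_path: str | None = None
    out_dir: str = "audit_out"
    world_path: str | None = None
    gazetteer_path: str | None = None
    body_sites_path: str | None = None
    lexicon_path: str | None = None
    generic_threshold: int = 1000
    min_samples: int = 50
    cutoff: date = ingest.DEFAULT_CUTOFF
    #: When set, generate a synthetic cohort instead of reading files.
    simulate_n: int | None = None
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "AuditConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "cutoff" in raw and isinstance(raw["cutoff"], str):
            raw["cutoff"] = date.fromisoformat(raw["cutoff"])
        return cls(**raw)

    def validate(self) -> None:
        if self.generic_threshold <= 0 or self.min_samples <= 0:
            raise AuditError("config: thresholds must be positive")
        if self.simulate_n is None and not self.xml_paths:
            raise AuditError("config: either xml_paths or simulate_n is required")
        paths = [("xml", p) for p in self.xml_paths]
        paths += [
            ("runinfo", self.runinfo_path),
            ("world", self.world_path),
            ("gazetteer", self.gazetteer_path),
            ("body_sites", self.body_sites_path),
            ("lexicon", self.lexicon_path),
        ]
        for label, candidate in paths:
            if candidate is not None and not Path(candidate).exists():
                raise AuditError(f"config: {label} path does not exist: {candidate}")


def _reference_paths(config: AuditConfig) -> dict[str, Path]:
    return {
        "world": Path(config.world_path) if config.world_path else packaged_path("world_countries.csv"),
        "gazetteer": Path(config.gazetteer_path) if config.gazetteer_path else packaged_path("gazetteer.csv"),
        "body_sites": Path(config.body_sites_path) if config.body_sites_path else packaged_path("body_sites.csv"),
        "lexicon": Path(config.lexicon_path) if config.lexicon_path else packaged_path("host_lexicon.yaml"),
    }


@dataclass
class ValidationReport:
    problems: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.problems


def validate_references(
    world: WorldTable, body_sites: BodySiteTable, lexicon: HostLexicon
) -> ValidationReport:
    """Enforce every reference-table invariant; collect row-level diagnostics."""
    report = ValidationReport()
    for name, obj in [("world", world), ("body_sites", body_sites), ("lexicon", lexicon)]:
        try:
            obj.validate()
        except ValueError as exc:
            report.problems.append(f"{name}: {exc}")
    logger.info("reference validation: %s (world table lists %d LDCs)",
                "ok" if report.ok else report.problems, world.n_ldc)
    return report


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_audit(config: AuditConfig) -> dict:
    """Run the full pipeline; returns the manifest (also written as JSON).

    Any stage error aborts with the stage name and cause, and partial
    outputs written to ``out_dir`` are removed.
    """
    config.validate()
    refs = _reference_paths(config)
    world = WorldTable.from_csv(refs["world"], refs["gazetteer"])
    body_sites = BodySiteTable.from_csv(refs["body_sites"])
    lexicon = HostLexicon.from_yaml(refs["lexicon"])
    validation = validate_references(world, body_sites, lexicon)
    if not validation.ok:
        raise AuditError(f"reference validation failed: {validation.problems}")

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out_dir / name
        df.to_csv(path, index=False, float_format="%.10g")
        written.append(path)

    stage_counts: list[dict] = []

    def record_stage(name: str, n_in: int, n_out: int) -> None:
        stage_counts.append({"stage": name, "n_in": n_in, "n_out": n_out, "n_removed": n_in - n_out})

    try:
        # --- ingest -------------------------------------------------------
        stage = "ingest"
        if config.simulate_n is not None:
            cohort = synthetic.SyntheticCohortConfig(n_samples=config.simulate_n, seed=config.seed)
            records, runinfo, _truth = synthetic.generate_cohort(cohort, body_sites, world)
        else:
            records = []
            for xml_path in config.xml_paths:
                records.extend(ingest.parse_biosample(str(xml_path)))
            runinfo = (
                ingest.parse_runinfo(config.runinfo_path)
                if config.runinfo_path
                else pd.DataFrame(columns=["Run", "BioSample", "LibraryStrategy", "ReleaseDate"])
            )
        n_parsed = len(records)
        ingest.link_runs(records, runinfo)
        records, seq_stats = ingest.filter_sequenced(records)
        records, date_stats = ingest.filter_release_date(records, config.cutoff)
        record_stage("parse", n_parsed, n_parsed)
        record_stage("filter_sequenced", seq_stats.n_in, seq_stats.n_kept)
        record_stage("filter_release_date", date_stats.n_in, date_stats.n_kept)
        usage = ingest.attribute_usage(records)

        # --- scope --------------------------------------------------------
        stage = "scope"
        records, scope_report = scope_records(records, body_sites, lexicon, config.generic_threshold)
        record_stage("scope", scope_report.n_input, scope_report.n_retained)

        # --- geolocate ----------------------------------------------------
        stage = "geolocate"
        records, geo_report = attribute_geography(records, world)
        record_stage("geolocate", len(records), len(records))

        # --- stats --------------------------------------------------------
        stage = "stats"
        country_table = stats.country_representation(records, world, config.min_samples)
        region_table = stats.regional_representation(records, world)
        body_table = stats.tabulate(records, "body_site")
        cross = stats.tabulate(records, "body_site_x_country")
        series = stats.time_series(records)
        amplicon_share = float("nan")
        n_runs = sum(len(r.runs) for r in records)
        if n_runs:
            n_amplicon = sum(
                1 for r in records for link in r.runs if link.library_strategy.upper() == "AMPLICON"
            )
            amplicon_share = n_amplicon / n_runs

        emit("table_country.csv", country_table)
        emit("table_region.csv", region_table)
        emit("table_body_site.csv", body_table)
        emit("crosstab_body_site_country.csv", cross)
        emit("time_series.csv", series)
        emit("attribute_usage.csv", usage)

        manifest = {
            "parameters": {
                "generic_threshold": config.generic_threshold,
                "min_samples": config.min_samples,
                "cutoff": config.cutoff.isoformat(),
                "seed": config.seed,
                "simulate_n": config.simulate_n,
            },
            "stages": stage_counts,
            "scope_report": {
                "n_generic_evaluated": scope_report.n_generic_evaluated,
                "n_distinct_host_values": scope_report.n_distinct_host_values,
                "n_values_flagged": scope_report.n_values_flagged,
                "n_records_flagged": scope_report.n_records_flagged,
                "flagged_percent": None
                if scope_report.n_generic_evaluated == 0
                else scope_report.flagged_percent,
            },
            "geo_report": {
                "n_records": geo_report.n_records,
                "n_known": geo_report.n_known,
                "n_distinct_countries": geo_report.n_distinct_countries,
                "status_counts": {s.value: geo_report.status_counts.get(s, 0) for s in GeoStatus},
            },
            "library_strategy": {"amplicon_run_share": None if n_runs == 0 else amplicon_share},
            "reference_checksums": {name: _checksum(path) for name, path in refs.items()},
        }
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        written.append(manifest_path)
        return manifest
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        if isinstance(exc, AuditError):
            raise
        raise AuditError(f"stage {stage!r} failed: {exc}") from exc
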