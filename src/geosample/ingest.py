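"""Parse BioSample-style metadata and apply the run/date filters.

Supports the NCBI BioSample XML dialect (BioSampleSet/BioSample/Attributes)
and an equivalent flat JSON dump, plus SRA RunInfo-style CSV run linkage.
Attribute names are lower-cased, trimmed and harmonized through a shipped
alias table (first occurrence wins on duplicates). Two filters mirror the
harvest rules of a repository audit: drop samples with no linked sequencing
runs, and drop samples released on/after a cutoff date (or with missing /
unparseable dates).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import date, datetime

import pandas as pd
from lxml import etree

from ._util import NULL_TOKENS, is_null_token
from .records import RunLink, SampleRecord
from .resources import read_packaged_csv

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = date(2021, 1, 1)


class ParseError(ValueError):
    pass


class DuplicateAccessionError(ParseError):
    pass


def load_attribute_aliases() -> dict[str, str]:
    df = read_packaged_csv("attribute_aliases.csv")
    return dict(zip(df.alias, df.canonical))


def _normalize_attribute(name: str, aliases: dict[str, str]) -> str:
    key = " ".join(name.strip().lower().split())
    return aliases.get(key, key)


def _parse_date(value: str | None) -> date | None:
    if not value:
        return None
    text = value.strip()
    for candidate in (text[:10], text):
        try:
            return date.fromisoformat(candidate)
        except ValueError:
            pass
    try:
        return datetime.strptime(text, "%m/%d/%Y").date()
    except ValueError:
        return None


def parse_biosample(
    source,
    aliases: dict[str, str] | None = None,
    dedupe_keep_first: bool = False,
) -> list[SampleRecord]:
    """Parse a BioSampleSet XML document into SampleRecords.

    One record per BioSample element. Records lacking a taxonomy ID get the
    sentinel 0 with a warning (dropped later by scoping). Duplicate
    accessions raise :class:`DuplicateAccessionError` unless
    ``dedupe_keep_first``; malformed XML raises :class:`ParseError` with the
    parser's position information.
    """
    if aliases is None:
        aliases = load_attribute_aliases()
    try:
        tree = etree.parse(source)
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed XML: {exc}") from exc

    records: list[SampleRecord] = []
    seen: set[str] = set()
    for element in tree.getroot().iter("BioSample"):
        accession = element.get("accession") or (element.findtext("Ids/Id[@db='BioSample']") or "").strip()
        if not accession:
            raise ParseError(f"BioSample element without accession at line {element.sourceline}")
        if accession in seen:
            if dedupe_keep_first:
                logger.warning("duplicate accession %s: keeping first occurrence", accession)
                continue
            raise DuplicateAccessionError(f"duplicate accession: {accession}")
        seen.add(accession)

        organism = element.find("Description/Organism")
        taxid_text = organism.get("taxonomy_id") if organism is not None else None
        if taxid_text is None:
            logger.warning("BioSample %s has no taxonomy ID; using sentinel 0", accession)
            taxid = 0
        else:
            taxid = int(taxid_text)

        attributes: dict[str, str] = {}
        for attr in element.iter("Attribute"):
            name = attr.get("attribute_name")
            if name is None:
                continue
            key = _normalize_attribute(name, aliases)
            value = attr.text or ""
            if key in attributes:
                if attributes[key] != value:
                    logger.warning(
                        "BioSample %s: attribute %r listed twice; keeping first value", accession, key
                    )
                continue
            attributes[key] = value

        release = _parse_date(element.get("publication_date"))
        records.append(SampleRecord(accession, taxid, attributes, release))
    return records


def parse_biosample_json(source, aliases: dict[str, str] | None = None) -> list[SampleRecord]:
    """Parse the flat JSON dialect: a list of objects with keys
    accession / taxonomy_id / release_date / attributes."""
    if aliases is None:
        aliases = load_attribute_aliases()
    raw = json.load(open(source)) if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__") else json.load(source)
    records = []
    seen: set[str] = set()
    for entry in raw:
        accession = entry["accession"]
        if accession in seen:
            raise DuplicateAccessionError(f"duplicate accession: {accession}")
        seen.add(accession)
        attributes = {
            _normalize_attribute(k, aliases): str(v) for k, v in (entry.get("attributes") or {}).items()
        }
        records.append(
            SampleRecord(
                accession,
                int(entry.get("taxonomy_id") or 0),
                attributes,
                _parse_date(entry.get("release_date")),
            )
        )
    return records


def parse_runinfo(source) -> pd.DataFrame:
    """Read an SRA RunInfo-style CSV (Run, BioSample, LibraryStrategy, ReleaseDate)."""
    df = pd.read_csv(source, dtype=str)
    missing = {"Run", "BioSample"} - set(df.columns)
    if missing:
        raise ParseError(f"runinfo is missing required columns: {sorted(missing)}")
    return df


def link_runs(records: list[SampleRecord], runinfo: pd.DataFrame) -> list[SampleRecord]:
    """Attach run links to records; deduplicate by run accession.

    RunInfo rows pointing at accessions absent from ``records`` are ignored
    with a warning (they belong to samples outside the parsed cohort).
    """
    by_accession = {rec.accession: rec for rec in records}
    n_unknown = 0
    seen_runs: set[tuple[str, str]] = set()
    for rec in records:
        rec.runs = []
    for row in runinfo.itertuples():
        rec = by_accession.get(row.BioSample)
        if rec is None:
            n_unknown += 1
            continue
        key = (row.BioSample, row.Run)
        if key in seen_runs:
            continue
        seen_runs.add(key)
        strategy = getattr(row, "LibraryStrategy", "") or ""
        rec.runs.append(RunLink(row.Run, strategy))
    if n_unknown:
        logger.warning("%d runinfo rows reference accessions outside the cohort; ignored", n_unknown)
    return records


@dataclass
class FilterStats:
    """Bookkeeping for one filter stage (conservation: n_in = n_kept + n_removed)."""

    stage: str
    n_in: int
    n_kept: int
    reasons: dict[str, int] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return self.n_in - self.n_kept


def filter_sequenced(records: list[SampleRecord]) -> tuple[list[SampleRecord], FilterStats]:
    """Keep only records associated with actual sequencing data (≥1 run)."""
    kept = [rec for rec in records if rec.runs]
    stats = FilterStats("sequenced", len(records), len(kept), {"no_runs": len(records) - len(kept)})
    if stats.n_removed:
        logger.info("filter_sequenced: removed %d/%d records with no runs", stats.n_removed, stats.n_in)
    return kept, stats


def filter_release_date(
    records: list[SampleRecord], cutoff: date = DEFAULT_CUTOFF
) -> tuple[list[SampleRecord], FilterStats]:
    """Keep records released strictly before ``cutoff``; drop missing dates."""
    kept: list[SampleRecord] = []
    n_missing = n_late = 0
    for rec in records:
        if rec.release_date is None:
            n_missing += 1
        elif rec.release_date >= cutoff:
            n_late += 1
        else:
            kept.append(rec)
    stats = FilterStats(
        "release_date", len(records), len(kept), {"missing_date": n_missing, "on_or_after_cutoff": n_late}
    )
    if stats.n_removed:
        logger.info(
            "filter_release_date: removed %d records (%d missing dates, %d on/after %s)",
            stats.n_removed, n_missing, n_late, cutoff,
        )
    return kept, stats


def attribute_usage(
    records: list[SampleRecord],
    count_null_as_present: bool = False,
    null_tokens: frozenset[str] = NULL_TOKENS,
) -> pd.DataFrame:
    """Per-attribute usage: how many samples carry a value for each field.

    Null-token values count as missing by default, mirroring the treatment of
    null geography; set ``count_null_as_present`` to count raw occurrences.
    """
    from collections import Counter

    counts: Counter = Counter()
    for rec in records:
        for name, value in rec.attributes.items():
            if count_null_as_present or not is_null_token(value, null_tokens):
                counts[name] += 1
    df = pd.DataFrame(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])), columns=["attribute", "samples"])
    return df
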