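"""Geographic attribution: free-text geography → country, SDG region, LDC flag.

Sample geography arrives as the INSDC ``geo_loc_name`` convention
("Country: subdivision") with heterogeneous spellings and null tokens. This
module resolves each record to an ISO-3166 alpha-3 code via a synonym
gazetteer, then joins the UN SDG region, least-developed-country flag and
2020 population from the packaged world table.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from ._util import NULL_TOKENS, fold, is_null_token
from .records import UNKNOWN_REGION, GeoAssignment, GeoStatus, SampleRecord
from .resources import packaged_path

logger = logging.getLogger(__name__)

#: Attribute names inspected for geography, in priority order (after
#: ingest-time alias harmonization the first normally suffices).
DEFAULT_GEO_ATTRIBUTES: tuple[str, ...] = (
    "geo_loc_name",
    "geographic location (country and/or sea)",
    "geographic location",
)

#: Antarctica has no UN population estimate and belongs to no SDG region; it
#: resolves to a country code but always maps to the Unknown region.
ANTARCTICA_CODE = "ATA"
_ANTARCTICA_ALIASES = {"antarctica", "ata"}


class WorldTableError(ValueError):
    """Raised when the world table or gazetteer violates an invariant."""


@dataclass
class WorldTable:
    """Country reference: populations, SDG regions, LDC membership, synonyms.

    ``countries`` has one row per country_code (population_thousands > 0,
    exactly 8 SDG regions overall); ``aliases`` maps folded alias strings to
    codes and always contains every canonical name and code.
    """

    countries: pd.DataFrame
    aliases: dict[str, str] = field(repr=False)
    _rows: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_frames(cls, countries: pd.DataFrame, gazetteer: pd.DataFrame | None = None) -> "WorldTable":
        aliases: dict[str, str] = {}

        def add(alias: str, code: str, source: str) -> None:
            key = fold(alias)
            if not key:
                return
            if key in aliases and aliases[key] != code:
                raise WorldTableError(
                    f"alias {alias!r} ({source}) maps to both {aliases[key]} and {code}"
                )
            aliases[key] = code

        for row in countries.itertuples():
            add(row.name, row.country_code, "canonical name")
            add(row.country_code, row.country_code, "country code")
        if gazetteer is not None:
            for row in gazetteer.itertuples():
                add(row.alias, row.country_code, "gazetteer")
        table = cls(countries=countries.reset_index(drop=True), aliases=aliases)
        table._rows = {row.country_code: row for row in table.countries.itertuples()}
        table.validate()
        return table

    @classmethod
    def from_csv(cls, countries_path, gazetteer_path=None) -> "WorldTable":
        countries = pd.read_csv(countries_path, comment="#")
        gazetteer = pd.read_csv(gazetteer_path, comment="#") if gazetteer_path else None
        return cls.from_frames(countries, gazetteer)

    @classmethod
    def packaged(cls) -> "WorldTable":
        return cls.from_csv(packaged_path("world_countries.csv"), packaged_path("gazetteer.csv"))

    def validate(self) -> None:
        """Enforce table invariants; raises with row-level diagnostics."""
        df = self.countries
        problems: list[str] = []
        dup = df[df.country_code.duplicated(keep=False)]
        if not dup.empty:
            problems.append(f"duplicate country codes: {sorted(dup.country_code.unique())}")
        bad_pop = df[~(df.population_thousands > 0)]
        if not bad_pop.empty:
            problems.append(f"non-positive populations: {sorted(bad_pop.country_code)}")
        regions = set(df.sdg_region.unique())
        if len(regions) != 8:
            problems.append(f"expected exactly 8 SDG regions, found {len(regions)}: {sorted(regions)}")
        unreachable = [
            row.country_code for row in df.itertuples() if self.aliases.get(fold(row.name)) != row.country_code
        ]
        if unreachable:
            problems.append(f"countries unreachable by canonical name: {unreachable}")
        known_codes = set(df.country_code)
        stray = sorted(set(self.aliases.values()) - known_codes - {ANTARCTICA_CODE})
        if stray:
            problems.append(f"gazetteer aliases point at unknown codes: {stray}")
        if problems:
            raise WorldTableError("; ".join(problems))

    # -- lookups -----------------------------------------------------------

    def lookup(self, token: str):
        """Row (itertuples namedtuple) for an alias, or None if unmatched."""
        code = self.aliases.get(fold(token))
        if code is None:
            return None
        if not self._rows:
            self._rows = {row.country_code: row for row in self.countries.itertuples()}
        return self._rows.get(code)

    @property
    def n_ldc(self) -> int:
        return int(self.countries.is_ldc.astype(bool).sum())

    def world_population(self) -> float:
        return float(self.countries.population_thousands.sum())

    def population_of(self, code: str) -> float:
        row = self.lookup(code)
        return float(row.population_thousands) if row is not None else float("nan")

    def region_of(self, code: str) -> str:
        if code == ANTARCTICA_CODE:
            return UNKNOWN_REGION
        row = self.lookup(code)
        return str(row.sdg_region) if row is not None else UNKNOWN_REGION


def parse_geo_value(
    raw: str | None, null_tokens: frozenset[str] = NULL_TOKENS
) -> tuple[str | None, str | None, GeoStatus]:
    """Split a geo_loc_name-style value into (country token, subdivision, status).

    The INSDC convention is "Country: subdivision"; the split is on the first
    colon with both parts trimmed. Null tokens yield ``NULL_TOKEN``; missing
    values yield ``ABSENT``. A returned token is only a *candidate* — it still
    has to survive the gazetteer lookup.
    """
    if raw is None:
        return None, None, GeoStatus.ABSENT
    stripped = raw.strip()
    if is_null_token(stripped, null_tokens):
        status = GeoStatus.ABSENT if stripped == "" else GeoStatus.NULL_TOKEN
        return None, None, status
    country, _, subdivision = stripped.partition(":")
    return country.strip(), (subdivision.strip() or None), GeoStatus.RESOLVED


def resolve_country(token: str, world: WorldTable, raw_value: str | None = None) -> GeoAssignment:
    """Exact (case/diacritic-insensitive) gazetteer lookup of a country token."""
    raw = raw_value if raw_value is not None else token
    if fold(token) in _ANTARCTICA_ALIASES:
        return GeoAssignment(raw, ANTARCTICA_CODE, "Antarctica", UNKNOWN_REGION, False, GeoStatus.RESOLVED)
    row = world.lookup(token)
    if row is None:
        return GeoAssignment(raw, None, None, UNKNOWN_REGION, False, GeoStatus.UNRECOGNIZED)
    return GeoAssignment(
        raw_value=raw,
        country_code=str(row.country_code),
        country_name=str(row.name),
        region=str(row.sdg_region),
        is_ldc=bool(row.is_ldc),
        status=GeoStatus.RESOLVED,
    )


@dataclass
class GeoReport:
    """Resolution outcome counts for one attribution pass."""

    n_records: int
    status_counts: Counter
    n_distinct_countries: int
    unrecognized_values: Counter = field(default_factory=Counter)

    @property
    def n_known(self) -> int:
        return self.status_counts.get(GeoStatus.RESOLVED, 0)


def attribute_geography(
    records: list[SampleRecord],
    world: WorldTable,
    geo_attributes: tuple[str, ...] = DEFAULT_GEO_ATTRIBUTES,
    null_tokens: frozenset[str] = NULL_TOKENS,
) -> tuple[list[SampleRecord], GeoReport]:
    """Attach a :class:`GeoAssignment` to every record.

    The first attribute in ``geo_attributes`` that is present on the record is
    used. Attribution is per-record and therefore independent of record order.
    """
    status_counts: Counter = Counter()
    countries: set[str] = set()
    unrecognized: Counter = Counter()
    for rec in records:
        raw = next((rec.attributes[a] for a in geo_attributes if a in rec.attributes), None)
        token, _, status = parse_geo_value(raw, null_tokens)
        if status is GeoStatus.RESOLVED and token is not None:
            geo = resolve_country(token, world, raw_value=raw)
        else:
            geo = GeoAssignment(raw, None, None, UNKNOWN_REGION, False, status)
        rec.geo = geo
        status_counts[geo.status] += 1
        if geo.status is GeoStatus.RESOLVED:
            countries.add(geo.country_code)  # type: ignore[arg-type]
        elif geo.status is GeoStatus.UNRECOGNIZED:
            unrecognized[token] += 1
    report = GeoReport(len(records), status_counts, len(countries), unrecognized)
    if report.unrecognized_values:
        logger.info("unrecognized geography values: %s", dict(report.unrecognized_values.most_common(10)))
    return records, report
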