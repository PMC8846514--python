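"""Synthetic BioSample-style cohorts with exact ground truth.

Generates metadata records that structurally emulate a repository dump of
human-microbiome samples — multinomial country composition, a body-site
mixture over human-labeled and generic taxonomy categories, configurable
geographic missingness and messy spellings, host attributes on generic
records, run linkage and 2010–2020 release dates — together with a
:class:`GroundTruth` table recording, per record, everything the generator
drew. Every downstream stage can therefore be tested against known truth
without any download.

Defaults reproduce the composition observed in the 2021 census of the INSDC
repositories: country weights proportional to the published top-20 country
counts, body-site weights proportional to the published per-site counts,
14% missing geography, 17.3% human-host rate among generic-category records,
and year weights following the repository's growth from a handful of samples
in 2010 to >100,000 in 2020.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from datetime import date
from typing import Mapping

import numpy as np
import pandas as pd
from lxml import etree

from ._util import NULL_TOKENS
from .geo import WorldTable
from .records import RunLink, SampleRecord
from .scope import GENERIC, HUMAN_LABELED, BodySiteTable

__all__ = [
    "SyntheticCohortConfig",
    "GroundTruth",
    "ConfigurationError",
    "generate_cohort",
    "write_biosample_xml",
    "write_runinfo_csv",
]


class ConfigurationError(ValueError):
    """Invalid generator configuration; the message names the field."""


# Published per-country sample counts (top 20 of the 2021 repository census),
# used as default country weights after normalization.
_COUNTRY_COUNTS_2021 = {
    "USA": 178960, "CHN": 36162, "GBR": 16076, "DNK": 11497, "AUS": 9266,
    "NLD": 9173, "CAN": 8829, "FIN": 7855, "ITA": 6265, "DEU": 5531,
    "ESP": 5517, "SWE": 5248, "ISR": 4831, "NZL": 4354, "JPN": 4298,
    "CHL": 3616, "BGD": 3502, "FRA": 3402, "MWI": 3052, "IND": 2997,
}

# Published per-body-site sample counts (same census).
_BODY_SITE_COUNTS_2021 = {
    "gut": 220017, "human metagenome": 69697, "oral": 47798, "skin": 36593,
    "vaginal": 17784, "lung": 17307, "nasopharyngeal": 15646, "feces": 6858,
    "reproductive system": 3180, "blood": 2707, "saliva": 2503, "milk": 2060,
    "urinary tract": 1187, "tracheal": 520, "sputum": 364, "eye": 359,
    "semen": 203, "bile": 45, "skeleton": 1,
}

# Annual release counts rising from 3 samples (2010) to 123,302 (2020),
# mirroring the observed repository growth curve.
_YEAR_COUNTS = {
    2010: 3, 2011: 300, 2012: 1500, 2013: 5000, 2014: 9000, 2015: 16000,
    2016: 25000, 2017: 41000, 2018: 60000, 2019: 90000, 2020: 123302,
}


def _normalize(counts: Mapping) -> dict:
    total = float(sum(counts.values()))
    return {k: v / total for k, v in counts.items()}


_HUMAN_HOST_VALUES = [
    ("host_taxid", "9606"),
    ("host", "Homo sapiens"),
    ("host", "human"),
    ("host", "Human adult"),
    ("host", "patient"),
    ("host", "crew member"),
]
_NONHUMAN_HOST_VALUES = [
    ("host", "Mus musculus"),
    ("host_taxid", "10090"),
    ("host", "Bos taurus"),
    ("host", "chicken"),
    ("host", "Sus scrofa domesticus"),
    ("host", "environmental"),
]
_SUBDIVISIONS = ["Minnesota", "Hubei", "Bavaria", "Western Province", "Copenhagen", "New South Wales"]
_LIBRARY_STRATEGIES = ["AMPLICON", "WGS"]
#: AMPLICON share among sequencing runs (the census reports roughly
#: three-quarters of samples carrying amplicon data).
_P_AMPLICON = 0.72


@dataclass
class SyntheticCohortConfig:
    """Generative parameters of one synthetic cohort; see module docstring."""

    n_samples: int = 2000
    country_weights: Mapping[str, float] = field(default_factory=lambda: _normalize(_COUNTRY_COUNTS_2021))
    body_site_weights: Mapping[str, float] = field(default_factory=lambda: _normalize(_BODY_SITE_COUNTS_2021))
    p_generic_category: float = 0.29
    p_human_host_given_generic: float = 0.173
    p_geo_missing: float = 0.14
    p_geo_messy: float = 0.30
    p_no_runs: float = 0.002
    year_weights: Mapping[int, float] = field(default_factory=lambda: _normalize(_YEAR_COUNTS))
    seed: int = 0
    null_tokens: tuple[str, ...] = tuple(sorted(NULL_TOKENS))

    def validate(self) -> None:
        if not isinstance(self.n_samples, (int, np.integer)) or self.n_samples < 1:
            raise ConfigurationError(f"n_samples must be a positive integer, got {self.n_samples!r}")
        for name in ("country_weights", "body_site_weights", "year_weights"):
            weights = getattr(self, name)
            if not weights:
                raise ConfigurationError(f"{name} must be a nonempty probability map")
            values = np.asarray(list(weights.values()), dtype=float)
            if (values < 0).any() or (values > 1).any():
                raise ConfigurationError(f"{name} entries must lie in [0, 1]")
            if abs(values.sum() - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} must sum to 1 (got {values.sum():.12f})")
        for name in (
            "p_generic_category", "p_human_host_given_generic",
            "p_geo_missing", "p_geo_messy", "p_no_runs",
        ):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1], got {p!r}")


@dataclass
class GroundTruth:
    """Per-record generative truth plus derived marginals.

    ``frame`` has one row per emitted record: accession, country, geo_missing,
    geo_messy, body_site, generic, human_host, year, n_runs. Marginal counts
    always sum to ``n`` for every seed, by construction.
    """

    frame: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def country_counts(self) -> dict[str, int]:
        return self.frame.country.value_counts().to_dict()

    @property
    def body_site_counts(self) -> dict[str, int]:
        return self.frame.body_site.value_counts().to_dict()

    @property
    def year_counts(self) -> dict[int, int]:
        return self.frame.year.value_counts().to_dict()

    @property
    def n_geo_missing(self) -> int:
        return int(self.frame.geo_missing.sum())

    @property
    def attribute_counts(self) -> dict[str, int]:
        from collections import Counter

        counts: Counter = Counter()
        for attrs in self.frame.attribute_names:
            counts.update(attrs)
        return dict(counts)

    def expected_stage_counts(self, generic_threshold: int = 1000, cutoff_year: int = 2021) -> dict[str, int]:
        """Record counts expected to survive each pipeline stage, in order."""
        df = self.frame
        after_runs = df[df.n_runs > 0]
        after_date = after_runs[after_runs.year < cutoff_year]
        generic_sizes = after_date[after_date.generic].groupby("generic_taxid").size()
        admitted = set(generic_sizes[generic_sizes >= generic_threshold].index)
        scoped = after_date[
            ~after_date.generic
            | (after_date.generic_taxid.isin(admitted) & after_date.human_host)
        ]
        return {
            "parsed": len(df),
            "sequenced": len(after_runs),
            "dated": len(after_date),
            "scoped": len(scoped),
        }


def generate_cohort(
    config: SyntheticCohortConfig,
    body_sites: BodySiteTable | None = None,
    world: WorldTable | None = None,
) -> tuple[list[SampleRecord], pd.DataFrame, GroundTruth]:
    """Draw one cohort. Fixed seed ⇒ byte-identical output.

    All random draws use a single seeded generator in a fixed field order
    (country, geo presentation, body site, category class, host, date, runs),
    each field vectorized over the cohort, so output is reproducible across
    platforms and n.
    """
    config.validate()
    table = body_sites if body_sites is not None else BodySiteTable.packaged()
    wt = world if world is not None else WorldTable.packaged()
    unknown_codes = sorted(set(config.country_weights) - set(wt.countries.country_code))
    if unknown_codes:
        raise ConfigurationError(f"country_weights contains codes absent from the world table: {unknown_codes}")

    rng = np.random.default_rng(config.seed)
    n = config.n_samples

    countries = list(config.country_weights)
    country_idx = rng.choice(len(countries), size=n, p=list(config.country_weights.values()))
    geo_missing = rng.random(n) < config.p_geo_missing
    null_choice = rng.integers(0, len(config.null_tokens), size=n)
    geo_as_attr_null = rng.random(n) < 0.5  # missing geo: null token vs absent attribute
    geo_messy = (~geo_missing) & (rng.random(n) < config.p_geo_messy)
    messy_style = rng.integers(0, 3, size=n)
    subdivision_idx = rng.integers(0, len(_SUBDIVISIONS), size=n)

    sites = list(config.body_site_weights)
    site_idx = rng.choice(len(sites), size=n, p=list(config.body_site_weights.values()))
    generic_draw = rng.random(n) < config.p_generic_category
    human_host = rng.random(n) < config.p_human_host_given_generic
    host_variant = rng.integers(0, max(len(_HUMAN_HOST_VALUES), len(_NONHUMAN_HOST_VALUES)), size=n)

    years = list(config.year_weights)
    year_idx = rng.choice(len(years), size=n, p=list(config.year_weights.values()))
    months = rng.integers(1, 13, size=n)
    days = rng.integers(1, 29, size=n)

    no_runs = rng.random(n) < config.p_no_runs
    runs_per_record = rng.integers(1, 4, size=n)
    amplicon = rng.random(int(runs_per_record.sum())) < _P_AMPLICON

    # Alias pools for messy spellings, from the gazetteer (canonical name and
    # bare code excluded so "messy" really is nonstandard).
    canonical = dict(zip(wt.countries.country_code, wt.countries["name"]))
    alias_pool: dict[str, list[str]] = {code: [] for code in countries}
    from .resources import read_packaged_csv

    for row in read_packaged_csv("gazetteer.csv").itertuples():
        if row.country_code in alias_pool:
            alias_pool[row.country_code].append(row.alias)
    alias_idx = rng.integers(0, 10**6, size=n)  # modded per-record by pool size

    records: list[SampleRecord] = []
    runinfo_rows: list[tuple[str, str, str, str]] = []
    truth_rows: list[dict] = []
    run_counter = 0
    run_cursor = 0

    site_human = {row.body_site: int(row.human_taxid) for row in table.df.itertuples()}
    site_generic = {
        row.body_site: (None if pd.isna(row.generic_taxid) else int(row.generic_taxid))
        for row in table.df.itertuples()
    }

    for i in range(n):
        accession = f"SAMN{i + 1:08d}"
        code = countries[country_idx[i]]
        site = sites[site_idx[i]]
        generic_taxid = site_generic[site]
        is_generic = bool(generic_draw[i]) and generic_taxid is not None
        taxid = generic_taxid if is_generic else site_human[site]

        attributes: dict[str, str] = {}
        if geo_missing[i]:
            if geo_as_attr_null[i]:
                attributes["geo_loc_name"] = config.null_tokens[null_choice[i]]
        elif geo_messy[i]:
            pool = alias_pool[code]
            style = messy_style[i]
            sub = _SUBDIVISIONS[subdivision_idx[i]]
            if style == 0 and pool:
                attributes["geo_loc_name"] = pool[alias_idx[i] % len(pool)]
            elif style == 1:
                attributes["geo_loc_name"] = f"{canonical[code]}: {sub}"
            else:
                base = pool[alias_idx[i] % len(pool)] if pool else canonical[code]
                attributes["geo_loc_name"] = f"{base}: {sub}"
        else:
            attributes["geo_loc_name"] = canonical[code]

        is_human_host = bool(human_host[i])
        if is_generic:
            pool2 = _HUMAN_HOST_VALUES if is_human_host else _NONHUMAN_HOST_VALUES
            key, value = pool2[host_variant[i] % len(pool2)]
            attributes[key] = value
        attributes["env_package"] = "human-associated"

        release = date(years[year_idx[i]], int(months[i]), int(days[i]))
        record = SampleRecord(
            accession=accession,
            taxonomy_id=int(taxid),
            attributes=attributes,
            release_date=release,
        )
        if not no_runs[i]:
            for _ in range(int(runs_per_record[i])):
                run_counter += 1
                strategy = _LIBRARY_STRATEGIES[0] if amplicon[run_cursor] else _LIBRARY_STRATEGIES[1]
                run_cursor += 1
                run_acc = f"SRR{run_counter:08d}"
                record.runs.append(RunLink(run_acc, strategy))
                runinfo_rows.append((run_acc, accession, strategy, release.isoformat()))
        records.append(record)
        truth_rows.append(
            {
                "accession": accession,
                "country": code,
                "geo_missing": bool(geo_missing[i]),
                "geo_messy": bool(geo_messy[i]),
                "body_site": site,
                "generic": is_generic,
                "generic_taxid": int(generic_taxid) if is_generic else -1,
                "human_host": is_generic and is_human_host,
                "year": years[year_idx[i]],
                "n_runs": 0 if no_runs[i] else int(runs_per_record[i]),
                "attribute_names": tuple(attributes),
            }
        )

    runs_df = pd.DataFrame(runinfo_rows, columns=["Run", "BioSample", "LibraryStrategy", "ReleaseDate"])
    truth = GroundTruth(pd.DataFrame(truth_rows))
    return records, runs_df, truth


# ---------------------------------------------------------------------------
# Writers (round-trip partners of metadata_ingest's parsers)
# ---------------------------------------------------------------------------

def _taxonomy_names(table: BodySiteTable) -> dict[int, str]:
    names: dict[int, str] = {}
    for row in table.df.itertuples():
        site = row.body_site
        if pd.notna(row.human_taxid):
            names[int(row.human_taxid)] = site if site == "human metagenome" else f"human {site} metagenome"
        if pd.notna(row.generic_taxid):
            names[int(row.generic_taxid)] = f"{site} metagenome"
    return names


def write_biosample_xml(records: list[SampleRecord], path, body_sites: BodySiteTable | None = None) -> None:
    """Serialize records as a BioSampleSet XML document (NCBI dialect)."""
    if not records:
        raise ValueError("cannot write an empty BioSampleSet")
    table = body_sites if body_sites is not None else BodySiteTable.packaged()
    names = _taxonomy_names(table)
    root = etree.Element("BioSampleSet")
    for rec in records:
        bs = etree.SubElement(root, "BioSample", accession=rec.accession)
        if rec.release_date is not None:
            bs.set("publication_date", rec.release_date.isoformat())
        ids = etree.SubElement(bs, "Ids")
        id_el = etree.SubElement(ids, "Id", db="BioSample", is_primary="1")
        id_el.text = rec.accession
        desc = etree.SubElement(bs, "Description")
        etree.SubElement(
            desc,
            "Organism",
            taxonomy_id=str(rec.taxonomy_id),
            taxonomy_name=names.get(rec.taxonomy_id, "metagenome"),
        )
        attrs = etree.SubElement(bs, "Attributes")
        for name, value in rec.attributes.items():
            attr = etree.SubElement(attrs, "Attribute", attribute_name=name)
            attr.text = value
    tree = etree.ElementTree(root)
    payload = etree.tostring(tree, xml_declaration=True, encoding="UTF-8", pretty_print=True)
    if hasattr(path, "write"):
        out = path
        out.write(payload if isinstance(out, (io.BufferedIOBase, io.RawIOBase)) else payload.decode())
    else:
        with open(path, "wb") as fh:
            fh.write(payload)


def write_runinfo_csv(runs: pd.DataFrame, path) -> None:
    """Serialize the run-linkage table as an SRA RunInfo-style CSV."""
    runs.to_csv(path, index=False)
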