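"""Cohort scoping: restrict records to human-microbiome samples.

Records filed under explicitly human taxonomy categories ("human gut
metagenome", ...) are kept outright. Records under the host-agnostic
"generic" sibling categories ("gut metagenome", ...) are admitted only when
(a) their category holds at least ``threshold`` samples and (b) their
host / host_taxid attribute indicates a human host per the lexicon.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd
import yaml

from ._util import NULL_TOKENS, fold, is_null_token, round_half_away
from .records import SampleRecord
from .resources import packaged_path

logger = logging.getLogger(__name__)

HUMAN_LABELED = "human-labeled"
GENERIC = "generic"

#: Anchor: NCBI taxonomy ID of the "human gut metagenome" category.
HUMAN_GUT_TAXID = 408170


class BodySiteTableError(ValueError):
    pass


@dataclass
class BodySiteTable:
    """Maps taxonomy IDs (human-labeled and generic) to body-site labels."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = self.df.copy()
        self.df["human_taxid"] = self.df["human_taxid"].astype("Int64")
        self.df["generic_taxid"] = self.df["generic_taxid"].astype("Int64")
        self._human = {int(t): s for s, t in zip(self.df.body_site, self.df.human_taxid) if pd.notna(t)}
        self._generic = {int(t): s for s, t in zip(self.df.body_site, self.df.generic_taxid) if pd.notna(t)}

    @classmethod
    def from_csv(cls, path) -> "BodySiteTable":
        return cls(pd.read_csv(path, comment="#"))

    @classmethod
    def packaged(cls) -> "BodySiteTable":
        return cls.from_csv(packaged_path("body_sites.csv"))

    def validate(self) -> None:
        problems: list[str] = []
        if self.df.body_site.duplicated().any():
            problems.append(f"duplicate body-site labels: {sorted(self.df.body_site[self.df.body_site.duplicated()])}")
        all_taxids = list(self._human) + list(self._generic)
        dupes = {t for t in all_taxids if all_taxids.count(t) > 1}
        if dupes:
            problems.append(f"taxonomy IDs appear in more than one row/column: {sorted(dupes)}")
        if self._human.get(HUMAN_GUT_TAXID) != "gut":
            problems.append(f"missing anchor row (gut, human_taxid {HUMAN_GUT_TAXID})")
        if problems:
            raise BodySiteTableError("; ".join(problems))

    @property
    def body_sites(self) -> list[str]:
        return list(self.df.body_site)

    def site_for_human(self, taxid: int) -> str | None:
        return self._human.get(taxid)

    def site_for_generic(self, taxid: int) -> str | None:
        return self._generic.get(taxid)

    def human_taxid_of(self, site: str) -> int:
        return int(self.df.set_index("body_site").human_taxid[site])

    def generic_taxid_of(self, site: str) -> int | None:
        val = self.df.set_index("body_site").generic_taxid[site]
        return None if pd.isna(val) else int(val)


@dataclass
class HostLexicon:
    """Rule set deciding whether a host value indicates a human host.

    ``human_taxids`` match numerically; ``positive_tokens`` are
    case-insensitive substrings; ``negative_overrides`` veto a positive match
    on a word boundary (so "adult mouse gut" is not human, while "humans" is).
    """

    human_taxids: frozenset[int] = frozenset({9606})
    positive_tokens: frozenset[str] = frozenset()
    negative_overrides: frozenset[str] = frozenset()
    _neg_re: re.Pattern | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        overlap = self.positive_tokens & self.negative_overrides
        if overlap:
            raise ValueError(f"positive and negative token sets overlap: {sorted(overlap)}")
        if self.negative_overrides:
            pattern = "|".join(re.escape(t) for t in sorted(self.negative_overrides, key=len, reverse=True))
            object.__setattr__(self, "_neg_re", re.compile(rf"(?<!\w)(?:{pattern})(?!\w)"))

    @classmethod
    def from_yaml(cls, path) -> "HostLexicon":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            human_taxids=frozenset(int(t) for t in raw.get("human_taxids", [9606])),
            positive_tokens=frozenset(fold(t) for t in raw.get("positive_tokens", [])),
            negative_overrides=frozenset(fold(t) for t in raw.get("negative_overrides", [])),
        )

    @classmethod
    def packaged(cls) -> "HostLexicon":
        return cls.from_yaml(packaged_path("host_lexicon.yaml"))

    def validate(self) -> None:
        # Disjointness is enforced at construction; nothing further to check.
        self.__post_init__()


def classify_body_site(record: SampleRecord, table: BodySiteTable) -> tuple[str | None, str | None]:
    """Body site and origin class for a record's taxonomy category."""
    site = table.site_for_human(record.taxonomy_id)
    if site is not None:
        return site, HUMAN_LABELED
    site = table.site_for_generic(record.taxonomy_id)
    if site is not None:
        return site, GENERIC
    return None, None


def select_generic_categories(per_category_counts: dict[int, int], threshold: int = 1000) -> set[int]:
    """Generic categories large enough to be worth host-screening (inclusive)."""
    for taxid, count in per_category_counts.items():
        if count < 0:
            raise ValueError(f"negative sample count for category {taxid}: {count}")
    return {taxid for taxid, count in per_category_counts.items() if count >= threshold}


def derive_putative_host(record: SampleRecord, null_tokens: frozenset[str] = NULL_TOKENS) -> str | None:
    """host_taxid if present and non-null, else host, else None."""
    for key in ("host_taxid", "host"):
        value = record.attributes.get(key)
        if value is not None and not is_null_token(value, null_tokens):
            return value
    return None


def flag_human_host(value: str | None, lexicon: HostLexicon) -> bool:
    """True iff the putative host value explicitly indicates a human."""
    if value is None:
        return False
    stripped = value.strip()
    try:
        return int(stripped) in lexicon.human_taxids
    except ValueError:
        pass
    folded = fold(stripped)
    if not any(tok in folded for tok in lexicon.positive_tokens):
        return False
    if lexicon._neg_re is not None and lexicon._neg_re.search(folded):
        return False
    return True


@dataclass
class ScopeReport:
    """Audit trail of the host-screening step.

    ``flagged_percent`` is the share of evaluated generic-category records
    whose host value was flagged human, rounded half-away at one decimal —
    the headline number of the screening stage.
    """

    n_input: int = 0
    n_human_labeled: int = 0
    n_generic_total: int = 0
    n_generic_evaluated: int = 0
    n_distinct_host_values: int = 0
    n_values_flagged: int = 0
    n_records_flagged: int = 0
    n_retained: int = 0
    admitted_categories: set[int] = field(default_factory=set)
    host_value_flags: dict[str, bool] = field(default_factory=dict)

    @property
    def flagged_percent(self) -> float:
        if self.n_generic_evaluated == 0:
            return float("nan")
        return round_half_away(100.0 * self.n_records_flagged / self.n_generic_evaluated, 1)


def scope_records(
    records: list[SampleRecord],
    table: BodySiteTable,
    lexicon: HostLexicon,
    threshold: int = 1000,
) -> tuple[list[SampleRecord], ScopeReport]:
    """Retain human-microbiome records; fill ``body_site`` on every survivor.

    Retained = human-labeled records ∪ (records of admitted generic
    categories whose host value is flagged human). Generic categories below
    the threshold are dropped wholesale, host value notwithstanding.
    """
    report = ScopeReport(n_input=len(records))
    generic_counts: dict[int, int] = {}
    classified: list[tuple[SampleRecord, str | None, str | None]] = []
    for rec in records:
        site, origin = classify_body_site(rec, table)
        classified.append((rec, site, origin))
        if origin == GENERIC:
            generic_counts[rec.taxonomy_id] = generic_counts.get(rec.taxonomy_id, 0) + 1
    report.n_generic_total = sum(generic_counts.values())
    report.admitted_categories = select_generic_categories(generic_counts, threshold)

    retained: list[SampleRecord] = []
    for rec, site, origin in classified:
        if origin == HUMAN_LABELED:
            rec.body_site, rec.body_site_origin = site, origin
            report.n_human_labeled += 1
            retained.append(rec)
        elif origin == GENERIC and rec.taxonomy_id in report.admitted_categories:
            report.n_generic_evaluated += 1
            host = derive_putative_host(rec)
            if host is not None and host not in report.host_value_flags:
                report.host_value_flags[host] = flag_human_host(host, lexicon)
            if host is not None and report.host_value_flags[host]:
                rec.body_site, rec.body_site_origin = site, origin
                report.n_records_flagged += 1
                retained.append(rec)
    report.n_distinct_host_values = len(report.host_value_flags)
    report.n_values_flagged = sum(report.host_value_flags.values())
    report.n_retained = len(retained)
    logger.info(
        "scope: %d/%d retained (%d human-labeled, %d/%d generic flagged human, %.1f%%)",
        report.n_retained, report.n_input, report.n_human_labeled,
        report.n_records_flagged, report.n_generic_evaluated,
        0.0 if report.n_generic_evaluated == 0 else 100.0 * report.n_records_flagged / report.n_generic_evaluated,
    )
    return retained, report
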