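"""Domain types shared across the pipeline.

A :class:`SampleRecord` is one BioSample-style metadata record — the unit of
all counting. Pipeline stages annotate it in place: scoping fills
``body_site``, geographic attribution fills ``geo``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from enum import Enum


class GeoStatus(str, Enum):
    """Outcome of resolving a record's free-text geographic attribute."""

    RESOLVED = "resolved"
    NULL_TOKEN = "null_token"
    UNRECOGNIZED = "unrecognized"
    ABSENT = "absent"


#: Region label used for any sample whose country cannot be placed in an SDG
#: region: unresolved geography, and Antarctica (which the UN assigns to no
#: region).
UNKNOWN_REGION = "Unknown"


@dataclass(frozen=True)
class GeoAssignment:
    """Resolved geography for one record.

    ``status == RESOLVED`` iff ``country_code`` is set; ``region`` is
    :data:`UNKNOWN_REGION` whenever the status is not resolved, and for
    Antarctica.
    """

    raw_value: str | None
    country_code: str | None
    country_name: str | None
    region: str
    is_ldc: bool
    status: GeoStatus

    def __post_init__(self) -> None:
        if (self.status is GeoStatus.RESOLVED) != (self.country_code is not None):
            raise ValueError("status 'resolved' requires a country_code and vice versa")
        if self.status is not GeoStatus.RESOLVED and self.region != UNKNOWN_REGION:
            raise ValueError("unresolved assignments must use the Unknown region")


@dataclass(frozen=True)
class RunLink:
    """One sequencing run linked to a sample."""

    run: str
    library_strategy: str = ""


@dataclass
class SampleRecord:
    accession: str
    taxonomy_id: int
    attributes: dict[str, str] = field(default_factory=dict)
    release_date: date | None = None
    runs: list[RunLink] = field(default_factory=list)
    body_site: str | None = None
    #: "human-labeled" (taxonomy category explicitly human) or "generic"
    #: (host-agnostic category, admitted via host flagging).
    body_site_origin: str | None = None
    geo: GeoAssignment | None = None

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be nonempty")
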