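"""Parsing, run linkage, and the run-existence / release-date filters."""

from __future__ import annotations

import io
from datetime import date

import pandas as pd
import pytest

from geosample.ingest import (
    DuplicateAccessionError,
    ParseError,
    attribute_usage,
    filter_release_date,
    filter_sequenced,
    link_runs,
    parse_biosample,
    parse_biosample_json,
    parse_runinfo,
)
from geosample.records import RunLink, SampleRecord


def _xml(body: str) -> io.BytesIO:
    return io.BytesIO(f"<BioSampleSet>{body}</BioSampleSet>".encode())


def _sample(accession: str, taxid: int = 408170, attrs: str = "") -> str:
    return (
        f'<BioSample accession="{accession}" publication_date="2020-06-01">'
        f'<Description><Organism taxonomy_id="{taxid}"/></Description>'
        f"<Attributes>{attrs}</Attributes></BioSample>"
    )


def test_parse_count_preservation():
    records = parse_biosample(_xml(_sample("SAMN1") + _sample("SAMN2") + _sample("SAMN3")))
    assert [r.accession for r in records] == ["SAMN1", "SAMN2", "SAMN3"]
    assert all(r.taxonomy_id == 408170 and r.release_date == date(2020, 6, 1) for r in records)


def test_duplicate_attribute_first_wins(caplog):
    attrs = (
        '<Attribute attribute_name="host">human</Attribute>'
        '<Attribute attribute_name="Host">mouse</Attribute>'
    )
    with caplog.at_level("WARNING"):
        (record,) = parse_biosample(_xml(_sample("SAMN1", attrs=attrs)))
    assert record.attributes["host"] == "human"
    assert any("listed twice" in m for m in caplog.messages)


def test_attribute_alias_harmonization():
    attrs = '<Attribute attribute_name="geographic location (country and/or sea)">Denmark</Attribute>'
    (record,) = parse_biosample(_xml(_sample("SAMN1", attrs=attrs)))
    assert record.attributes == {"geo_loc_name": "Denmark"}


def test_empty_biosampleset():
    assert parse_biosample(io.BytesIO(b"<BioSampleSet/>")) == []


def test_malformed_xml_raises_parse_error():
    with pytest.raises(ParseError, match="malformed XML"):
        parse_biosample(io.BytesIO(b"<BioSampleSet><BioSample>"))


def test_missing_taxonomy_id_gets_sentinel(caplog):
    body = '<BioSample accession="SAMN9"><Attributes/></BioSample>'
    with caplog.at_level("WARNING"):
        (record,) = parse_biosample(_xml(body))
    assert record.taxonomy_id == 0


def test_duplicate_accession_rejected_unless_overridden():
    doc = _sample("SAMN1") + _sample("SAMN1")
    with pytest.raises(DuplicateAccessionError, match="SAMN1"):
        parse_biosample(_xml(doc))
    assert len(parse_biosample(_xml(doc), dedupe_keep_first=True)) == 1


def test_parse_json_dialect():
    payload = io.StringIO(
        '[{"accession": "SAMN1", "taxonomy_id": 408170, "release_date": "2019-03-02",'
        ' "attributes": {"Geographic Location": "Chile"}}]'
    )
    (record,) = parse_biosample_json(payload)
    assert record.taxonomy_id == 408170
    assert record.release_date == date(2019, 3, 2)
    assert record.attributes == {"geo_loc_name": "Chile"}


def test_link_runs_matching_and_dedupe(caplog):
    records = [SampleRecord("SAMN1", 408170), SampleRecord("SAMN2", 408170)]
    runinfo = pd.DataFrame(
        {
            "Run": ["SRR1", "SRR1", "SRR2", "SRR3", "SRR4"],
            "BioSample": ["SAMN1", "SAMN1", "SAMN1", "SAMN1", "SAMNX"],
            "LibraryStrategy": ["AMPLICON"] * 5,
        }
    )
    with caplog.at_level("WARNING"):
        link_runs(records, runinfo)
    assert [r.run for r in records[0].runs] == ["SRR1", "SRR2", "SRR3"]
    assert records[1].runs == []
    assert any("outside the cohort" in m for m in caplog.messages)


def test_runinfo_requires_columns():
    with pytest.raises(ParseError, match="BioSample"):
        parse_runinfo(io.StringIO("Run,Strategy\nSRR1,WGS\n"))


def test_filter_sequenced_counts_and_idempotence():
    records = [SampleRecord(f"S{i}", 408170) for i in range(10)]
    for rec in records[:8]:
        rec.runs = [RunLink("SRR" + rec.accession)]
    kept, stats = filter_sequenced(records)
    assert (stats.n_in, len(kept), stats.n_removed) == (10, 8, 2)
    again, stats2 = filter_sequenced(kept)
    assert again == kept and stats2.n_removed == 0
    none_kept, all_removed = filter_sequenced([SampleRecord("S", 408170)])
    assert none_kept == [] and all_removed.n_removed == all_removed.n_in == 1


@pytest.mark.parametrize(
    "release, kept",
    [(date(2020, 12, 31), True), (date(2021, 1, 1), False), (None, False)],
)
def test_release_date_boundary(release, kept):
    record = SampleRecord("SAMN1", 408170, release_date=release)
    surviving, stats = filter_release_date([record])
    assert (len(surviving) == 1) is kept
    if release is None:
        assert stats.reasons["missing_date"] == 1


def test_pipeline_conservation_on_synthetic_cohort(small_cohort):
    _, records, runs, truth = small_cohort
    kept_seq, seq_stats = filter_sequenced(records)
    kept_date, date_stats = filter_release_date(kept_seq)
    assert seq_stats.n_in == seq_stats.n_kept + seq_stats.n_removed
    assert len(records) == len(kept_date) + seq_stats.n_removed + date_stats.n_removed
    expected = truth.expected_stage_counts()
    assert len(kept_seq) == expected["sequenced"]
    assert len(kept_date) == expected["dated"]
    # Idempotence of the date filter.
    again, stats2 = filter_release_date(kept_date)
    assert again == kept_date and stats2.n_removed == 0


def test_attribute_usage_counts():
    records = [
        SampleRecord("S1", 1, {"host": "human"}),
        SampleRecord("S2", 1, {"host": "human", "age": "33"}),
        SampleRecord("S3", 1, {"host": "missing"}),
    ]
    usage = attribute_usage(records).set_index("attribute").samples
    assert usage["host"] == 2  # null token treated as missing
    assert usage["age"] == 1
    assert "env_package" not in usage
    raw = attribute_usage(records, count_null_as_present=True).set_index("attribute").samples
    assert raw["host"] == 3


def test_attribute_usage_matches_generator_truth(small_cohort):
    _, records, _, truth = small_cohort
    usage = attribute_usage(records, count_null_as_present=True).set_index("attribute").samples
    assert usage.to_dict() == truth.attribute_counts
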