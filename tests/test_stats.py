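"""Counting, shares, representation proportion/index, scaling, time series."""

from __future__ import annotations

import math
from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from geosample._util import round_half_away
from geosample.geo import attribute_geography
from geosample.records import SampleRecord
from geosample.stats import (
    display_transform,
    raw_index,
    representation_from_counts,
    representation_proportion,
    scale_indices,
    shares,
    tabulate,
    time_series,
)
from geosample.synthetic import SyntheticCohortConfig, generate_cohort


def _located_records(world):
    values = ["USA"] * 3 + ["missing", "Atlantis"] + ["China"] * 5
    records = [
        SampleRecord(f"S{i}", 408170, {"geo_loc_name": v}, release_date=date(2020, 1, 1))
        for i, v in enumerate(values)
    ]
    for r in records:
        r.body_site = "gut"
    attribute_geography(records, world)
    return records


def test_tabulate_country_brute_force(world):
    counts = tabulate(_located_records(world), "country").set_index("unit").samples
    assert counts.to_dict() == {"USA": 3, "CHN": 5, "Unknown": 2}


def test_tabulate_empty_input():
    assert tabulate([], "country").empty
    assert tabulate([], "body_site").empty


def test_body_site_countries_column_excludes_unknown(world):
    table = tabulate(_located_records(world), "body_site")
    row = table.set_index("body_site").loc["gut"]
    assert row.samples == 10  # unknown-location samples counted in Samples...
    assert row.countries == 2  # ...but not in Countries


def test_tabulation_counts_partition_records(world, body_sites):
    config = SyntheticCohortConfig(n_samples=800, seed=21)
    records, _, _ = generate_cohort(config, body_sites, world)
    for r in records:
        r.body_site = "gut"
    attribute_geography(records, world)
    for level in ("country", "region", "body_site", "body_site_x_country", "year_x_region"):
        assert int(tabulate(records, level).samples.sum()) == len(records)


def test_shares_columns():
    counts = pd.DataFrame({"unit": ["USA", "CHN", "Unknown"], "samples": [178960, 36162, 62118]})
    table = shares(counts, total_all=444829, total_known=382711).set_index("unit")
    assert round_half_away(100 * table.share_all["USA"], 1) == 40.2
    assert round_half_away(100 * table.share_all["CHN"], 1) == 8.1
    assert math.isnan(table.share_known["Unknown"])
    solo = shares(pd.DataFrame({"unit": ["X"], "samples": [7]}), 7, 7)
    assert float(solo.share_all.iloc[0]) == 1.0
    with pytest.raises(ValueError):
        shares(counts, 0, 1)


def test_representation_proportion_basics():
    assert representation_proportion(0.2, 0.2) == 1.0
    assert representation_proportion(0.5, 0.25) == 2.0
    with pytest.raises(ValueError):
        representation_proportion(0.0, 0.2)
    with pytest.raises(ValueError):
        representation_proportion(0.2, 0.0)


def test_raw_index_definition():
    assert raw_index(2.0, 1.0) == 2.0
    assert raw_index(1.0, 2.0) == -2.0
    assert raw_index(1.0, 1.0) == 1.0  # proportionality tie-break: positive branch
    assert math.isnan(raw_index(0.0, 5.0))
    with pytest.raises(ValueError):
        raw_index(-1.0, 2.0)


def test_raw_index_most_underrepresented_region():
    # Share of located samples vs share of world population for the most
    # underrepresented region, from the published per-region counts.
    sample_pct = 100 * 6685 / 382570
    pop_pct = 100 * 2014709 / 7794799
    assert round_half_away(raw_index(sample_pct, pop_pct), 1) == -14.8


@settings(derandomize=True, max_examples=200)
@given(
    a=st.floats(min_value=0.01, max_value=100.0),
    b=st.floats(min_value=0.01, max_value=100.0),
)
def test_raw_index_antisymmetry(a, b):
    # Holds for distinct shares; equality is the positive-branch tie-break.
    assume(a != b)
    assert raw_index(a, b) == pytest.approx(-raw_index(b, a))


def _rows(raw_values, samples=None):
    n = len(raw_values)
    return pd.DataFrame(
        {
            "unit": [f"U{i}" for i in range(n)],
            "samples": samples if samples is not None else [1000] * n,
            "raw_index": raw_values,
        }
    )


def test_scale_indices_hand_computed():
    out = scale_indices(_rows([2.0, 4.0, -3.0, -6.0])).set_index("unit").scaled_index
    assert out["U0"] == 50.0 and out["U1"] == 100.0
    assert out["U2"] == -50.0 and out["U3"] == -100.0


def test_scale_indices_degenerate_and_exclusions():
    single = scale_indices(_rows([3.7]))
    assert single.scaled_index.iloc[0] == 100.0
    out = scale_indices(_rows([2.0, 5.0, float("nan")], samples=[50, 1000, 0]))
    assert out.excluded.tolist() == ["excluded-low-n", None, "no-samples"]
    assert out.scaled_index.iloc[1] == 100.0


@settings(derandomize=True, max_examples=50)
@given(
    raws=st.lists(
        st.one_of(
            st.floats(min_value=1.0, max_value=1e3),
            st.floats(min_value=-1e3, max_value=-1.0),
        ),
        min_size=2,
        max_size=12,
    )
)
def test_scaling_preserves_sign_and_order(raws):
    out = scale_indices(_rows(raws))
    scaled = out.scaled_index.to_numpy()
    raw = np.asarray(raws)
    assert (np.sign(scaled) == np.sign(raw)).all()
    order = np.argsort(raw)
    assert (np.diff(scaled[order]) >= -1e-9).all()


def test_display_transform():
    assert display_transform(0.0) == 0.0
    assert display_transform(100.0) == pytest.approx(math.log10(101), abs=1e-12)
    grid = np.linspace(-100, 100, 1001)
    assert (np.diff(display_transform(grid)) > 0).all()


def test_representation_from_counts_handles_unknown_row():
    counts = pd.DataFrame(
        {
            "unit": ["A", "B", "Unknown"],
            "samples": [75, 25, 10],
            "population_thousands": [500.0, 500.0, np.nan],
        }
    )
    out = representation_from_counts(counts).set_index("unit")
    assert out.share_known["A"] == 0.75
    assert out.repr_proportion["A"] == pytest.approx(1.5)
    assert out.repr_proportion["B"] == pytest.approx(0.5)
    assert math.isnan(out.repr_proportion["Unknown"])
    assert out.raw_index["B"] == pytest.approx(-2.0)


def _dated(records, year=2020):
    for r in records:
        if r.release_date is None:
            r.release_date = date(year, 1, 1)
    return records


def test_time_series_single_and_two_year(world):
    records = _dated(_located_records(world))
    ts = time_series(records)
    assert (ts.samples_released == ts.cumulative_samples).all()

    extra = [
        SampleRecord(f"T{i}", 408170, {"geo_loc_name": "USA"}, release_date=date(2019, 5, 1))
        for i in range(4)
    ]
    attribute_geography(extra, world)
    ts2 = time_series(records + extra).set_index(["year", "region"])
    eu_na = "Europe and Northern America"
    assert (
        ts2.cumulative_samples[(2020, eu_na)]
        == ts2.samples_released[(2019, eu_na)] + ts2.samples_released[(2020, eu_na)]
    )
    shares_by_year = ts2.annual_share.groupby("year").sum()
    assert np.allclose(shares_by_year, 1.0)


def test_time_series_annual_counts_match_truth(world, body_sites, small_cohort):
    _, records, _, truth = small_cohort
    attribute_geography(records, world)
    ts = time_series(records)
    annual = ts.groupby("year").samples_released.sum()
    assert annual[annual > 0].to_dict() == truth.year_counts
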