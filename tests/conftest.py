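from __future__ import annotations

import pytest

from geosample.geo import WorldTable
from geosample.scope import BodySiteTable, HostLexicon
from geosample.synthetic import SyntheticCohortConfig, generate_cohort


@pytest.fixture(scope="session")
def world() -> WorldTable:
    return WorldTable.packaged()


@pytest.fixture(scope="session")
def body_sites() -> BodySiteTable:
    return BodySiteTable.packaged()


@pytest.fixture(scope="session")
def lexicon() -> HostLexicon:
    return HostLexicon.packaged()


@pytest.fixture()
def small_cohort(body_sites, world):
    """A 500-record default-parameter cohort with its ground truth."""
    config = SyntheticCohortConfig(n_samples=500, seed=3)
    records, runs, truth = generate_cohort(config, body_sites, world)
    return config, records, runs, truth
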