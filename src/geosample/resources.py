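"""Access to the packaged reference tables."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd


def packaged_path(name: str) -> Path:
    """Filesystem path of a packaged data file (tables ship uncompressed)."""
    return Path(str(resources.files("geosample.data").joinpath(name)))


def read_packaged_csv(name: str, **kwargs) -> pd.DataFrame:
    return pd.read_csv(packaged_path(name), comment="#", **kwargs)


def load_region_benchmark() -> dict[str, pd.DataFrame]:
    """Published 2021 repository-census counts by SDG region and LDC grouping.

    Returns the two blocks ("sdg_region", "ldc") as DataFrames with columns
    unit / samples / population_thousands; Unknown rows carry NaN population.
    """
    df = read_packaged_csv("repository_audit_2021_regions.csv")
    return {block: g.drop(columns="block").reset_index(drop=True) for block, g in df.groupby("block")}
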