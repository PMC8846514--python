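"""Representation statistics: counts, shares, proportions, signed index.

The central quantity is the *representation proportion* of a unit (country,
region, or country group):

    repr_proportion = (unit share of known-location samples)
                      / (unit share of world population)

so 1 means proportional representation. For mapping, a signed *raw index*
spreads the two sides of 1 apart: overrepresented units keep the ratio
(sample% / population%, ≥ 1); underrepresented units take the negative
reciprocal −(population% / sample%), i.e. the factor by which their sample
count would have to be multiplied to reach proportionality. After excluding
units with ``min_samples`` or fewer samples, positive and negative scores
are min–max scaled independently onto (0, 100] and [−100, 0) (x →
±100·|x|/max|x|), and a sign-preserving log10 display transform
(sign(x)·log10(1+|x|)) adds contrast for mid-range scores.

Known-location denominators: regional tables exclude Antarctica (no SDG
region, pooled into Unknown), country tables include it — which is why a
repository audit can report two slightly different Unknown totals.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from ._util import round_half_away
from .geo import WorldTable
from .records import UNKNOWN_REGION, GeoStatus, SampleRecord

__all__ = [
    "tabulate",
    "shares",
    "representation_proportion",
    "raw_index",
    "scale_indices",
    "display_transform",
    "representation_from_counts",
    "regional_representation",
    "country_representation",
    "time_series",
]

UNKNOWN = "Unknown"
#: Sentinel reasons in the ``excluded`` column of scaled index tables.
NO_SAMPLES = "no-samples"
EXCLUDED_LOW_N = "excluded-low-n"

_LEVELS = ("country", "region", "body_site", "body_site_x_country", "year_x_region")


def _country_of(rec: SampleRecord) -> str:
    if rec.geo is not None and rec.geo.status is GeoStatus.RESOLVED:
        return rec.geo.country_code  # type: ignore[return-value]
    return UNKNOWN


def _region_of(rec: SampleRecord) -> str:
    return rec.geo.region if rec.geo is not None else UNKNOWN_REGION


def tabulate(records: list[SampleRecord], level: str) -> pd.DataFrame:
    """Count samples at the requested level; counts partition the records.

    Levels: ``country`` / ``region`` (with an Unknown row), ``body_site``
    (with a Countries column counting distinct resolved countries — samples
    of unknown origin are inside Samples but never Countries),
    ``body_site_x_country`` and ``year_x_region`` cross-tabs.
    """
    if level not in _LEVELS:
        raise ValueError(f"unknown tabulation level {level!r}; expected one of {_LEVELS}")
    if not records:
        cols = {
            "country": ["unit", "samples"],
            "region": ["unit", "samples"],
            "body_site": ["body_site", "samples", "countries"],
            "body_site_x_country": ["body_site", "country", "samples"],
            "year_x_region": ["year", "region", "samples"],
        }[level]
        return pd.DataFrame(columns=cols)

    if level == "country":
        df = pd.DataFrame({"unit": [_country_of(r) for r in records]})
        out = df.value_counts("unit").rename("samples").reset_index()
    elif level == "region":
        df = pd.DataFrame({"unit": [_region_of(r) for r in records]})
        out = df.value_counts("unit").rename("samples").reset_index()
    elif level == "body_site":
        df = pd.DataFrame(
            {"body_site": [r.body_site for r in records], "country": [_country_of(r) for r in records]}
        )
        out = (
            df.groupby("body_site", dropna=False)
            .agg(
                samples=("country", "size"),
                countries=("country", lambda c: c[c != UNKNOWN].nunique()),
            )
            .reset_index()
            .sort_values("samples", ascending=False, kind="stable")
            .reset_index(drop=True)
        )
    elif level == "body_site_x_country":
        df = pd.DataFrame(
            {"body_site": [r.body_site for r in records], "country": [_country_of(r) for r in records]}
        )
        out = df.value_counts(["body_site", "country"]).rename("samples").reset_index()
    else:  # year_x_region
        df = pd.DataFrame(
            {
                "year": [r.release_date.year if r.release_date else -1 for r in records],
                "region": [_region_of(r) for r in records],
            }
        )
        out = df.value_counts(["year", "region"]).rename("samples").reset_index()
        out = out.sort_values(["year", "region"], kind="stable").reset_index(drop=True)

    if level in ("country", "region"):
        out = out.sort_values(["samples", "unit"], ascending=[False, True], kind="stable").reset_index(drop=True)
    assert int(out.samples.sum()) == len(records)
    return out


def shares(counts: pd.DataFrame, total_all: int, total_known: int, unknown_label: str = UNKNOWN) -> pd.DataFrame:
    """Attach share_all (of all samples) and share_known (of located samples).

    ``share_known`` is NaN for the Unknown row. Shares are kept in full
    precision; rounding happens only at the presentation layer.
    """
    if total_all <= 0 or total_known <= 0:
        raise ValueError("totals must be positive")
    out = counts.copy()
    out["share_all"] = out["samples"] / total_all
    known = out["unit"] != unknown_label
    out["share_known"] = np.where(known, out["samples"] / total_known, np.nan)
    return out


def representation_proportion(share_known: float, pop_share: float) -> float:
    """Unit share of known-location samples over its share of world population."""
    if pop_share <= 0:
        raise ValueError("pop_share must be positive")
    if share_known <= 0:
        raise ValueError("representation proportion is undefined for zero samples")
    return share_known / pop_share


def raw_index(sample_pct: float, pop_pct: float) -> float:
    """Signed representation index on percentage inputs.

    ratio if sample% ≥ pop% (overrepresented, ≥ 1), negative reciprocal
    −(pop%/sample%) if underrepresented. Zero samples → NaN (the no-samples
    sentinel, mapped separately on a choropleth). Exact proportionality sits
    on the positive branch with value 1.
    """
    if sample_pct < 0 or pop_pct <= 0:
        raise ValueError("sample_pct must be ≥ 0 and pop_pct > 0")
    if sample_pct == 0:
        return math.nan
    if sample_pct >= pop_pct:
        return sample_pct / pop_pct
    return -(pop_pct / sample_pct)


def scale_indices(rows: pd.DataFrame, min_samples: int = 50) -> pd.DataFrame:
    """Min–max scale raw indices onto ±100, per sign class.

    Units with ``samples ≤ min_samples`` (inclusive, "50 or fewer") are
    excluded before scaling; units with no samples keep the no-samples
    sentinel. Scaling maps x → 100·x/max(x) for positive scores and
    x → −100·|x|/max|x| for negative scores, so sign and within-sign ordering
    are preserved and the proportionality anchor stays at 0.
    """
    out = rows.copy()
    out["excluded"] = None
    out.loc[out["raw_index"].isna(), "excluded"] = NO_SAMPLES
    out.loc[out["excluded"].isna() & (out["samples"] <= min_samples), "excluded"] = EXCLUDED_LOW_N
    eligible = out["excluded"].isna()
    out["scaled_index"] = np.nan
    pos = eligible & (out["raw_index"] > 0)
    neg = eligible & (out["raw_index"] < 0)
    if pos.any():
        out.loc[pos, "scaled_index"] = 100.0 * out.loc[pos, "raw_index"] / out.loc[pos, "raw_index"].max()
    if neg.any():
        out.loc[neg, "scaled_index"] = -100.0 * out.loc[neg, "raw_index"].abs() / out.loc[neg, "raw_index"].abs().max()
    if not (pos.any() or neg.any()):
        import logging

        logging.getLogger(__name__).warning("scale_indices: every unit excluded; nothing to scale")
    return out


def display_transform(scaled_index):
    """Sign-preserving log10 map-color transform: sign(x)·log10(1+|x|).

    The +1 offset keeps 0 (proportionality) at 0 and the map monotone.
    Accepts scalars or arrays.
    """
    x = np.asarray(scaled_index, dtype=float)
    result = np.sign(x) * np.log10(1.0 + np.abs(x))
    return float(result) if np.isscalar(scaled_index) or result.ndim == 0 else result


def representation_from_counts(
    counts: pd.DataFrame,
    unit_col: str = "unit",
    samples_col: str = "samples",
    population_col: str = "population_thousands",
    total_all: int | None = None,
) -> pd.DataFrame:
    """Full representation table from (unit, samples, population) rows.

    Rows without a population (Unknown) contribute to ``share_all`` only;
    the known-location total is the sample sum over populated rows and the
    world population is the population sum. This is the arithmetic core used
    both on pipeline output and on published per-region count tables.
    """
    df = counts.rename(
        columns={unit_col: "unit", samples_col: "samples", population_col: "population"}
    ).copy()
    known = df["population"].notna()
    total_known = int(df.loc[known, "samples"].sum())
    world_pop = float(df.loc[known, "population"].sum())
    if total_all is None:
        total_all = int(df["samples"].sum())
    df["share_all"] = df["samples"] / total_all
    df["share_known"] = np.where(known, df["samples"] / total_known, np.nan)
    df["pop_share"] = df["population"] / world_pop
    df["repr_proportion"] = np.where(
        known & (df["samples"] > 0), df["share_known"] / df["pop_share"], np.nan
    )
    df["raw_index"] = [
        raw_index(100.0 * sk, 100.0 * ps) if (k and s > 0) else math.nan
        for sk, ps, k, s in zip(df["share_known"], df["pop_share"], known, df["samples"])
    ]
    return df


def _counts_with_population(records, world: WorldTable, level: str) -> pd.DataFrame:
    counts = tabulate(records, level)
    if level == "region":
        pops = world.countries.groupby("sdg_region").population_thousands.sum()
        counts["population_thousands"] = counts["unit"].map(pops)
        # Regions with zero samples still belong in the table.
        missing = sorted(set(pops.index) - set(counts["unit"]))
        if missing:
            extra = pd.DataFrame(
                {"unit": missing, "samples": 0, "population_thousands": [pops[m] for m in missing]}
            )
            counts = pd.concat([counts, extra], ignore_index=True)
    else:
        pops = world.countries.set_index("country_code").population_thousands
        counts["population_thousands"] = counts["unit"].map(pops)
        missing = sorted(set(pops.index) - set(counts["unit"]))
        if missing:
            extra = pd.DataFrame(
                {"unit": missing, "samples": 0, "population_thousands": [pops[m] for m in missing]}
            )
            counts = pd.concat([counts, extra], ignore_index=True)
    return counts


def regional_representation(records: list[SampleRecord], world: WorldTable) -> pd.DataFrame:
    """Per-SDG-region representation table (Antarctica pooled into Unknown)."""
    return representation_from_counts(_counts_with_population(records, world, "region"))


def country_representation(
    records: list[SampleRecord], world: WorldTable, min_samples: int = 50
) -> pd.DataFrame:
    """Per-country representation table with the scaled signed index."""
    df = representation_from_counts(_counts_with_population(records, world, "country"))
    return scale_indices(df, min_samples=min_samples)


def time_series(records: list[SampleRecord]) -> pd.DataFrame:
    """Annual and cumulative sample counts per region, with annual shares."""
    counts = tabulate(records, "year_x_region")
    if counts.empty:
        return pd.DataFrame(columns=["year", "region", "samples_released", "cumulative_samples", "annual_share"])
    counts = counts.rename(columns={"samples": "samples_released"})
    full = (
        counts.set_index(["year", "region"])
        .samples_released.unstack(fill_value=0)
        .sort_index()
        .stack()
        .rename("samples_released")
        .reset_index()
    )
    full["cumulative_samples"] = full.groupby("region").samples_released.cumsum()
    full["annual_share"] = full.samples_released / full.groupby("year").samples_released.transform("sum")
    return full


def percent(x: float, ndigits: int = 1) -> float:
    """Presentation rounding of a fraction to a percentage."""
    return round_half_away(100.0 * x, ndigits)
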