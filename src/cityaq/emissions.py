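"""Tiered emission inventory and scenario edits.

The inventory holds annual release rates (tons/year) for the five PM2.5
precursor/primary pollutants, resolved by source kind (area / point / line),
hierarchical tier (tier1 category / tier2 fuel / tier3 technology) and
region (ZCTA, borough).  Policy scenarios are expressed as edits — percent
or absolute tons/year changes scoped to a region and tier subtree, or an
AADT (traffic-volume) factor for line sources — applied immutably so the
baseline inventory is never touched.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, field_validator
from shapely.geometry import shape

POLLUTANTS = ("PM25", "NOX", "SO2", "VOC", "NH3")

log = logging.getLogger("cityaq")


@dataclass
class Inventory:
    """Sources as a DataFrame plus their geometries.

    ``df`` columns: source_id, kind, tier1, tier2, tier3, zcta_id, borough,
    aadt, and one tons/year column per pollutant.  ``geometries`` maps
    source_id to a shapely Polygon (area), a dict of stack parameters
    (point: x, y, stack_height, stack_diameter, exit_velocity, exit_temp),
    or a shapely LineString (line).
    """

    df: pd.DataFrame
    geometries: dict = field(default_factory=dict)

    def __post_init__(self):
        for p in POLLUTANTS:
            if p not in self.df.columns:
                self.df[p] = 0.0
            if (self.df[p] < 0).any():
                bad = self.df.loc[self.df[p] < 0, "source_id"].tolist()
                raise ValueError(f"negative {p} rate for sources {bad}")

    def copy(self) -> "Inventory":
        return Inventory(self.df.copy(), dict(self.geometries))

    def total(self, pollutant: str) -> float:
        return float(self.df[pollutant].sum())


def load_inventory(csv_path: str | Path, geojson_path: str | Path) -> Inventory:
    """Read the long-form inventory CSV (one row per source x pollutant) and
    the companion GeoJSON of source geometries."""
    long = pd.read_csv(csv_path, dtype={"zcta_id": str})
    wide = (
        long.pivot_table(
            index=["source_id", "kind", "tier1", "tier2", "tier3", "zcta_id", "borough"],
            columns="pollutant",
            values="rate_tpy",
            aggfunc="sum",
            fill_value=0.0,
        )
        .reindex(columns=list(POLLUTANTS), fill_value=0.0)
        .reset_index()
    )
    wide.columns.name = None
    if "aadt" in long.columns:
        aadt = long.groupby("source_id")["aadt"].first()
        wide["aadt"] = wide["source_id"].map(aadt).fillna(0.0)
    else:
        wide["aadt"] = 0.0
    geoms: dict = {}
    with open(geojson_path) as fh:
        fc = json.load(fh)
    for feat in fc["features"]:
        sid = feat["properties"]["source_id"]
        if feat["properties"].get("kind") == "point":
            geoms[sid] = dict(feat["properties"])
            x, y = feat["geometry"]["coordinates"]
            geoms[sid].update(x=x, y=y)
        else:
            geoms[sid] = shape(feat["geometry"])
    return Inventory(wide, geoms)


class ScenarioEdit(BaseModel):
    """One scoped emission change.

    ``change_mode='percent'`` scales matching rates by (1 + value/100);
    ``'absolute_tpy'`` adds value (floored at zero).  ``aadt_factor``
    multiplies all pollutant rates of matching line sources, the activity
    basis for road emissions.  Omitting ``pollutants`` targets all five.
    """

    scope: Literal["zcta", "borough", "city"] = "city"
    identifier: Optional[str] = None  # zcta_id or borough name; None for city
    tier1: Optional[str] = None
    tier2: Optional[str] = None
    tier3: Optional[str] = None
    pollutants: Optional[list[str]] = None
    change_mode: Literal["percent", "absolute_tpy"] = "percent"
    value: float = 0.0
    aadt_factor: Optional[float] = None

    @field_validator("value")
    @classmethod
    def _pct_floor(cls, v, info):
        return v

    def model_post_init(self, __context):
        if self.change_mode == "percent" and self.value < -100:
            raise ValueError("percent change below -100 is not meaningful")
        if self.pollutants:
            unknown = set(self.pollutants) - set(POLLUTANTS)
            if unknown:
                raise ValueError(f"unknown pollutants {unknown}")


def _match_mask(df: pd.DataFrame, edit: ScenarioEdit) -> pd.Series:
    m = pd.Series(True, index=df.index)
    if edit.scope == "zcta":
        m &= df["zcta_id"].astype(str) == str(edit.identifier)
    elif edit.scope == "borough":
        m &= df["borough"] == edit.identifier
    for level in ("tier1", "tier2", "tier3"):
        want = getattr(edit, level)
        if want is not None:
            m &= df[level].astype(str).str.startswith(want)
    return m


def apply_scenario(inventory: Inventory, edits: Sequence[ScenarioEdit]) -> Inventory:
    """Return a new inventory with all edits applied; the input is unchanged.

    Edits matching zero sources produce a warning (recorded in the run log),
    not an error — a no-op edit is a plausible user exploration.
    """
    inv = inventory.copy()
    df = inv.df
    for edit in edits:
        mask = _match_mask(df, edit)
        if not mask.any():
            msg = f"scenario edit matched no sources: {edit.model_dump(exclude_none=True)}"
            warnings.warn(msg)
            log.warning(msg)
            continue
        cols = list(edit.pollutants) if edit.pollutants else list(POLLUTANTS)
        if edit.aadt_factor is not None:
            line = mask & (df["kind"] == "line")
            df.loc[line, list(POLLUTANTS)] = (
                df.loc[line, list(POLLUTANTS)] * edit.aadt_factor
            )
            if "aadt" in df.columns:
                df.loc[line, "aadt"] *= edit.aadt_factor
        if edit.value != 0.0:
            if edit.change_mode == "percent":
                df.loc[mask, cols] = df.loc[mask, cols] * (1.0 + edit.value / 100.0)
            else:
                df.loc[mask, cols] = (df.loc[mask, cols] + edit.value).clip(lower=0.0)
    return inv


def load_scenario(path: str | Path) -> list[ScenarioEdit]:
    with open(path) as fh:
        doc = json.load(fh)
    return [ScenarioEdit.model_validate(e) for e in doc["edits"]]


def load_surrogates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"zcta_id": str})
    validate_surrogates(df)
    return df


def validate_surrogates(surrogates: pd.DataFrame) -> None:
    sums = surrogates.groupby(["county", "tier1"])["weight"].sum()
    bad = sums[(sums - 1.0).abs() > 1e-6]
    if len(bad):
        raise ValueError(f"surrogate weights do not sum to 1: {bad.to_dict()}")


def allocate_county_to_zcta(
    county_totals: pd.DataFrame, surrogates: pd.DataFrame
) -> pd.DataFrame:
    """Distribute county tons/year to ZCTAs with spatial-surrogate weights.

    ``county_totals`` columns: county, tier1, pollutant, total_tpy.
    Mass is conserved exactly per (county, tier1, pollutant).
    """
    validate_surrogates(surrogates)
    have = set(map(tuple, surrogates[["county", "tier1"]].drop_duplicates().values))
    need = set(map(tuple, county_totals[["county", "tier1"]].drop_duplicates().values))
    missing = need - have
    if missing:
        raise KeyError(f"no surrogate rows for (county, tier1): {sorted(missing)}")
    merged = county_totals.merge(surrogates, on=["county", "tier1"])
    merged["rate_tpy"] = merged["total_tpy"] * merged["weight"]
    return merged[["county", "tier1", "pollutant", "zcta_id", "rate_tpy"]]


def voc_to_soa(inventory: Inventory, soa_yield: Mapping[str, float]) -> pd.Series:
    """SOA-equivalent emission rates (tons/year) per source.

    Anthropogenic VOC emissions are scaled by a tier1-specific mass yield
    and later dispersed like a primary pollutant — the reduced-form stand-in
    for secondary-organic-aerosol chemistry.
    """
    tiers = inventory.df["tier1"].unique()
    missing = [t for t in tiers if t not in soa_yield]
    if missing:
        raise KeyError(f"no SOA yield for tier1 categories: {missing}")
    y = inventory.df["tier1"].map(soa_yield).astype(float)
    if ((y < 0) | (y > 1)).any():
        raise ValueError("SOA yields must lie in [0, 1]")
    out = inventory.df["VOC"] * y
    out.index = inventory.df["source_id"]
    return out
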