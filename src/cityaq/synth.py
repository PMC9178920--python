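"""Synthetic-city input generator.

Builds a fully self-contained toy city on disk — ZCTA polygons, a tiered
area/point/line emission inventory, an hourly two-regime wind year, census
population, ZCTA-varying baseline health rates, county-level transported
background, surrogate weights and a synthetic monitor table — so every stage
of the modelling chain is testable without external downloads.

The default world is a 6 x 6 grid of 1 km^2 ZCTAs with a "Manhattan-like"
high-density western stripe (flagged for the roughness adjustment), two
deliberately small polygons that exercise the single-receptor area rule,
area sources in every ZCTA across several tier categories (with a fuel
tier2 split so fuel-switch scenarios have something to zero out), two
power-generation stacks and two crossing arterial roads with AADT.  Wind
hours are drawn from a 70/30 mixture of two regimes (SW 5 m/s class D,
NW 3 m/s class B), the oracle for representative-hour weight recovery.
Baseline asthma rates are highest in the northeast quadrant so health
benefits concentrate where baseline incidence is high, as they do in real
cities.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from shapely.geometry import LineString, Polygon, mapping

from .config import RunConfig
from .health import ENDPOINTS

TIER1_VOCABULARY = (
    "fuel_combustion_residential",
    "fuel_combustion_commercial",
    "commercial_cooking",
    "industrial_processes",
    "solvent_use",
    "road_dust",
    "waste_disposal",
    "nonroad_equipment",
    "power_generation",
    "onroad_mobile",
)


class SynthSpec(BaseModel):
    """Parameters of the generated toy city."""

    nx: int = 6
    ny: int = 6
    cell_m: float = 1000.0
    pop_density_low: float = 2_000.0  # people per km^2
    pop_density_high: float = 40_000.0
    area_pm25_tpy: tuple[float, float] = (0.5, 6.0)  # tons/year per km^2 per tier
    n_point: int = 2
    n_line: int = 2
    n_hours: int = 8760
    regime_split: float = 0.7  # share of hours in regime 1
    seed: int = 0

    def model_post_init(self, __context):
        if self.nx < 2 or self.ny < 2:
            raise ValueError("grid must be at least 2 x 2")


def _boroughs(spec: SynthSpec) -> list[str]:
    """Column -> borough mapping; westernmost column is the flagged stripe."""
    names = ["Manhattan", "Bronx", "Brooklyn", "Queens", "Richmond"]
    return [names[min(i * len(names) // spec.nx, len(names) - 1)] for i in range(spec.nx)]


def generate(spec: SynthSpec, out_dir: str | Path) -> RunConfig:
    """Write every input file the pipeline consumes; returns the RunConfig.

    Byte-identical output for a fixed spec (all randomness flows from
    ``spec.seed``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    boroughs = _boroughs(spec)
    c = spec.cell_m

    # --- ZCTA polygons -----------------------------------------------------
    features, zrows = [], []
    for i in range(spec.nx):
        for j in range(spec.ny):
            zcta = f"Z{i}{j}"
            x0, y0 = i * c, j * c
            if (i, j) == (1, 1):
                # mid-sized block: ~323k sq ft, single-receptor band
                poly = Polygon(
                    [(x0, y0), (x0 + 200, y0), (x0 + 200, y0 + 150), (x0, y0 + 150)]
                )
            elif (i, j) == (2, 1):
                # tiny block: < 100k sq ft, still a single receptor
                poly = Polygon([(x0, y0), (x0 + 80, y0), (x0 + 80, y0 + 80), (x0, y0 + 80)])
            else:
                poly = Polygon([(x0, y0), (x0 + c, y0), (x0 + c, y0 + c), (x0, y0 + c)])
            borough = boroughs[i]
            dens = (
                spec.pop_density_high
                if borough == "Manhattan"
                else rng.uniform(spec.pop_density_low, spec.pop_density_high / 4)
            )
            pop = int(dens * poly.area / 1e6)
            features.append(
                {
                    "type": "Feature",
                    "geometry": mapping(poly),
                    "properties": {"zcta_id": zcta, "borough": borough, "population": pop},
                }
            )
            zrows.append({"zcta_id": zcta, "borough": borough, "population": pop, "poly": poly})
    with open(out / "zcta.geojson", "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
    zdf = pd.DataFrame(zrows)

    # --- inventory ---------------------------------------------------------
    inv_rows, geo_feats = [], []
    area_tiers = [
        ("commercial_cooking", "charbroiler", {"PM25": 1.0, "VOC": 0.6}),
        ("fuel_combustion_residential", None, {"PM25": 0.6, "SO2": 0.5, "NOX": 0.8, "NH3": 0.05}),
    ]
    for r in zrows:
        for tier1, tier2, mix in area_tiers:
            if tier2 is None:
                # alternate heating fuel so a fuel-switch edit has targets
                tier2 = "no4_oil" if (r["borough"] in ("Manhattan", "Bronx")) else "natural_gas"
            sid = f"A-{r['zcta_id']}-{tier1[:4]}"
            # rates are emission densities times polygon area, so small
            # blocks emit proportionally less than full-size ZCTAs
            base = rng.uniform(*spec.area_pm25_tpy) * r["poly"].area / 1e6
            if r["borough"] == "Manhattan":
                base *= 2.0  # dense stripe emits more
            inv_rows.extend(
                {
                    "source_id": sid,
                    "kind": "area",
                    "tier1": tier1,
                    "tier2": tier2,
                    "tier3": "default",
                    "pollutant": pol,
                    "rate_tpy": round(base * frac, 4),
                    "zcta_id": r["zcta_id"],
                    "borough": r["borough"],
                    "aadt": 0.0,
                }
                for pol, frac in mix.items()
            )
            geo_feats.append(
                {
                    "type": "Feature",
                    "geometry": mapping(r["poly"]),
                    "properties": {"source_id": sid, "kind": "area"},
                }
            )
    # point stacks (power generation) in two random large cells
    big = zdf[~zdf["zcta_id"].isin(["Z11", "Z21"])].reset_index(drop=True)
    for p in range(spec.n_point):
        row = big.iloc[int(rng.integers(len(big)))]
        cx, cy = row["poly"].centroid.x, row["poly"].centroid.y
        sid = f"P-{p}"
        inv_rows.extend(
            {
                "source_id": sid,
                "kind": "point",
                "tier1": "power_generation",
                "tier2": "natural_gas",
                "tier3": "turbine",
                "pollutant": pol,
                "rate_tpy": rate,
                "zcta_id": row["zcta_id"],
                "borough": row["borough"],
                "aadt": 0.0,
            }
            for pol, rate in {"PM25": 40.0, "NOX": 300.0, "SO2": 80.0}.items()
        )
        geo_feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [cx, cy]},
                "properties": {
                    "source_id": sid,
                    "kind": "point",
                    "stack_height": 60.0,
                    "stack_diameter": 3.0,
                    "exit_velocity": 15.0,
                    "exit_temp": 420.0,
                },
            }
        )
    # arterial roads: one W-E, one S-N, crossing mid-city
    W, H = spec.nx * c, spec.ny * c
    roads = [
        LineString([(0, H * 0.45), (W, H * 0.45)]),
        LineString([(W * 0.55, 0), (W * 0.55, H)]),
    ][: spec.n_line]
    for li, road in enumerate(roads):
        sid = f"L-{li}"
        # register the road under the ZCTA at its midpoint
        mid = road.interpolate(0.5, normalized=True)
        host = zdf.iloc[int(min(mid.x // c, spec.nx - 1) * spec.ny + min(mid.y // c, spec.ny - 1))]
        inv_rows.extend(
            {
                "source_id": sid,
                "kind": "line",
                "tier1": "onroad_mobile",
                "tier2": "gasoline",
                "tier3": "light_duty",
                "pollutant": pol,
                "rate_tpy": rate,
                "zcta_id": host["zcta_id"],
                "borough": host["borough"],
                "aadt": 80_000.0,
            }
            for pol, rate in {"PM25": 25.0, "NOX": 400.0, "VOC": 120.0}.items()
        )
        geo_feats.append(
            {
                "type": "Feature",
                "geometry": mapping(road),
                "properties": {"source_id": sid, "kind": "line"},
            }
        )
    pd.DataFrame(inv_rows).to_csv(out / "inventory.csv", index=False)
    with open(out / "source_geometries.geojson", "w") as fh:
        json.dump({"type": "FeatureCollection", "features": geo_feats}, fh)

    # --- meteorology: two-regime wind year ---------------------------------
    n1 = int(round(spec.regime_split * spec.n_hours))
    regime = np.concatenate([np.zeros(n1, int), np.ones(spec.n_hours - n1, int)])
    rng.shuffle(regime)
    wd = np.where(regime == 0, 225.0, 315.0) + rng.normal(0, 8, spec.n_hours)
    ws = np.where(regime == 0, 5.0, 3.0) * rng.lognormal(0, 0.12, spec.n_hours)
    stab = np.where(regime == 0, "D", "B")
    mh = np.where(regime == 0, 800.0, 1200.0) * rng.lognormal(0, 0.1, spec.n_hours)
    pd.DataFrame(
        {
            "datetime": pd.date_range("2016-01-01", periods=spec.n_hours, freq="h"),
            "wind_speed_ms": ws.round(3),
            "wind_dir_deg": np.mod(wd, 360).round(2),
            "stability_class": stab,
            "mixing_height_m": mh.round(1),
        }
    ).to_csv(out / "met.csv", index=False)

    # --- population & baseline health rates --------------------------------
    zdf[["zcta_id", "borough", "population"]].to_csv(out / "population.csv", index=False)
    base_rows = []
    rate_scale = {
        "adult_mortality": 0.008,
        "infant_mortality": 0.004,
        "nonfatal_heart_attacks": 0.004,
        "respiratory_hospitalizations": 0.012,
        "cardiovascular_hospitalizations": 0.010,
        "acute_bronchitis": 0.04,
        "upper_respiratory_symptoms": 0.3,
        "lower_respiratory_symptoms": 0.2,
        "asthma_ed_visits": 0.010,
        "asthma_exacerbations": 0.15,
        "minor_restricted_activity_days": 2.0,
        "work_loss_days": 0.9,
    }
    age_frac = {"infant_mortality": 0.012, "acute_bronchitis": 0.06, "adult_mortality": 0.65}
    for r in zrows:
        i, j = int(r["zcta_id"][1]), int(r["zcta_id"][2])
        # asthma burden gradient: highest in the northeast quadrant
        asthma_mult = 1.0 + 2.0 * (i / (spec.nx - 1)) * (j / (spec.ny - 1))
        for ep in ENDPOINTS:
            mult = asthma_mult if ep.startswith("asthma") else rng.uniform(0.8, 1.2)
            base_rows.append(
                {
                    "zcta_id": r["zcta_id"],
                    "endpoint": ep,
                    "rate": round(rate_scale[ep] * mult, 6),
                    "population": int(r["population"] * age_frac.get(ep, 0.9)),
                }
            )
    pd.DataFrame(base_rows).to_csv(out / "baselines.csv", index=False)

    # --- transported background and secondary-PM coefficients --------------
    counties = sorted(set(boroughs))
    col_of = {b: i for i, b in enumerate(_boroughs(spec)) if b not in ()}
    trans_rows, coef_rows = [], []
    for cty in counties:
        west = 1.0 - col_of.get(cty, 0) / max(spec.nx - 1, 1)  # decays eastward
        trans_rows.append(
            {
                "county": cty,
                "primary_transported": round(1.2 + 1.0 * west, 3),
                "soa_transported": round(0.3 + 0.3 * west, 3),
            }
        )
        for comp, prec, coef in (
            ("nh4so4", "SO2", 18.0),
            ("nh4no3", "NOX", 3.0),
            ("nh4no3", "NH3", 6.0),
        ):
            coef_rows.append(
                {"county": cty, "component": comp, "precursor": prec, "coef_ug_per_kty": coef}
            )
    pd.DataFrame(trans_rows).to_csv(out / "transported.csv", index=False)
    pd.DataFrame(coef_rows).to_csv(out / "secondary_coefficients.csv", index=False)
    zdf.assign(county=zdf["borough"])[["zcta_id", "county"]].to_csv(
        out / "zcta_county.csv", index=False
    )

    # --- surrogate weights (population shares per county-tier) -------------
    surr_rows = []
    for cty, grp in zdf.groupby("borough"):
        w = grp["population"] / grp["population"].sum()
        for tier1 in TIER1_VOCABULARY:
            for zcta, wi in zip(grp["zcta_id"], w):
                surr_rows.append(
                    {"county": cty, "tier1": tier1, "zcta_id": zcta, "weight": round(wi, 10)}
                )
    surr = pd.DataFrame(surr_rows)
    # force exact unit sums despite rounding
    surr["weight"] = surr.groupby(["county", "tier1"])["weight"].transform(lambda s: s / s.sum())
    surr.to_csv(out / "surrogates.csv", index=False)

    # --- synthetic monitor pairs (labelled synthetic; not NYC data) --------
    mon = []
    for k in range(8):
        obs = rng.uniform(6.0, 9.0)
        mod = obs * rng.lognormal(0, 0.12)
        mon.append(
            {
                "network": "AQS" if k < 6 else "LOCAL",
                "site": f"synthetic-site-{k}",
                "zcta_id": zdf["zcta_id"].iloc[int(rng.integers(len(zdf)))],
                "observed": round(obs, 2),
                "modeled": round(mod, 2),
            }
        )
    pd.DataFrame(mon).to_csv(out / "monitor_pairs.csv", index=False)

    cfg = RunConfig(
        polygons=str(out / "zcta.geojson"),
        inventory=str(out / "inventory.csv"),
        geometries=str(out / "source_geometries.geojson"),
        met=str(out / "met.csv"),
        population=str(out / "population.csv"),
        baselines=str(out / "baselines.csv"),
        transported=str(out / "transported.csv"),
        surrogates=str(out / "surrogates.csv"),
        secondary_coefficients=str(out / "secondary_coefficients.csv"),
        zcta_county=str(out / "zcta_county.csv"),
        seed=spec.seed,
        out_dir=str(out / "results"),
    )
    with open(out / "config.json", "w") as fh:
        json.dump(cfg.model_dump(), fh, indent=2)
    return cfg
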