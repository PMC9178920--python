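"""End-to-end orchestration: baseline run, scenario deltas, reports.

A baseline run builds the receptor network, reduces the met year to
weighted representative hours, evaluates the unit-emission transfer matrix
once, and assembles total PM2.5.  Because every local component is linear
in emission rates, a scenario run re-weights the cached transfer matrix
with the edited rate vector — no plume kernel is ever re-evaluated — which
is what makes iterative policy screening fast.

Delta fields (baseline minus scenario) are aggregated receptor -> ZCTA ->
borough -> city and fed to the health module; reports carry the
city-average delta (mean +/- sd, min-max across ZCTAs), per-endpoint
avoided events with low/high bounds where paired, and dollars.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import mapping as geo_mapping

from . import __version__
from .config import RunConfig
from .dispersion import (
    ALL_COMPONENTS,
    ConcentrationField,
    annual_average,
    assemble_total_pm,
    secondary_inorganic,
    transfer_matrix,
)
from .emissions import Inventory, ScenarioEdit, apply_scenario, load_inventory, voc_to_soa
from .geometry import (
    Receptor,
    ZctaPolygon,
    aggregate_receptors_to_zcta,
    build_receptor_network,
    load_zcta_polygons,
    receptors_to_frame,
)
from .meteorology import (
    RepresentativeMetSet,
    load_met_csv,
    select_representative_hours,
)


@dataclass
class Baseline:
    """Everything a scenario run reuses."""

    config: RunConfig
    polygons: list[ZctaPolygon]
    receptors: list[Receptor]
    repset: RepresentativeMetSet
    inventory: Inventory
    tmatrix: pd.DataFrame
    field: ConcentrationField
    zcta_county: dict[str, str]
    transported: pd.DataFrame
    soa_yield: dict[str, float]
    manifest: dict = field(default_factory=dict)


@dataclass
class ScenarioReport:
    zcta_delta: pd.DataFrame  # per-ZCTA component deltas + total
    hia: pd.DataFrame  # per-ZCTA per-endpoint per-variant results
    city: pd.DataFrame  # per-endpoint city totals
    borough: pd.DataFrame  # borough rollups of delta and dollars
    summary: dict  # mean/sd/min/max delta, dollars low/high

    def validate(self) -> None:
        s = self.summary
        if not (s["delta_min"] - 1e-12 <= s["delta_mean"] <= s["delta_max"] + 1e-12):
            raise AssertionError("delta summary ordering violated")


def _receptor_roughness(
    receptors: Sequence[Receptor], zcta_borough: Mapping[str, str], cfg: RunConfig
) -> np.ndarray:
    met = cfg.met_options
    base = met.roughness_default_m
    return np.array(
        [
            base + (met.roughness_delta_m if zcta_borough[r.zcta_id] in met.adjusted_boroughs else 0.0)
            for r in receptors
        ]
    )


def _county_precursors(inv: Inventory, zcta_county: Mapping[str, str]) -> pd.DataFrame:
    df = inv.df.copy()
    df["county"] = df["zcta_id"].map(zcta_county)
    long = df.melt(
        id_vars=["county"],
        value_vars=["SO2", "NOX", "NH3"],
        var_name="pollutant",
        value_name="rate",
    )
    out = long.groupby(["county", "pollutant"], as_index=False)["rate"].sum()
    return out.rename(columns={"rate": "total_tpy"})


def _assemble(bl_cfg: RunConfig, inv, receptors, repset, tmatrix, zcta_county, transported,
              secondary_coefs, soa_yield) -> ConcentrationField:
    soa = voc_to_soa(inv, soa_yield)
    local = annual_average(inv, receptors, repset, bl_cfg.dispersion, soa, tmatrix=tmatrix)
    secondary = None
    if secondary_coefs is not None:
        secondary = secondary_inorganic(_county_precursors(inv, zcta_county), secondary_coefs)
    return assemble_total_pm(local, receptors, zcta_county, transported, secondary)


def run_baseline(config: RunConfig) -> Baseline:
    """Full baseline chain; deterministic for a fixed config (incl. seed)."""
    for name in ("polygons", "inventory", "geometries", "met", "baselines", "transported"):
        p = getattr(config, name)
        if not Path(p).exists():
            raise FileNotFoundError(f"missing input file for '{name}': {p}")
    polygons = load_zcta_polygons(config.polygons)
    rcfg = config.receptors.model_copy(update={"seed": config.receptors.seed + config.seed})
    receptors = build_receptor_network(polygons, rcfg)
    hours = load_met_csv(config.met, roughness=config.met_options.roughness_default_m)
    repset = select_representative_hours(
        hours, config.met_options.n_rep, seed=config.met_options.seed + config.seed,
        cfg=config.met_options,
    )
    inv = load_inventory(config.inventory, config.geometries)
    zcta_borough = {zp.zcta_id: zp.borough for zp in polygons}
    if config.zcta_county:
        zc = pd.read_csv(config.zcta_county, dtype=str)
        zcta_county = dict(zip(zc["zcta_id"], zc["county"]))
    else:
        zcta_county = zcta_borough
    roughness = _receptor_roughness(receptors, zcta_borough, config)
    tmatrix = transfer_matrix(inv, receptors, repset, config.dispersion, roughness)
    transported = pd.read_csv(config.transported)
    secondary_coefs = (
        pd.read_csv(config.secondary_coefficients) if config.secondary_coefficients else None
    )
    soa_yield = {t: config.health.soa_yield_default for t in inv.df["tier1"].unique()}
    fld = _assemble(config, inv, receptors, repset, tmatrix, zcta_county, transported,
                    secondary_coefs, soa_yield)
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package_version": __version__,
        "python": platform.python_version(),
        "n_receptors": len(receptors),
        "n_rep_hours": len(repset.hours),
        "n_sources": len(inv.df),
    }
    return Baseline(
        config, polygons, receptors, repset, inv, tmatrix, fld,
        dict(zcta_county), transported, soa_yield, manifest,
    )


def run_scenario(baseline: Baseline, edits: Sequence[ScenarioEdit]) -> ScenarioReport:
    """Apply edits, re-weight the cached transfer matrix, difference against
    baseline, aggregate, and run the health impact assessment."""
    from .health import load_cr_functions, load_unit_values, overall_benefits, run_hia

    cfg = baseline.config
    inv2 = apply_scenario(baseline.inventory, edits)
    secondary_coefs = (
        pd.read_csv(cfg.secondary_coefficients) if cfg.secondary_coefficients else None
    )
    fld2 = _assemble(cfg, inv2, baseline.receptors, baseline.repset, baseline.tmatrix,
                     baseline.zcta_county, baseline.transported, secondary_coefs,
                     baseline.soa_yield)
    delta = baseline.field.df[list(ALL_COMPONENTS) + ["total"]] - fld2.df[
        list(ALL_COMPONENTS) + ["total"]
    ]
    # receptor -> ZCTA (unweighted mean over receptors of all parts)
    zcta_delta = pd.DataFrame(
        {
            col: aggregate_receptors_to_zcta(delta[col].to_dict(), baseline.receptors)
            for col in delta.columns
        }
    )
    zcta_delta.index.name = "zcta_id"
    zcta_delta = zcta_delta.reset_index()

    baselines = pd.read_csv(cfg.baselines, dtype={"zcta_id": str})
    cr = load_cr_functions(cfg.health.cr_functions)
    uv = load_unit_values(cfg.health.unit_values)
    hia, city = run_hia(
        dict(zip(zcta_delta["zcta_id"], zcta_delta["total"])), baselines, cr, uv
    )
    borough_of = {zp.zcta_id: zp.borough for zp in baseline.polygons}
    hb = hia.assign(borough=hia["zcta_id"].map(borough_of))
    borough = (
        hb.groupby("borough")[["avoided_events", "dollars"]].sum().reset_index()
    )
    d = zcta_delta["total"]
    summary = {
        "delta_mean": float(d.mean()),
        "delta_sd": float(d.std(ddof=0)),
        "delta_min": float(d.min()),
        "delta_max": float(d.max()),
        "n_zcta": int(len(d)),
        **overall_benefits(city),
    }
    report = ScenarioReport(zcta_delta, hia, city, borough, summary)
    report.validate()
    return report


def write_outputs(report: ScenarioReport, baseline: Baseline, out_dir: str | Path) -> dict:
    """Write the standard output set; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "zcta_delta": out / "zcta_delta.csv",
        "zcta_hia": out / "zcta_hia.csv",
        "city_summary": out / "city_summary.csv",
        "zcta_delta_geojson": out / "zcta_delta.geojson",
        "receptors": out / "receptors.csv",
        "manifest": out / "manifest.json",
    }
    report.zcta_delta.to_csv(paths["zcta_delta"], index=False)
    report.hia.to_csv(paths["zcta_hia"], index=False)
    report.city.to_csv(paths["city_summary"], index=False)
    receptors_to_frame(baseline.receptors).to_csv(paths["receptors"], index=False)
    dmap = report.zcta_delta.set_index("zcta_id")
    ev = (
        report.hia.groupby("zcta_id")["avoided_events"].sum()
        if len(report.hia)
        else pd.Series(dtype=float)
    )
    feats = []
    for zp in baseline.polygons:
        if zp.zcta_id not in dmap.index:
            continue
        props = {
            "zcta_id": zp.zcta_id,
            "borough": zp.borough,
            "delta_total": float(dmap.loc[zp.zcta_id, "total"]),
            "avoided_events": float(ev.get(zp.zcta_id, 0.0)),
        }
        feats.append(
            {"type": "Feature", "geometry": geo_mapping(zp.polygon), "properties": props}
        )
    with open(paths["zcta_delta_geojson"], "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
    with open(paths["manifest"], "w") as fh:
        json.dump({**baseline.manifest, "summary": report.summary}, fh, indent=2)
    return {k: str(v) for k, v in paths.items()}


def plot_choropleth(
    report: ScenarioReport, baseline: Baseline, path: str | Path, column: str = "total"
) -> None:
    """Optional map of the per-ZCTA delta field."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import PatchCollection
    from matplotlib.patches import Polygon as MplPolygon

    dmap = report.zcta_delta.set_index("zcta_id")[column]
    patches, vals = [], []
    for zp in baseline.polygons:
        patches.append(MplPolygon(np.asarray(zp.polygon.exterior.coords)))
        vals.append(dmap.get(zp.zcta_id, 0.0))
    fig, ax = plt.subplots(figsize=(6, 6))
    pc = PatchCollection(patches, cmap="viridis")
    pc.set_array(np.asarray(vals))
    ax.add_collection(pc)
    ax.autoscale()
    ax.set_aspect("equal")
    fig.colorbar(pc, ax=ax, label=f"delta {column} (ug/m3)")
    fig.savefig(path, dpi=120)
    plt.close(fig)
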