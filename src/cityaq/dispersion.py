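"""Reduced-form Gaussian-plume dispersion and total-PM2.5 assembly.

Local primary PM2.5 (and SOA-equivalent emissions, dispersed identically)
is computed at each receptor as a weighted sum of steady-state Gaussian
plume kernels over the representative meteorological hours:

    C_annual(r) = sum_h w_h * sum_s kernel(s, r, h)

with Pasquill-Gifford sigma curves (urban default, rural selectable),
image-source ground reflection, a mixing-lid well-mixed limit, Briggs plume
rise for stacks, and a multiplicative sigma_z roughness enhancement.  These
are standard screening-model choices — no building downwash, no deposition,
constant annual emissions.

Everything local is strictly linear in emission rates, so the whole local
field collapses to a transfer matrix T[receptor, source] of ug/m3 per
ton/year: a scenario run is a matrix re-weighting, not a re-dispersion.

Secondary inorganic PM (ammonium sulfate from SO2, ammonium nitrate from
NOx + NH3) uses configured linear county-level coefficients; transported
primary PM and transported SOA enter as county-level input tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon

from .config import GRAMS_PER_TON, SECONDS_PER_YEAR, DispersionConfig
from .emissions import Inventory
from .geometry import Receptor
from .meteorology import MetHour, RepresentativeMetSet

log = logging.getLogger("cityaq")

G_PER_M3_TO_UG = 1.0e6
TPY_TO_GPS = GRAMS_PER_TON / SECONDS_PER_YEAR  # tons/year -> g/s

LOCAL_COMPONENTS = ("primary_local_area", "primary_local_point", "primary_local_line", "soa_local")
ALL_COMPONENTS = (
    "primary_local_area",
    "primary_local_point",
    "primary_local_line",
    "primary_transported",
    "nh4so4",
    "nh4no3",
    "soa_local",
    "soa_transported",
)


# ---------------------------------------------------------------------------
# Pasquill-Gifford dispersion coefficients (Briggs interpolation formulas)
# ---------------------------------------------------------------------------

_RURAL = {
    "A": (0.22, 1e-4, -0.5, 0.20, 0.0, 0.0),
    "B": (0.16, 1e-4, -0.5, 0.12, 0.0, 0.0),
    "C": (0.11, 1e-4, -0.5, 0.08, 2e-4, -0.5),
    "D": (0.08, 1e-4, -0.5, 0.06, 1.5e-3, -0.5),
    "E": (0.06, 1e-4, -0.5, 0.03, 3e-4, -1.0),
    "F": (0.04, 1e-4, -0.5, 0.016, 3e-4, -1.0),
}
_URBAN = {
    "A": (0.32, 4e-4, -0.5, 0.24, 1e-3, 0.5),
    "B": (0.32, 4e-4, -0.5, 0.24, 1e-3, 0.5),
    "C": (0.22, 4e-4, -0.5, 0.20, 0.0, 0.0),
    "D": (0.16, 4e-4, -0.5, 0.14, 3e-4, -0.5),
    "E": (0.11, 4e-4, -0.5, 0.08, 1.5e-4, -0.5),
    "F": (0.11, 4e-4, -0.5, 0.08, 1.5e-4, -0.5),
}


def sigma_yz(
    x: np.ndarray,
    stability: str,
    scheme: str = "urban",
    roughness: float | np.ndarray = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Horizontal/vertical plume spread (m) at downwind distance x (m).

    The roughness length enhances sigma_z multiplicatively by
    ``1 + 0.2 ln(z0 / 0.1 m)`` — a screening-grade surrogate for surface
    scaling, configurable via the met/dispersion config.
    """
    table = _URBAN if scheme == "urban" else _RURAL
    ay, by, py, az, bz, pz = table[stability]
    x = np.asarray(x, dtype=float)
    sy = ay * x * np.power(1.0 + by * x, py) if by else ay * x
    sz = az * x * np.power(1.0 + bz * x, pz) if bz else az * x
    sz = sz * (1.0 + 0.2 * np.log(np.asarray(roughness) / 0.1))
    return sy, sz


def briggs_plume_rise(
    stack_height: float,
    stack_diameter: float,
    exit_velocity: float,
    exit_temp: float,
    u: float,
    ambient_temp: float = 293.0,
) -> float:
    """Final plume rise (m) above the stack top: max of Briggs buoyancy and
    momentum rise for neutral/unstable conditions."""
    g = 9.80665
    dT = max(exit_temp - ambient_temp, 0.0)
    fb = g * exit_velocity * stack_diameter**2 * dT / (4.0 * max(exit_temp, 1.0))
    rise_m = 3.0 * stack_diameter * exit_velocity / u
    if fb <= 0:
        return rise_m
    rise_b = (21.425 * fb**0.75 / u) if fb < 55.0 else (38.71 * fb**0.6 / u)
    return max(rise_m, rise_b)


# ---------------------------------------------------------------------------
# Plume kernels (all vectorised over receptors)
# ---------------------------------------------------------------------------


def _wind_frame(
    sx: float, sy_: float, rx: np.ndarray, ry: np.ndarray, wind_dir: float
) -> tuple[np.ndarray, np.ndarray]:
    """Downwind / crosswind receptor offsets (m) relative to a source.

    ``wind_dir`` is the direction the wind blows FROM (degrees from north),
    so the transport direction is the opposite unit vector.
    """
    th = np.deg2rad(wind_dir)
    dx, dy = (-np.sin(th), -np.cos(th))  # transport direction
    ox, oy = np.asarray(rx) - sx, np.asarray(ry) - sy_
    downwind = ox * dx + oy * dy
    crosswind = -ox * dy + oy * dx
    return downwind, crosswind


def gaussian_point(
    q_gps: float,
    downwind: np.ndarray,
    crosswind: np.ndarray,
    z: np.ndarray,
    h_eff: float,
    met: MetHour,
    cfg: DispersionConfig,
    roughness: float | np.ndarray | None = None,
) -> np.ndarray:
    """Steady-state point-source kernel, ug/m3 at the receptors.

    Ground reflection by image source; vertical growth capped by the mixing
    lid: once sigma_z exceeds ``mixing_cap * zi`` the plume is treated as
    uniformly mixed below zi.  Upwind receptors (downwind <= 0) get zero.
    """
    u = met.wind_speed
    zi = met.mixing_height
    z0 = met.roughness if roughness is None else roughness
    x = np.asarray(downwind, dtype=float)
    out = np.zeros_like(x)
    live = x > 0
    if not live.any() or q_gps == 0.0:
        return out
    xe = np.maximum(x[live], cfg.min_standoff_m)
    sy, sz = sigma_yz(xe, met.stability, cfg.sigma_scheme,
                      np.asarray(z0)[live] if np.ndim(z0) else z0)
    yterm = np.exp(-np.asarray(crosswind)[live] ** 2 / (2.0 * sy**2))
    zr = np.asarray(z)[live] if np.ndim(z) else np.full(xe.shape, z)
    mixed = sz > cfg.mixing_cap * zi
    # image sources: ground + first mixing-lid reflections
    vert = np.zeros_like(xe)
    for n in (-1, 0, 1):
        vert += np.exp(-((zr - h_eff + 2 * n * zi) ** 2) / (2 * sz**2))
        vert += np.exp(-((zr + h_eff + 2 * n * zi) ** 2) / (2 * sz**2))
    c = q_gps / (2.0 * np.pi * u * sy * sz) * yterm * vert
    c_mixed = q_gps / (np.sqrt(2.0 * np.pi) * sy * u * zi) * yterm
    out[live] = np.where(mixed, c_mixed, c) * G_PER_M3_TO_UG
    return out


def point_kernel(
    source: Mapping,
    receptors_xyz: tuple[np.ndarray, np.ndarray, np.ndarray],
    met: MetHour,
    q_gps: float = 1.0,
    cfg: DispersionConfig | None = None,
    roughness: np.ndarray | None = None,
) -> np.ndarray:
    """Concentration (ug/m3) from a stack at the receptors for one hour.

    ``source`` carries x, y, stack_height, stack_diameter, exit_velocity,
    exit_temp; plume rise is Briggs (configurable off).
    """
    cfg = cfg or DispersionConfig()
    rx, ry, rz = receptors_xyz
    h = float(source.get("stack_height", 0.0))
    if cfg.plume_rise and source.get("stack_diameter"):
        h += briggs_plume_rise(
            h,
            float(source["stack_diameter"]),
            float(source.get("exit_velocity", 0.0)),
            float(source.get("exit_temp", cfg.ambient_temp_k)),
            met.wind_speed,
            cfg.ambient_temp_k,
        )
    dw, cw = _wind_frame(float(source["x"]), float(source["y"]), rx, ry, met.wind_dir)
    return gaussian_point(q_gps, dw, cw, rz, h, met, cfg, roughness)


def area_kernel(
    polygon: Polygon,
    receptors_xyz: tuple[np.ndarray, np.ndarray, np.ndarray],
    met: MetHour,
    q_gps: float = 1.0,
    cfg: DispersionConfig | None = None,
    roughness: np.ndarray | None = None,
    grid_n: int | None = None,
) -> np.ndarray:
    """Area source as a grid of ground-level point sub-cells.

    The polygon is covered by an n x n grid (default >= 10, i.e. >= 100
    cells over the bounding box); cells whose center falls inside carry an
    equal share of the total release, conserving mass at any refinement.
    """
    cfg = cfg or DispersionConfig()
    n = grid_n or cfg.area_grid_n
    rx, ry, rz = receptors_xyz
    if q_gps == 0.0:
        return np.zeros_like(np.asarray(rx, dtype=float))
    minx, miny, maxx, maxy = polygon.bounds
    xs = np.linspace(minx, maxx, n, endpoint=False) + (maxx - minx) / (2 * n)
    ys = np.linspace(miny, maxy, n, endpoint=False) + (maxy - miny) / (2 * n)
    gx, gy = np.meshgrid(xs, ys)
    import shapely

    inside = shapely.contains_xy(polygon, gx.ravel(), gy.ravel())
    cx, cy = gx.ravel()[inside], gy.ravel()[inside]
    if cx.size == 0:  # degenerate/tiny polygon: single cell at centroid
        cx, cy = np.array([polygon.centroid.x]), np.array([polygon.centroid.y])
    import shapely as _shp

    if bool(np.any(_shp.contains_xy(polygon, np.asarray(rx), np.asarray(ry)))):
        log.debug("receptor(s) inside area source polygon; sub-cell standoff applied")
    q_cell = q_gps / cx.size
    out = np.zeros_like(np.asarray(rx, dtype=float))
    for sx_, sy_ in zip(cx, cy):
        dw, cw = _wind_frame(sx_, sy_, rx, ry, met.wind_dir)
        out += gaussian_point(q_cell, dw, cw, rz, 0.0, met, cfg, roughness)
    return out


def line_kernel(
    line: LineString,
    receptors_xyz: tuple[np.ndarray, np.ndarray, np.ndarray],
    met: MetHour,
    q_gps: float = 1.0,
    cfg: DispersionConfig | None = None,
    roughness: np.ndarray | None = None,
    rtol: float = 1e-3,
    max_depth: int = 10,
) -> np.ndarray:
    """Line source integrated along its segments.

    Total release ``q_gps`` is spread uniformly per unit length and the
    ground-level point kernel is integrated by Romberg-style trapezoid
    refinement (vectorised over receptors) until the field changes by less
    than ``rtol`` or the depth limit is hit.
    """
    cfg = cfg or DispersionConfig()
    rx, ry, rz = receptors_xyz
    out = np.zeros_like(np.asarray(rx, dtype=float))
    total_len = line.length
    if total_len == 0 or q_gps == 0.0:
        return out
    q_per_m = q_gps / total_len
    coords = np.asarray(line.coords)
    for (x0, y0), (x1, y1) in zip(coords[:-1], coords[1:]):
        seg_len = float(np.hypot(x1 - x0, y1 - y0))
        if seg_len == 0:
            continue

        def field_at(t: np.ndarray) -> np.ndarray:
            """(len(t), n_receptors) point-kernel values along the segment."""
            vals = np.empty((t.size, out.size))
            for i, ti in enumerate(t):
                sx_ = x0 + ti * (x1 - x0)
                sy_ = y0 + ti * (y1 - y0)
                dw, cw = _wind_frame(sx_, sy_, rx, ry, met.wind_dir)
                vals[i] = gaussian_point(1.0, dw, cw, rz, 0.0, met, cfg, roughness)
            return vals

        t = np.linspace(0.0, 1.0, 9)
        vals = field_at(t)
        integral = np.trapezoid(vals, t, axis=0)
        for _ in range(max_depth):
            tm = (t[:-1] + t[1:]) / 2.0  # midpoints only: reuse old values
            vals_m = field_at(tm)
            t_new = np.empty(t.size + tm.size)
            v_new = np.empty((t_new.size, out.size))
            t_new[0::2], t_new[1::2] = t, tm
            v_new[0::2], v_new[1::2] = vals, vals_m
            new_integral = np.trapezoid(v_new, t_new, axis=0)
            t, vals = t_new, v_new
            denom = np.max(np.abs(new_integral))
            if denom == 0 or np.max(np.abs(new_integral - integral)) <= rtol * denom:
                integral = new_integral
                break
            integral = new_integral
        out += integral * q_per_m * seg_len
    return out


# ---------------------------------------------------------------------------
# Annual averaging via the unit-emission transfer matrix
# ---------------------------------------------------------------------------


@dataclass
class ConcentrationField:
    """Receptor-level PM2.5 split by component (ug/m3)."""

    df: pd.DataFrame  # index receptor_id, columns ALL_COMPONENTS (+ total)

    def __post_init__(self):
        for c in ALL_COMPONENTS:
            if c not in self.df.columns:
                self.df[c] = 0.0
        if (self.df[list(ALL_COMPONENTS)] < -1e-9).any().any():
            raise ValueError("negative concentration component")
        self.df["total"] = self.df[list(ALL_COMPONENTS)].sum(axis=1)

    def totals(self) -> pd.Series:
        return self.df["total"]


def _receptor_arrays(receptors: Sequence[Receptor]) -> tuple[np.ndarray, ...]:
    return (
        np.array([r.x for r in receptors]),
        np.array([r.y for r in receptors]),
        np.array([r.z for r in receptors]),
    )


def transfer_matrix(
    inventory: Inventory,
    receptors: Sequence[Receptor],
    repset: RepresentativeMetSet,
    cfg: DispersionConfig | None = None,
    receptor_roughness: np.ndarray | None = None,
) -> pd.DataFrame:
    """Annual-average concentration per unit emission rate.

    Returns a (n_receptors x n_sources) DataFrame of ug/m3 per ton/year.
    Local primary and SOA fields are exact linear maps of the emission-rate
    vector through this matrix; scenarios re-weight it without re-running
    the plume kernels.
    """
    cfg = cfg or DispersionConfig()
    xyz = _receptor_arrays(receptors)
    n_r = len(receptors)
    src = inventory.df
    T = np.zeros((n_r, len(src)))
    for hour, w in zip(repset.hours, repset.weights):
        # per-receptor roughness (regional adjustment) overrides the hour's
        z0 = np.asarray(receptor_roughness) if receptor_roughness is not None else hour.roughness
        for j, row in enumerate(src.itertuples()):
            geom = inventory.geometries[row.source_id]
            if row.kind == "point":
                k = point_kernel(geom, xyz, hour, TPY_TO_GPS, cfg, z0)
            elif row.kind == "area":
                k = area_kernel(geom, xyz, hour, TPY_TO_GPS, cfg, z0)
            elif row.kind == "line":
                k = line_kernel(geom, xyz, hour, TPY_TO_GPS, cfg, z0)
            else:
                raise ValueError(f"unknown source kind {row.kind!r}")
            T[:, j] += w * k
    return pd.DataFrame(
        T, index=[r.receptor_id for r in receptors], columns=src["source_id"].tolist()
    )


def annual_average(
    inventory: Inventory,
    receptors: Sequence[Receptor],
    repset: RepresentativeMetSet,
    cfg: DispersionConfig | None = None,
    soa_rates: pd.Series | None = None,
    receptor_roughness: np.ndarray | None = None,
    tmatrix: pd.DataFrame | None = None,
) -> ConcentrationField:
    """Weighted-hour annual-average local primary PM2.5 and local SOA.

    Components are tracked by source kind.  ``soa_rates`` are the
    SOA-equivalent tons/year per source (from ``emissions.voc_to_soa``),
    dispersed with the same kernels.  A precomputed ``tmatrix`` (baseline
    cache) short-circuits the plume evaluation.
    """
    if tmatrix is None:
        tmatrix = transfer_matrix(inventory, receptors, repset, cfg, receptor_roughness)
    src = inventory.df.set_index("source_id")
    comp = {c: np.zeros(tmatrix.shape[0]) for c in ALL_COMPONENTS}
    for kind, col in (
        ("area", "primary_local_area"),
        ("point", "primary_local_point"),
        ("line", "primary_local_line"),
    ):
        ids = src.index[src["kind"] == kind]
        if len(ids):
            comp[col] = tmatrix[ids].to_numpy() @ src.loc[ids, "PM25"].to_numpy()
    if soa_rates is not None:
        rates = soa_rates.reindex(tmatrix.columns).fillna(0.0).to_numpy()
        comp["soa_local"] = tmatrix.to_numpy() @ rates
    df = pd.DataFrame(comp, index=tmatrix.index)
    df.index.name = "receptor_id"
    return ConcentrationField(df)


def secondary_inorganic(
    county_precursor_totals: pd.DataFrame,
    coefficients: pd.DataFrame,
) -> pd.DataFrame:
    """County-level secondary inorganic PM2.5 from precursor totals.

    Linearised chemistry: each component (nh4so4 from SO2; nh4no3 from NOx
    and NH3) is coefficient x precursor kilotons/year, uniform within the
    county.  ``county_precursor_totals`` columns: county, pollutant,
    total_tpy.  ``coefficients`` columns: county, component, precursor,
    coef_ug_per_kty.
    """
    need = set(map(tuple, county_precursor_totals[["county", "pollutant"]].values))
    have = set(map(tuple, coefficients[["county", "precursor"]].values))
    missing = {t for t in need if t[1] in set(coefficients["precursor"]) and t not in have}
    if missing:
        raise KeyError(f"missing secondary-PM coefficient for {sorted(missing)}")
    merged = coefficients.merge(
        county_precursor_totals,
        left_on=["county", "precursor"],
        right_on=["county", "pollutant"],
        how="left",
    )
    merged["total_tpy"] = merged["total_tpy"].fillna(0.0)
    merged["conc"] = merged["coef_ug_per_kty"] * merged["total_tpy"] / 1000.0
    out = merged.pivot_table(
        index="county", columns="component", values="conc", aggfunc="sum", fill_value=0.0
    ).reindex(columns=["nh4so4", "nh4no3"], fill_value=0.0)
    out.columns.name = None
    return out.reset_index()


def assemble_total_pm(
    field: ConcentrationField,
    receptors: Sequence[Receptor],
    zcta_county: Mapping[str, str],
    transported: pd.DataFrame,
    secondary: pd.DataFrame | None = None,
) -> ConcentrationField:
    """Add county-level transported primary / transported SOA / secondary
    inorganic components to the local field and recompute totals.

    ``transported`` columns: county, primary_transported, soa_transported;
    ``secondary`` columns: county, nh4so4, nh4no3.
    """
    df = field.df.copy()
    counties = pd.Series(
        [zcta_county[r.zcta_id] for r in receptors],
        index=[r.receptor_id for r in receptors],
    ).reindex(df.index)
    tr = transported.set_index("county")
    missing = set(counties) - set(tr.index)
    if missing:
        raise KeyError(f"no transported-PM row for counties {sorted(missing)}")
    df["primary_transported"] = counties.map(tr["primary_transported"]).to_numpy()
    df["soa_transported"] = counties.map(tr["soa_transported"]).to_numpy()
    if secondary is not None:
        sec = secondary.set_index("county")
        missing = set(counties) - set(sec.index)
        if missing:
            raise KeyError(f"no secondary-PM row for counties {sorted(missing)}")
        df["nh4so4"] = counties.map(sec["nh4so4"]).to_numpy()
        df["nh4no3"] = counties.map(sec["nh4no3"]).to_numpy()
    return ConcentrationField(df.drop(columns=["total"]))
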