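"""ZCTA polygons and the receptor network.

ZCTA (ZIP Code Tabulation Area) polygons are the exposure and reporting
units.  Each polygon part is discretised into receptors — the points where
plume concentrations are evaluated at breathing height:

* small polygons (below an upper area threshold expressed in square feet,
  roughly a dense-city block) get a single receptor at the centroid;
* large polygons are split into ``k_large`` Voronoi cells via k-means on
  points sampled uniformly inside the polygon, and one receptor is placed
  at the centroid of each cell clipped to the polygon.

Coordinates are planar meters in a user-declared projected CRS; the package
never reprojects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import GeometryCollection, MultiPoint, Point, Polygon, mapping, shape
from shapely.ops import nearest_points, voronoi_diagram
from sklearn.cluster import KMeans

from .config import M2_PER_SQFT, SQFT_PER_M2, ReceptorConfig


@dataclass(frozen=True)
class ZctaPolygon:
    """One polygon part of a ZCTA (a ZCTA may have several disjoint parts)."""

    zcta_id: str
    borough: str
    polygon: Polygon
    population: int
    part_index: int = 0

    @property
    def area_m2(self) -> float:
        return self.polygon.area

    @property
    def area_sqft(self) -> float:
        return self.polygon.area * SQFT_PER_M2

    def validate(self) -> None:
        if not self.polygon.is_valid or self.polygon.area <= 0:
            raise ValueError(
                f"degenerate polygon for ZCTA {self.zcta_id} part {self.part_index}: "
                f"area={self.polygon.area}"
            )


@dataclass(frozen=True)
class Receptor:
    receptor_id: str
    zcta_id: str
    x: float
    y: float
    z: float = 1.8


def load_zcta_polygons(path: str | Path) -> list[ZctaPolygon]:
    """Read a GeoJSON FeatureCollection (planar meters) into polygon parts.

    MultiPolygon features are split into separate parts sharing a zcta_id.
    """
    with open(path) as fh:
        fc = json.load(fh)
    out: list[ZctaPolygon] = []
    for feat in fc["features"]:
        props = feat["properties"]
        geom = shape(feat["geometry"])
        parts = list(geom.geoms) if geom.geom_type == "MultiPolygon" else [geom]
        for i, part in enumerate(parts):
            zp = ZctaPolygon(
                zcta_id=str(props["zcta_id"]),
                borough=str(props.get("borough", "")),
                polygon=part,
                population=int(props.get("population", 0)),
                part_index=i,
            )
            zp.validate()
            out.append(zp)
    return out


def _sample_in_polygon(poly: Polygon, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform rejection sampling of n interior points."""
    minx, miny, maxx, maxy = poly.bounds
    pts: list[np.ndarray] = []
    while sum(len(p) for p in pts) < n:
        m = max(4 * n, 256)
        cand = np.column_stack(
            [rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)]
        )
        import shapely

        inside = shapely.contains_xy(poly, cand[:, 0], cand[:, 1])
        pts.append(cand[inside])
    return np.concatenate(pts)[:n]


def _interior_point(poly: Polygon, pt: Point) -> Point:
    """Snap a point to (strictly) inside the polygon if it falls outside."""
    if poly.contains(pt):
        return pt
    near = nearest_points(poly, pt)[0]
    if poly.contains(near):
        return near
    # nearest point lies on the boundary of a concave part: nudge inward
    anchor = poly.representative_point()
    for frac in (1e-6, 1e-4, 1e-2, 0.1, 0.5):
        cand = Point(
            near.x + frac * (anchor.x - near.x), near.y + frac * (anchor.y - near.y)
        )
        if poly.contains(cand):
            return cand
    return anchor


def voronoi_cells(poly: Polygon, k: int, cfg: ReceptorConfig, seed: int) -> list[Polygon]:
    """Split ``poly`` into k Voronoi cells around k-means cluster centers.

    k-means runs on ``cfg.n_samples`` uniform interior samples; the Voronoi
    diagram of the k centers is clipped to the polygon, so the cells tile it
    exactly (up to boundary measure zero).
    """
    rng = np.random.default_rng(seed)
    samples = _sample_in_polygon(poly, cfg.n_samples, rng)
    km = KMeans(n_clusters=k, n_init=cfg.n_restarts, random_state=seed).fit(samples)
    centers = MultiPoint([Point(c) for c in km.cluster_centers_])
    vor: GeometryCollection = voronoi_diagram(centers, envelope=poly.buffer(poly.length))
    cells = []
    for cell in vor.geoms:
        clipped = cell.intersection(poly)
        if not clipped.is_empty and clipped.area > 0:
            if clipped.geom_type == "MultiPolygon":
                cells.extend(list(clipped.geoms))
            else:
                cells.append(clipped)
    return cells


def place_receptors(
    zp: ZctaPolygon, cfg: ReceptorConfig | None = None, seed: int | None = None
) -> list[Receptor]:
    """Receptors for one polygon part.

    Area within [small, large] sq ft (and anything smaller) -> one centroid
    receptor.  Area above the large threshold -> ``k_large`` receptors at
    the centroids of the clipped Voronoi cells.  Receptors falling outside a
    concave polygon are snapped to the nearest interior point.
    """
    cfg = cfg or ReceptorConfig()
    seed = cfg.seed if seed is None else seed
    zp.validate()
    prefix = f"{zp.zcta_id}-{zp.part_index}"
    if zp.area_sqft <= cfg.large_area_sqft:
        pt = _interior_point(zp.polygon, zp.polygon.centroid)
        return [Receptor(f"{prefix}-r0", zp.zcta_id, pt.x, pt.y, cfg.height_m)]
    cells = voronoi_cells(zp.polygon, cfg.k_large, cfg, seed)
    # order cells deterministically (by centroid x then y)
    cells.sort(key=lambda c: (round(c.centroid.x, 6), round(c.centroid.y, 6)))
    recs = []
    for i, cell in enumerate(cells[: cfg.k_large]):
        pt = _interior_point(zp.polygon, cell.centroid)
        recs.append(Receptor(f"{prefix}-r{i}", zp.zcta_id, pt.x, pt.y, cfg.height_m))
    return recs


def build_receptor_network(
    polygons: Iterable[ZctaPolygon], cfg: ReceptorConfig | None = None
) -> list[Receptor]:
    cfg = cfg or ReceptorConfig()
    recs: list[Receptor] = []
    for zp in polygons:
        recs.extend(place_receptors(zp, cfg, seed=cfg.seed + hash_part(zp)))
    return recs


def hash_part(zp: ZctaPolygon) -> int:
    """Stable small-int offset so each part draws an independent sample set."""
    h = 0
    for ch in f"{zp.zcta_id}:{zp.part_index}":
        h = (h * 131 + ord(ch)) % 1_000_003
    return h


def aggregate_receptors_to_zcta(
    values: Mapping[str, float], receptors: Sequence[Receptor]
) -> dict[str, float]:
    """ZCTA exposure = unweighted mean over all its receptors (all parts)."""
    missing = [r.receptor_id for r in receptors if r.receptor_id not in values]
    if missing:
        raise KeyError(f"missing receptor values: {missing}")
    df = pd.DataFrame(
        {
            "zcta_id": [r.zcta_id for r in receptors],
            "value": [values[r.receptor_id] for r in receptors],
        }
    )
    return df.groupby("zcta_id")["value"].mean().to_dict()


def receptors_to_frame(receptors: Sequence[Receptor]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.receptor_id, r.zcta_id, r.x, r.y, r.z) for r in receptors],
        columns=["receptor_id", "zcta_id", "x", "y", "z"],
    )


def receptors_to_geojson(receptors: Sequence[Receptor]) -> dict:
    return {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(Point(r.x, r.y)),
                "properties": {"receptor_id": r.receptor_id, "zcta_id": r.zcta_id, "z": r.z},
            }
            for r in receptors
        ],
    }
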