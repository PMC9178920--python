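"""Run configuration.

All tunable knobs of the modelling chain live here as pydantic models so a
whole run is described by one structured file (JSON/dict), hashable for
baseline caching and recorded in the output manifest.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, Field

SQFT_PER_M2 = 1.0 / 0.09290304  # 1 m^2 in square feet
M2_PER_SQFT = 0.09290304
GRAMS_PER_TON = 907_184.74  # US short ton
SECONDS_PER_YEAR = 31_536_000.0


class ReceptorConfig(BaseModel):
    """Receptor-network rules (areas are in square feet, heights in meters)."""

    k_large: int = 10
    height_m: float = 1.8
    seed: int = 0
    small_area_sqft: float = 100_000.0
    large_area_sqft: float = 500_000.0
    n_samples: int = 2000  # uniform interior samples fed to k-means
    n_restarts: int = 10


class MetConfig(BaseModel):
    n_rep: int = 100
    seed: int = 0
    roughness_default_m: float = 1.0  # urban standard roughness length
    roughness_delta_m: float = 0.25  # added in the high-rise district
    adjusted_boroughs: list[str] = Field(default_factory=lambda: ["Manhattan"])
    calm_floor_ms: float = 0.5


class DispersionConfig(BaseModel):
    sigma_scheme: str = "urban"  # "urban" | "rural" Pasquill-Gifford curves
    area_grid_n: int = 10  # area sources subdivided into n x n point cells
    mixing_cap: float = 1.6  # sigma_z > cap * mixing height -> well-mixed
    plume_rise: bool = True  # Briggs rise for point stacks
    min_standoff_m: float = 1.0
    ambient_temp_k: float = 293.0


class HealthConfig(BaseModel):
    cr_functions: Optional[str] = None  # JSON path; None -> packaged defaults
    unit_values: Optional[str] = None
    soa_yield_default: float = 0.05  # VOC -> SOA mass yield per tier1


class RunConfig(BaseModel):
    """Paths plus the per-stage sections; one file drives a full run."""

    polygons: str
    inventory: str
    geometries: str
    met: str
    population: str
    baselines: str
    transported: str
    surrogates: Optional[str] = None
    secondary_coefficients: Optional[str] = None
    zcta_county: Optional[str] = None
    seed: int = 0
    out_dir: str = "out"

    receptors: ReceptorConfig = Field(default_factory=ReceptorConfig)
    met_options: MetConfig = Field(default_factory=MetConfig)
    dispersion: DispersionConfig = Field(default_factory=DispersionConfig)
    health: HealthConfig = Field(default_factory=HealthConfig)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))
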