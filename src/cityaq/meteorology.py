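"""Representative-hour meteorology.

A year of hourly surface observations (wind, Pasquill-Gifford stability,
mixing height) is reduced to <= n_rep weighted representative hours by
k-means clustering in (u, v, stability) feature space — the
meteorologically-weighted-averaging idea: annual-average concentrations are
then weighted sums over ~100 states instead of 8760 hourly runs.

Wind direction follows the meteorological convention: degrees from north,
the direction the wind blows FROM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .config import MetConfig

STABILITY_ORDER = "ABCDEF"


@dataclass(frozen=True)
class MetHour:
    wind_speed: float  # m/s
    wind_dir: float  # degrees from north, direction wind blows FROM
    stability: str  # Pasquill-Gifford class A-F
    mixing_height: float  # m
    roughness: float = 1.0  # m

    def __post_init__(self):
        if self.stability not in STABILITY_ORDER:
            raise ValueError(f"unknown stability class {self.stability!r}")
        if not 0 <= self.wind_dir < 360:
            object.__setattr__(self, "wind_dir", self.wind_dir % 360.0)
        if self.mixing_height <= 0:
            raise ValueError("mixing height must be positive")

    @property
    def uv(self) -> tuple[float, float]:
        """Wind vector components (direction air moves toward)."""
        th = np.deg2rad(self.wind_dir)
        return (-self.wind_speed * np.sin(th), -self.wind_speed * np.cos(th))


@dataclass(frozen=True)
class RepresentativeMetSet:
    hours: tuple[MetHour, ...]
    weights: tuple[float, ...]

    def __post_init__(self):
        w = np.asarray(self.weights)
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")
        if len(self.hours) != len(self.weights):
            raise ValueError("hours/weights length mismatch")


def load_met_csv(path: str | Path, roughness: float = 1.0) -> list[MetHour]:
    df = pd.read_csv(path)
    return [
        MetHour(
            wind_speed=float(r.wind_speed_ms),
            wind_dir=float(r.wind_dir_deg),
            stability=str(r.stability_class),
            mixing_height=float(r.mixing_height_m),
            roughness=roughness,
        )
        for r in df.itertuples()
    ]


def _features(hours: Sequence[MetHour]) -> np.ndarray:
    """(u, v, ordinal stability) scaled to unit variance per column."""
    feats = np.array(
        [[*h.uv, STABILITY_ORDER.index(h.stability) + 1.0] for h in hours]
    )
    std = feats.std(axis=0)
    std[std == 0] = 1.0
    return (feats - feats.mean(axis=0)) / std


def floor_calms(hours: Sequence[MetHour], floor: float = 0.5) -> list[MetHour]:
    """Calm hours are floored, not dropped — keeps weights interpretable and
    the plume kernel's 1/u finite."""
    return [
        replace(h, wind_speed=floor) if h.wind_speed < floor else h for h in hours
    ]


def select_representative_hours(
    hourly: Sequence[MetHour], n_rep: int = 100, seed: int = 0, cfg: MetConfig | None = None
) -> RepresentativeMetSet:
    """Cluster the year into n_rep states; each cluster contributes its
    medoid (member nearest the cluster mean) with weight = cluster share.

    The medoid, not the mean, is kept so every representative state is a
    physically consistent observed hour.
    """
    cfg = cfg or MetConfig()
    hours = floor_calms(hourly, cfg.calm_floor_ms)
    n = len(hours)
    if n == 0:
        raise ValueError("no valid hours")
    if n <= n_rep:
        if n < n_rep:
            warnings.warn(
                f"only {n} valid hours for n_rep={n_rep}; keeping all with equal weight"
            )
        return RepresentativeMetSet(tuple(hours), tuple([1.0 / n] * n))
    feats = _features(hours)
    km = KMeans(n_clusters=n_rep, n_init=10, random_state=seed).fit(feats)
    reps, weights = [], []
    for c in range(n_rep):
        members = np.flatnonzero(km.labels_ == c)
        if members.size == 0:
            continue
        d = np.linalg.norm(feats[members] - km.cluster_centers_[c], axis=1)
        reps.append(hours[members[np.argmin(d)]])
        weights.append(members.size / n)
    w = np.array(weights)
    w = w / w.sum()  # renormalize after any empty clusters
    return RepresentativeMetSet(tuple(reps), tuple(w))


def apply_roughness_region(
    hours: Sequence[MetHour], in_region: bool, delta_roughness: float
) -> list[MetHour]:
    """Roughness-length adjustment for a high-rise district.

    Returns a copy of ``hours`` with roughness incremented by ``delta`` when
    the receptor region is flagged; the adjustment only affects the
    dispersion-parameter lookup (sigma_z enhancement), a screening-grade
    stand-in for building-induced turbulence.
    """
    if delta_roughness < 0:
        raise ValueError("delta_roughness must be >= 0")
    if not in_region or delta_roughness == 0:
        return list(hours)
    return [replace(h, roughness=h.roughness + delta_roughness) for h in hours]
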