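"""Monitor-vs-model evaluation statistics.

Paired annual-average PM2.5 comparisons at monitoring sites, with the
statistical performance measures standard in the air-quality model
evaluation literature:

* FAC2 — fraction of pairs with modeled/observed within [0.5, 2]; 1 is perfect.
* NMSE — mean squared error normalised by the product of the means; 0 is perfect.
* per-site bias (modeled - observed) and percent difference relative to the
  modeled value.

A 19-site 2016 NYC comparison table (16 regulatory AQS sites plus 3
community-network sites) ships as a packaged fixture; the regulatory subset
is the default evaluation set, with ``subset="all"`` covering every site.
MB, NMB and Pearson r are provided as additional literature measures.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class MonitorPair:
    network: str
    site: str
    zcta_id: str
    observed: float
    modeled: float

    def __post_init__(self):
        if self.observed <= 0 or self.modeled <= 0:
            raise ValueError(f"non-positive concentration at site {self.site}")


def load_monitor_pairs(path: str | Path | None = None, subset: str = "all") -> pd.DataFrame:
    """Load a pairs CSV (network, site, zcta_id, observed, modeled).

    ``subset='aqs'`` keeps the regulatory-network rows only.
    """
    if path is None:
        text = resources.files("cityaq").joinpath("data/nyc_monitor_pairs_2016.csv").read_text()
        df = pd.read_csv(StringIO(text), dtype={"zcta_id": str})
    else:
        df = pd.read_csv(path, dtype={"zcta_id": str})
    if (df["observed"] <= 0).any() or (df["modeled"] <= 0).any():
        raise ValueError("observed and modeled must be positive")
    if subset.lower() == "aqs":
        df = df[df["network"] == "AQS"].reset_index(drop=True)
    return df


def site_bias(observed: float, modeled: float) -> float:
    """Signed model error, ug/m3 (modeled - observed)."""
    return modeled - observed


def site_pct_diff(observed: float, modeled: float) -> float:
    """Percent difference, relative to the modeled value."""
    if modeled == 0:
        raise ZeroDivisionError("modeled concentration is zero")
    return 100.0 * (modeled - observed) / modeled


def fac2(observed: np.ndarray, modeled: np.ndarray) -> float:
    """Fraction of pairs with 0.5 <= modeled/observed <= 2."""
    o, m = np.asarray(observed, float), np.asarray(modeled, float)
    if o.size == 0:
        raise ValueError("need at least one pair")
    r = m / o
    return float(np.mean((r >= 0.5) & (r <= 2.0)))


def nmse(observed: np.ndarray, modeled: np.ndarray) -> float:
    """Normalised mean square error: mean((o-m)^2) / (mean(o) * mean(m))."""
    o, m = np.asarray(observed, float), np.asarray(modeled, float)
    if o.size == 0:
        raise ValueError("need at least one pair")
    if o.mean() == 0 or m.mean() == 0:
        raise ZeroDivisionError("zero mean concentration")
    return float(np.mean((o - m) ** 2) / (o.mean() * m.mean()))


def evaluate(pairs: pd.DataFrame) -> dict:
    """All evaluation statistics for a pairs table, plus per-site columns."""
    o = pairs["observed"].to_numpy()
    m = pairs["modeled"].to_numpy()
    per_site = pairs.copy()
    per_site["bias"] = m - o
    per_site["pct_diff"] = 100.0 * (m - o) / m
    r = float(np.corrcoef(o, m)[0, 1]) if len(o) > 1 else float("nan")
    return {
        "n": int(len(pairs)),
        "fac2": fac2(o, m),
        "nmse": nmse(o, m),
        "mb": float(np.mean(m - o)),
        "nmb": float(np.sum(m - o) / np.sum(o)),
        "r": r,
        "per_site": per_site,
    }
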