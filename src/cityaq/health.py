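"""Health impact assessment: avoided events and monetized benefits.

A change in annual-average PM2.5 at the ZCTA level is converted into
avoided health events per endpoint with the log-linear
concentration-response form used across EPA screening tools:

    avoided = rate * population * (1 - exp(-beta * dC))

where ``rate`` is the baseline annual incidence per person, ``population``
the count in the endpoint's age range, ``beta`` the C-R coefficient per
(ug/m3), and ``dC`` the concentration reduction.  Mortality and nonfatal
heart attacks carry paired low/high coefficient variants; dollars are
events times an endpoint unit value (value of a statistical life for
mortality), current-year USD, no discounting.

The shipped default coefficient and valuation tables are illustrative,
not calibrated to any regulatory tool; users supply their own for real
analyses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

ENDPOINTS = (
    "adult_mortality",
    "infant_mortality",
    "nonfatal_heart_attacks",
    "respiratory_hospitalizations",
    "cardiovascular_hospitalizations",
    "acute_bronchitis",
    "upper_respiratory_symptoms",
    "lower_respiratory_symptoms",
    "asthma_ed_visits",
    "asthma_exacerbations",
    "minor_restricted_activity_days",
    "work_loss_days",
)

PAIRED_ENDPOINTS = ("adult_mortality", "nonfatal_heart_attacks")


@dataclass(frozen=True)
class CRFunction:
    endpoint: str
    beta: float  # per ug/m3
    variant: str = "single"  # low | high | single
    age_min: int = 0
    age_max: int = 99

    def __post_init__(self):
        if self.beta < 0:
            raise ValueError(f"negative beta for {self.endpoint}")


def load_cr_functions(path: str | Path | None = None) -> list[CRFunction]:
    """Load the C-R coefficient set (JSON list); default = packaged table."""
    if path is None:
        text = resources.files("cityaq").joinpath("data/cr_functions.json").read_text()
    else:
        text = Path(path).read_text()
    funcs = [CRFunction(**d) for d in json.loads(text)]
    by_ep: dict[str, dict[str, float]] = {}
    for f in funcs:
        by_ep.setdefault(f.endpoint, {})[f.variant] = f.beta
    for ep, variants in by_ep.items():
        if "low" in variants and "high" in variants and variants["low"] > variants["high"]:
            raise ValueError(f"low beta exceeds high beta for {ep}")
    return funcs


def load_unit_values(path: str | Path | None = None) -> dict[str, float]:
    if path is None:
        text = resources.files("cityaq").joinpath("data/unit_values.json").read_text()
    else:
        text = Path(path).read_text()
    vals = json.loads(text)
    if any(v < 0 for v in vals.values()):
        raise ValueError("unit values must be >= 0")
    return vals


def avoided_events(
    delta_c: float, rate: float, population: float, beta: float
) -> float:
    """Avoided events/year for one (ZCTA, endpoint) cell.

    Monotone increasing and concave in delta_c, bounded above by
    rate * population; negative delta_c (a disbenefit) yields negative
    avoided events.
    """
    return rate * population * -np.expm1(-beta * delta_c)


def run_hia(
    delta_field: Mapping[str, float],
    baselines: pd.DataFrame,
    cr_set: Sequence[CRFunction],
    unit_values: Mapping[str, float],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-ZCTA, per-endpoint, per-variant avoided events and dollars.

    ``delta_field`` maps zcta_id -> PM2.5 reduction (ug/m3).  ``baselines``
    columns: zcta_id, endpoint, rate (events/person/year), population (count
    in the endpoint's age range).  Returns (per-ZCTA results, city totals);
    paired endpoints report low and high rows.
    """
    base = baselines.set_index(["zcta_id", "endpoint"]).sort_index()
    rows = []
    for zcta, dc in delta_field.items():
        for cr in cr_set:
            key = (str(zcta), cr.endpoint)
            if key not in base.index:
                raise KeyError(f"missing baseline for zcta={zcta} endpoint={cr.endpoint}")
            if cr.endpoint not in unit_values:
                raise KeyError(f"missing unit value for endpoint {cr.endpoint}")
            rate = float(base.loc[key, "rate"])
            pop = float(base.loc[key, "population"])
            ev = avoided_events(dc, rate, pop, cr.beta)
            rows.append(
                {
                    "zcta_id": str(zcta),
                    "endpoint": cr.endpoint,
                    "variant": cr.variant,
                    "delta_c": dc,
                    "avoided_events": ev,
                    "dollars": ev * unit_values[cr.endpoint],
                }
            )
    results = pd.DataFrame(rows)
    city = (
        results.groupby(["endpoint", "variant"], sort=False)[["avoided_events", "dollars"]]
        .sum()
        .reset_index()
    )
    return results, city


def monetize(results: pd.DataFrame, unit_values: Mapping[str, float]) -> pd.DataFrame:
    """Recompute dollars = events x unit value (per row); mortality uses the
    value-of-statistical-life entry.  Returns the frame with dollars set."""
    out = results.copy()
    out["dollars"] = out.apply(
        lambda r: r["avoided_events"] * unit_values[r["endpoint"]], axis=1
    )
    return out


def overall_benefits(city: pd.DataFrame) -> dict[str, float]:
    """City-wide total dollars under the low and the high bound.

    Paired endpoints contribute their low variant to the low bound and high
    to the high bound; single-variant endpoints contribute to both.
    """
    low = high = 0.0
    for (_, variant), grp in city.groupby(["endpoint", "variant"], sort=False):
        d = float(grp["dollars"].sum())
        if variant == "low":
            low += d
        elif variant == "high":
            high += d
        else:
            low += d
            high += d
    return {"dollars_low": low, "dollars_high": high}
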