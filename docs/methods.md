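# Methods

`cityaq` chains five stages: receptor-network construction, meteorological
reduction, Gaussian-plume dispersion of a tiered inventory, assembly of
total PM2.5 from local and county-level components, and a log-linear health
impact assessment. This note records the model forms, the defaults and why,
the numerical choices, and what the synthetic test city does and does not
establish.

## Receptor network

ZCTA polygons arrive as a GeoJSON FeatureCollection in planar meters of a
user-declared projected CRS; the package never reprojects — geodesy is the
caller's responsibility. A ZCTA may consist of several disjoint parts, each
discretised independently.

Area thresholds follow the block-scale convention and are expressed in
square feet (1 sq ft = 0.09290304 m²): polygons of 100,000–500,000 sq ft
(roughly one dense-city block) receive a single receptor at the centroid.
Polygons below 100,000 sq ft also receive one centroid receptor — the rule
is kept monotone rather than inventing a sub-block scheme. Larger polygons
are split into `k_large` (default 10) cells: k-means on 2,000 uniform
interior samples (10 restarts, seeded), Voronoi diagram of the cluster
centers clipped to the polygon, one receptor at each clipped cell's
centroid. Cells tile the polygon up to boundary measure zero, which the
tests verify both by exact area accounting and by Monte-Carlo point
membership. Centroids of concave cells that fall outside are snapped to the
nearest interior point (nudged off the boundary toward a representative
interior point). Receptor height defaults to 1.8 m, the conventional adult
breathing height and typical monitor inlet height.

ZCTA exposure is the unweighted mean over all receptors of all the ZCTA's
parts. Receptor counts are therefore a deterministic function of the area
distribution and `k_large`, and placement is bit-reproducible for a fixed
seed.

## Representative meteorology

A year of hourly surface records (wind speed/direction, Pasquill–Gifford
stability A–F, mixing height) is clustered by k-means with k = `n_rep`
(default 100) in feature space (u, v, ordinal stability 1–6), each feature
scaled to unit variance. Each cluster contributes its *medoid* — the
observed hour nearest the cluster mean — so every representative state is a
physically consistent measurement, with weight = cluster share. Weights are
renormalised after any empty clusters; annual averages are then weighted
sums over the representative set. Calm hours (< 0.5 m/s) are floored to
0.5 m/s rather than dropped, keeping weights interpretable and the 1/u plume
factor finite. Wind direction uses the meteorological convention (degrees
from north, blowing FROM).

Stability as an ordinal clustering feature is a design choice: it preserves
the A→F ordering without asserting a metric between classes. Fidelity is
characterised empirically: on a 200-hour two-regime year, 50 representative
hours reproduce the all-hours annual mean within ~2% (the suite requires
< 5%), and a 2-cluster reduction recovers the 70/30 regime mixture within
±0.02.

A high-rise district ("Manhattan-like" in the synthetic city) is handled by
adding `roughness_delta_m` (default 0.25 m) to the base roughness length
(default 1.0 m, the urban standard) for receptors in flagged boroughs, i.e.
an effective 1.25 m. The base-plus-delta split is deliberately exposed as
configuration because either interpretation (0.25 m absolute vs +0.25 m) can
be set without code changes. Roughness affects only the σ_z lookup (below);
no building-downwash mechanics are modeled.

## Emission inventory and scenarios

Sources are area polygons, point stacks (with stack height/diameter, exit
velocity and temperature), or polylines with AADT; each carries a tier1 /
tier2 / tier3 category (e.g. category / fuel / technology) and annual rates
in tons/year for PM2.5, NOx, SO2, VOC and NH3. Tiers are free-form strings
matched by prefix at each level, so an edit can target a category, a fuel
within it, or a technology. Tons/year convert to g/s with 1 short ton =
907,184.74 g over 31,536,000 s (constant emissions; no temporal profiles).

Scenario edits are scoped (zcta / borough / city), tier-filtered, optionally
pollutant-filtered, and either multiplicative (percent, ≥ −100) or additive
(tons/year, floored at zero); an `aadt_factor` scales all pollutant rates of
matching line sources with traffic volume. Application is immutable (the
baseline inventory is untouched), edits on disjoint scopes commute, and an
edit matching nothing warns rather than fails — a no-op is a legitimate
exploration. County-to-ZCTA allocation uses spatial-surrogate weight tables
validated to sum to one per (county, tier1); allocation conserves mass
exactly.

SOA-equivalent emissions are VOC × a per-tier1 mass yield (anthropogenic
only) and are dispersed exactly like a primary pollutant. The shipped yield
default (0.05 for every tier) is an explicit, overridable placeholder: real
yields are source-category-specific and must be supplied by the user.

## Dispersion

The local kernel is the steady-state Gaussian plume with image-source ground
reflection and first-order mixing-lid reflections (n = −1, 0, 1); once
σ_z > 1.6 × mixing height the plume is treated as uniformly mixed below the
lid. Receptors strictly upwind receive zero; a 1 m minimum standoff guards
the near-field singularity. σ_y, σ_z follow the Briggs interpolation
formulas for the Pasquill–Gifford classes, urban curves by default (rural
selectable). Roughness enters as a multiplicative σ_z enhancement
1 + 0.2·ln(z0/0.1 m) — a screening-grade surrogate for surface-layer
scaling, documented as such and configurable. Point stacks get Briggs final
plume rise (buoyancy and momentum, whichever is larger; ambient 293 K),
switchable off.

Area sources are integrated by covering the bounding box with an n×n grid
(default 10, i.e. ≥ 100 sub-cells for a convex polygon) of ground-level
point sources sharing the release equally — mass-conserving at any
refinement; the tests require < 1% agreement with a point source in the
shrinking-polygon limit and < 2% self-convergence between 10×10 and 40×40
grids. Receptors inside a source polygon are handled by the sub-cell
standoff and logged. Line sources spread the release uniformly per unit
length and integrate the point kernel along each segment by trapezoid
refinement with Richardson-style doubling (vectorised over receptors,
relative tolerance 1e-3, depth-limited); the perpendicular-wind receptor
matches the closed-form infinite-line expression within 3%.

Because every kernel is linear in Q, the annual-average local field is
T·e, where T[receptor, source] is the weighted-hour unit transfer matrix
(µg/m³ per ton/year) and e the rate vector. `run_baseline` computes T once;
`run_scenario` re-weights it. This makes superposition exact to rounding
(the suite checks combined-scenario deltas equal the sum of parts at ~1e-16)
and scenario turnaround independent of dispersion cost.

Secondary inorganic PM uses linear county coefficients (µg/m³ per
kiloton/yr): ammonium sulfate from SO2; ammonium nitrate from NOx and NH3.
Coefficients are inputs — linearised chemistry has no universal values —
and the shipped synthetic table is illustrative. Transported primary PM and
transported SOA are county-level input tables applied uniformly to the
county's receptors. Total PM2.5 is the sum of eight tracked components
(local primary by source kind, transported primary, sulfate, nitrate, local
and transported SOA).

## Health impact assessment

For each ZCTA and endpoint, avoided events = rate × population ×
(1 − e^(−β·ΔC)) with ΔC the PM2.5 reduction; the function is monotone,
concave, bounded by the baseline burden, and signs correctly for
disbenefits. Twelve endpoints are shipped; adult mortality and nonfatal
heart attacks carry paired low/high β. `population` is the count already
restricted to the endpoint's age range — no internal age pyramid. Dollars
are events × per-endpoint unit values (VSL for mortality), current-year
USD with no discounting or income growth: the output is an annual snapshot.
The shipped β table and unit values are *illustrative defaults*, clearly
not calibrated to any regulatory tool; any real analysis must supply its
own tables (JSON, same schema). City low/high dollar bounds combine the
low (resp. high) variant of paired endpoints with all single-variant
endpoints.

## Model evaluation

FAC2 (fraction of pairs with modeled/observed in [0.5, 2]) and NMSE
(mean(o−m)² / (mean o · mean m)), plus per-site bias (modeled − observed)
and percent difference taken relative to the *modeled* value — the
convention under which the packaged 19-site 2016 NYC annual-average table
reproduces its published bias and % difference columns to printed precision
(±0.01 µg/m³ / ±0.1 pp). On that table the 16 regulatory (AQS) sites give
FAC2 = 1 and NMSE = 0.053 (0.05 at two decimals); including the three
community-network sites gives 0.06. The regulatory subset is the default
(`subset="aqs"`); MB, NMB and Pearson r are reported alongside.

## Synthetic city

The generator writes a complete input bundle: a 6×6 grid of 1 km² ZCTAs
(two cells shrunk to exercise the single-receptor band and the sub-block
case), boroughs assigned by column with a high-density "Manhattan" stripe
flagged for the roughness adjustment, area sources in every ZCTA
(commercial cooking; residential fuel combustion with a no4_oil /
natural_gas tier2 split so fuel-switch scenarios have targets), two
power-generation stacks, two crossing arterial roads with AADT, a
two-regime wind year (70% SW 5 m/s class D, 30% NW 3 m/s class B — the
oracle for weight recovery), population, ZCTA-varying baseline rates with
an asthma gradient (northeast quadrant highest, so benefits concentrate
where baseline burden is high), county transported background decaying
eastward, unit-sum surrogate tables, and a synthetic monitor table
(labelled synthetic; not observations).

Area emission rates default to U(0.5, 6) tons/year per km² per tier
(doubled in the dense stripe), scaled by polygon area — the density scale
of a large U.S. city inventory, where the largest single area category is a
few tons/year per km². Defaults produce a baseline around 5–6 µg/m³ total
PM2.5 with sd ~3 across receptors on the default seed.

What the synthetic city does **not** establish: calibrated magnitudes for
any real city (its inventory, β values and valuation tables are synthetic
or illustrative), AERMOD-grade dispersion (no downwash, no
similarity-theory profiles, no deposition), real chemistry (SOA yields and
inorganic coefficients are placeholders), or temporal structure (constant
emissions, annual averages only). Passing tests demonstrate the internal
correctness and invariances of the chain — linearity, conservation,
convergence to analytic limits, determinism — not agreement with ambient
measurements; the packaged NYC monitor table is the only observational
anchor and it validates the evaluation statistics, not the dispersion.

## Numerical and engineering choices

* All randomness (sampling, k-means, the generator) flows from explicit
  seeds; reruns are byte-identical, and run manifests record the config
  hash and seed.
* Voronoi cells are ordered by centroid coordinates before receptor naming
  so receptor ids are stable across platforms.
* Weights, surrogate tables and C-R variant pairs are validated at load
  (sum-to-one within 1e-6/1e-9, low ≤ high, non-negative rates); degenerate
  polygons, missing county rows and missing baselines fail fast with the
  offending identifier in the message.
* Problem sizes in the test suite (3×3 city, 240-hour met record, 12
  representative hours) are chosen so the full suite characterises every
  operation in well under a minute of dispersion time; the acceptance
  script runs the full default city (6×6, 8,760 hours, 100 representative
  hours, 342 receptors) in about a minute and a half.
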