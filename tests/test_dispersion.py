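import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, Point, Polygon

from cityaq.config import DispersionConfig
from cityaq.dispersion import (
    ConcentrationField,
    annual_average,
    area_kernel,
    assemble_total_pm,
    line_kernel,
    point_kernel,
    secondary_inorganic,
    sigma_yz,
    transfer_matrix,
)
from cityaq.emissions import Inventory
from cityaq.geometry import Receptor
from cityaq.meteorology import MetHour, RepresentativeMetSet

CFG = DispersionConfig(plume_rise=False)
GROUND = {"x": 0.0, "y": 0.0, "stack_height": 0.0}


def hour(wd=270.0, ws=5.0, stab="D", zi=1000.0, z0=1.0):
    return MetHour(ws, wd, stab, zi, z0)


class TestPointKernel:
    def test_matches_hand_evaluated_gaussian(self, met_hour):
        """Ground release, centerline, ground-level receptor: the textbook
        expression Q/(pi u sy sz) evaluated independently at the model's
        sigma curves (reflection doubles the half-space kernel)."""
        xyz = (np.array([1000.0]), np.array([0.0]), np.array([0.0]))
        got = point_kernel(GROUND, xyz, met_hour, q_gps=1.0, cfg=CFG)
        sy, sz = sigma_yz(np.array([1000.0]), "D", "urban", 1.0)
        want = 1.0e6 / (np.pi * 5.0 * sy[0] * sz[0])
        assert got[0] == pytest.approx(want, rel=1e-9)

    def test_elevated_source_off_centerline(self, met_hour):
        """Full expression with crosswind offset and stack height, written
        out independently term by term."""
        x, y, z, H = 800.0, 120.0, 1.8, 50.0
        xyz = (np.array([x]), np.array([y]), np.array([z]))
        got = point_kernel({"x": 0.0, "y": 0.0, "stack_height": H}, xyz, met_hour, 2.0, CFG)
        sy, sz = sigma_yz(np.array([x]), "D", "urban", 1.0)
        sy, sz = sy[0], sz[0]
        want = (
            2.0e6 / (2 * np.pi * 5.0 * sy * sz)
            * np.exp(-y**2 / (2 * sy**2))
            * (np.exp(-((z - H) ** 2) / (2 * sz**2)) + np.exp(-((z + H) ** 2) / (2 * sz**2)))
        )
        assert got[0] == pytest.approx(want, rel=1e-6)

    def test_zero_emission_and_upwind_zero(self, met_hour, receptor_line):
        assert (point_kernel(GROUND, receptor_line, met_hour, 0.0, CFG) == 0).all()
        upwind = (np.array([-500.0]), np.array([0.0]), np.array([1.8]))
        assert point_kernel(GROUND, upwind, met_hour, 1.0, CFG)[0] == 0.0

    def test_doubling_emission_doubles_concentration(self, met_hour, receptor_line):
        c1 = point_kernel(GROUND, receptor_line, met_hour, 1.0, CFG)
        c2 = point_kernel(GROUND, receptor_line, met_hour, 2.0, CFG)
        np.testing.assert_allclose(c2, 2 * c1, rtol=1e-12)

    def test_concentration_decays_with_crosswind_offset(self, met_hour):
        y = np.array([0.0, 50.0, 150.0, 400.0])
        xyz = (np.full_like(y, 1000.0), y, np.full_like(y, 1.8))
        c = point_kernel(GROUND, xyz, met_hour, 1.0, CFG)
        assert (np.diff(c) < 0).all()

    def test_well_mixed_limit_inside_shallow_boundary_layer(self):
        """Far downwind under a low lid the plume is uniform below zi."""
        h = hour(zi=50.0, stab="B")
        xyz = (np.array([20000.0]), np.array([0.0]), np.array([1.8]))
        got = point_kernel(GROUND, xyz, h, 1.0, CFG)
        sy, _ = sigma_yz(np.array([20000.0]), "B", "urban", 1.0)
        want = 1.0e6 / (np.sqrt(2 * np.pi) * sy[0] * 5.0 * 50.0)
        assert got[0] == pytest.approx(want, rel=1e-9)


class TestAreaKernel:
    def test_tiny_polygon_matches_point_source(self, met_hour, receptor_line):
        """In the shrinking-polygon limit the area kernel is a point kernel."""
        tiny = Point(0.0, 0.0).buffer(0.5, quad_segs=8)  # ~0.78 m^2
        a = area_kernel(tiny, receptor_line, met_hour, 1.0, CFG)
        p = point_kernel(GROUND, receptor_line, met_hour, 1.0, CFG)
        np.testing.assert_allclose(a, p, rtol=0.01)

    def test_grid_self_convergence(self, met_hour):
        """10x10 vs 40x40 sub-grids differ < 2% at a receptor 500 m downwind."""
        poly = Polygon([(-100, -100), (100, -100), (100, 100), (-100, 100)])
        xyz = (np.array([500.0]), np.array([0.0]), np.array([1.8]))
        c10 = area_kernel(poly, xyz, met_hour, 1.0, CFG, grid_n=10)
        c40 = area_kernel(poly, xyz, met_hour, 1.0, CFG, grid_n=40)
        assert abs(c10[0] - c40[0]) / c40[0] < 0.02

    def test_zero_rate(self, met_hour, receptor_line):
        poly = Polygon([(-50, -50), (50, -50), (50, 50), (-50, 50)])
        assert (area_kernel(poly, receptor_line, met_hour, 0.0, CFG) == 0).all()


class TestLineKernel:
    def test_perpendicular_wind_matches_infinite_line_closed_form(self, met_hour):
        """Long straight road, wind perpendicular, receptor on the
        centerline: C = sqrt(2/pi) q/(u sz) (with ground reflection) —
        the analytic infinite-line limit."""
        L = 40_000.0
        road = LineString([(0.0, -L / 2), (0.0, L / 2)])  # north-south road
        x = 300.0  # wind from west blows across the road onto the receptor
        xyz = (np.array([x]), np.array([0.0]), np.array([0.0]))
        q = 2.0  # g/s total
        got = line_kernel(road, xyz, met_hour, q, CFG)
        _, sz = sigma_yz(np.array([x]), "D", "urban", 1.0)
        q_per_m = q / L
        want = np.sqrt(2 / np.pi) * q_per_m * 1.0e6 / (5.0 * sz[0]) * 2.0 / 2.0
        # (vert factor exp(0)*2 for ground reflection, /2 already in sqrt form)
        want = 2.0 * q_per_m * 1.0e6 / (np.sqrt(2 * np.pi) * 5.0 * sz[0])
        assert got[0] == pytest.approx(want, rel=0.03)

    def test_two_half_lines_sum_to_whole(self, met_hour):
        whole = LineString([(-500.0, 200.0), (500.0, 200.0)])
        left = LineString([(-500.0, 200.0), (0.0, 200.0)])
        right = LineString([(0.0, 200.0), (500.0, 200.0)])
        xyz = (np.array([100.0, 400.0]), np.array([-100.0, -300.0]), np.array([1.8, 1.8]))
        h = hour(wd=0.0)  # wind from north pushes the plume south over receptors
        cw = line_kernel(whole, xyz, h, 1.0, CFG)
        # each half carries half the total release (uniform per unit length)
        ch = line_kernel(left, xyz, h, 0.5, CFG) + line_kernel(right, xyz, h, 0.5, CFG)
        np.testing.assert_allclose(cw, ch, rtol=1e-3)

    def test_zero_length_line(self, met_hour, receptor_line):
        degenerate = LineString([(0.0, 0.0), (0.0, 0.0)])
        assert (line_kernel(degenerate, receptor_line, met_hour, 1.0, CFG) == 0).all()


def _mini_world():
    receptors = [
        Receptor("r0", "Z0", 400.0, 0.0, 1.8),
        Receptor("r1", "Z0", 900.0, 150.0, 1.8),
        Receptor("r2", "Z1", 1500.0, -200.0, 1.8),
    ]
    df = pd.DataFrame(
        [
            ["s_area", "area", "cooking", "c", "d", "Z0", "B", 3.0, 0, 0, 1.0, 0, 0.0],
            ["s_pt", "point", "power", "g", "t", "Z1", "B", 10.0, 0, 0, 0.0, 0, 0.0],
            ["s_line", "line", "onroad", "g", "l", "Z1", "B", 4.0, 0, 0, 2.0, 0, 1e4],
        ],
        columns=["source_id", "kind", "tier1", "tier2", "tier3", "zcta_id", "borough",
                 "PM25", "NOX", "SO2", "VOC", "NH3", "aadt"],
    )
    geoms = {
        "s_area": Polygon([(-100, -100), (100, -100), (100, 100), (-100, 100)]),
        "s_pt": {"x": 0.0, "y": 300.0, "stack_height": 40.0, "stack_diameter": 2.0,
                 "exit_velocity": 10.0, "exit_temp": 400.0},
        "s_line": LineString([(0.0, -800.0), (0.0, 800.0)]),
    }
    return Inventory(df, geoms), receptors


def test_annual_average_equals_brute_force_triple_loop():
    """The weighted representative-hour average must equal the naive loop
    over (hour, source, receptor) with per-receptor scalar kernel calls."""
    from cityaq.dispersion import TPY_TO_GPS

    inv, receptors = _mini_world()
    hours = (hour(270.0), hour(300.0, ws=3.0, stab="B"), hour(250.0, ws=6.0, stab="C"))
    repset = RepresentativeMetSet(hours, (0.5, 0.3, 0.2))
    cfg = DispersionConfig()
    field = annual_average(inv, receptors, repset, cfg)

    kernels = {"area": area_kernel, "line": line_kernel}
    for i, r in enumerate(receptors):
        xyz1 = (np.array([r.x]), np.array([r.y]), np.array([r.z]))
        total = 0.0
        for h, w in zip(repset.hours, repset.weights):
            for row in inv.df.itertuples():
                q = row.PM25 * TPY_TO_GPS
                if row.kind == "point":
                    c = point_kernel(inv.geometries[row.source_id], xyz1, h, q, cfg)
                else:
                    c = kernels[row.kind](inv.geometries[row.source_id], xyz1, h, q, cfg)
                total += w * float(c[0])
        cols = ["primary_local_area", "primary_local_point", "primary_local_line"]
        # line quadrature is adaptive, so agreement is at its tolerance
        assert field.df.iloc[i][cols].sum() == pytest.approx(total, rel=1e-3)


def test_single_hour_weight_one_equals_that_hours_field():
    inv, receptors = _mini_world()
    h = hour(270.0)
    one = annual_average(inv, receptors, RepresentativeMetSet((h,), (1.0,)))
    two = annual_average(
        inv, receptors, RepresentativeMetSet((h, hour(90.0)), (1.0, 0.0))
    )
    pd.testing.assert_frame_equal(one.df, two.df)


def test_mirror_winds_give_symmetric_receptors():
    """Two equal-weight hours with mirror winds (east/west) produce equal
    concentrations at receptors mirrored about the source."""
    inv, _ = _mini_world()
    inv.df = inv.df[inv.df.kind == "point"].reset_index(drop=True)
    inv.geometries = {"s_pt": {"x": 0.0, "y": 0.0, "stack_height": 10.0}}
    receptors = [Receptor("e", "Z", 600.0, 0.0, 1.8), Receptor("w", "Z", -600.0, 0.0, 1.8)]
    repset = RepresentativeMetSet((hour(270.0), hour(90.0)), (0.5, 0.5))
    field = annual_average(inv, receptors, repset, DispersionConfig(plume_rise=False))
    assert field.df.loc["e", "primary_local_point"] == pytest.approx(
        field.df.loc["w", "primary_local_point"], rel=1e-12
    )


def test_transfer_matrix_linearity():
    """C(alpha E) = alpha C(E): the field is the matrix times the rates."""
    inv, receptors = _mini_world()
    repset = RepresentativeMetSet((hour(270.0),), (1.0,))
    T = transfer_matrix(inv, receptors, repset)
    base = annual_average(inv, receptors, repset, tmatrix=T)
    inv2 = inv.copy()
    inv2.df[["PM25"]] *= 3.0
    tripled = annual_average(inv2, receptors, repset, tmatrix=T)
    np.testing.assert_allclose(
        tripled.df[["primary_local_area", "primary_local_point", "primary_local_line"]],
        3 * base.df[["primary_local_area", "primary_local_point", "primary_local_line"]],
        rtol=1e-12,
    )


class TestSecondaryInorganic:
    coefs = pd.DataFrame(
        [
            {"county": "C", "component": "nh4so4", "precursor": "SO2", "coef_ug_per_kty": 20.0},
            {"county": "C", "component": "nh4no3", "precursor": "NOX", "coef_ug_per_kty": 2.0},
            {"county": "C", "component": "nh4no3", "precursor": "NH3", "coef_ug_per_kty": 5.0},
        ]
    )

    def totals(self, so2, nox, nh3):
        return pd.DataFrame(
            [{"county": "C", "pollutant": "SO2", "total_tpy": so2},
             {"county": "C", "pollutant": "NOX", "total_tpy": nox},
             {"county": "C", "pollutant": "NH3", "total_tpy": nh3}]
        )

    def test_zero_precursors_zero_secondary(self):
        out = secondary_inorganic(self.totals(0, 0, 0), self.coefs)
        assert out[["nh4so4", "nh4no3"]].to_numpy().sum() == 0.0

    def test_linearity_in_coefficients(self):
        a = secondary_inorganic(self.totals(500, 1000, 100), self.coefs)
        doubled = self.coefs.copy()
        doubled["coef_ug_per_kty"] *= 2
        b = secondary_inorganic(self.totals(500, 1000, 100), doubled)
        np.testing.assert_allclose(b[["nh4so4", "nh4no3"]], 2 * a[["nh4so4", "nh4no3"]])

    def test_hand_arithmetic(self):
        out = secondary_inorganic(self.totals(500.0, 1000.0, 100.0), self.coefs).iloc[0]
        assert out["nh4so4"] == pytest.approx(20.0 * 0.5)
        assert out["nh4no3"] == pytest.approx(2.0 * 1.0 + 5.0 * 0.1)

    def test_missing_coefficient_errors(self):
        with pytest.raises(KeyError):
            secondary_inorganic(
                pd.DataFrame([{"county": "X", "pollutant": "SO2", "total_tpy": 1.0}]), self.coefs
            )


class TestAssembleTotal:
    def _field(self, receptors, local=0.0, soa=0.0):
        df = pd.DataFrame(
            {"primary_local_area": local, "soa_local": soa},
            index=[r.receptor_id for r in receptors],
        )
        return ConcentrationField(df)

    def test_all_zero_inputs_give_zero_total(self):
        recs = [Receptor("r0", "Z0", 0, 0)]
        tr = pd.DataFrame([{"county": "C", "primary_transported": 0.0, "soa_transported": 0.0}])
        out = assemble_total_pm(self._field(recs), recs, {"Z0": "C"}, tr)
        assert out.df["total"].iloc[0] == 0.0

    def test_component_summation(self):
        recs = [Receptor("r0", "Z0", 0, 0)]
        tr = pd.DataFrame([{"county": "C", "primary_transported": 1.0, "soa_transported": 0.1}])
        sec = pd.DataFrame([{"county": "C", "nh4so4": 0.5, "nh4no3": 0.25}])
        out = assemble_total_pm(self._field(recs, local=2.0, soa=0.15), recs, {"Z0": "C"}, tr, sec)
        assert out.df["total"].iloc[0] == pytest.approx(2.0 + 0.15 + 1.0 + 0.1 + 0.5 + 0.25)

    def test_constructed_secondary_shares(self):
        """Coefficients constructed so ammonium sulfate / SOA / ammonium
        nitrate split the secondary sum 45:40:15 reproduce those shares in
        the assembled field."""
        recs = [Receptor("r0", "Z0", 0, 0)]
        soa = 0.40
        sec = pd.DataFrame([{"county": "C", "nh4so4": 0.45, "nh4no3": 0.15}])
        tr = pd.DataFrame([{"county": "C", "primary_transported": 0.0, "soa_transported": 0.0}])
        out = assemble_total_pm(self._field(recs, soa=soa), recs, {"Z0": "C"}, tr, sec)
        row = out.df.iloc[0]
        secondary_sum = row["nh4so4"] + row["nh4no3"] + row["soa_local"] + row["soa_transported"]
        assert row["nh4so4"] / secondary_sum == pytest.approx(0.45)
        assert (row["soa_local"] + row["soa_transported"]) / secondary_sum == pytest.approx(0.40)
        assert row["nh4no3"] / secondary_sum == pytest.approx(0.15)

    def test_missing_county_row_errors(self):
        recs = [Receptor("r0", "Z0", 0, 0)]
        tr = pd.DataFrame([{"county": "OTHER", "primary_transported": 1.0, "soa_transported": 0.0}])
        with pytest.raises(KeyError, match="C"):
            assemble_total_pm(self._field(recs), recs, {"Z0": "C"}, tr)
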