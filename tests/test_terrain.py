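import math

import numpy as np
import pytest
from scipy import stats

from reefscape.grid import MultiscaleStack
from reefscape.terrain import (TerrainParams, VariableStack, aspect_components, bpi,
                               compare_sources, curvatures, derive_all, layer_name,
                               local_quadratic, slope, svf, vrm)

from conftest import make_grid, plane_grid

INTERIOR = (slice(2, -2), slice(2, -2))


# ---------------------------------------------------------------------------
# Local quadratic fit
# ---------------------------------------------------------------------------

class TestLocalQuadratic:
    def test_plane(self):
        g = plane_grid(7, 7, gx=2.0)
        q = local_quadratic(g)
        assert np.allclose(q["zx"][INTERIOR], 2.0, atol=1e-10)
        assert np.allclose(q["zy"][INTERIOR], 0.0, atol=1e-10)
        for key in ("zxx", "zyy", "zxy"):
            assert np.allclose(q[key][INTERIOR], 0.0, atol=1e-10)

    def test_paraboloid(self):
        nr = nc = 9
        xs = (np.arange(nc) + 0.5)
        ys = nr - (np.arange(nr) + 0.5)
        X, Y = np.meshgrid(xs, ys)
        g = make_grid(X**2 + Y**2)
        q = local_quadratic(g)
        assert np.allclose(q["zxx"][INTERIOR], 2.0, atol=1e-9)
        assert np.allclose(q["zyy"][INTERIOR], 2.0, atol=1e-9)
        assert np.allclose(q["zxy"][INTERIOR], 0.0, atol=1e-9)

    def test_random_patch_matches_normal_equations(self):
        rng = np.random.default_rng(12)
        vals = rng.normal(size=(3, 3))
        px = 2.0
        g = make_grid(vals, px=px)
        q = local_quadratic(g, TerrainParams(fit_window=3))
        # dense least-squares oracle at the centre cell
        rows, zs = [], []
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                x, y = dc * px, -dr * px
                rows.append([x * x, y * y, x * y, x, y, 1.0])
                zs.append(vals[1 + dr, 1 + dc])
        coef, *_ = np.linalg.lstsq(np.array(rows), np.array(zs), rcond=None)
        a, b, c, d, e, _f = coef
        assert q["zx"][1, 1] == pytest.approx(d, abs=1e-10)
        assert q["zy"][1, 1] == pytest.approx(e, abs=1e-10)
        assert q["zxx"][1, 1] == pytest.approx(2 * a, abs=1e-10)
        assert q["zyy"][1, 1] == pytest.approx(2 * b, abs=1e-10)
        assert q["zxy"][1, 1] == pytest.approx(c, abs=1e-10)

    def test_window_larger_than_grid(self):
        from reefscape.grid import RasterError

        with pytest.raises(RasterError):
            local_quadratic(make_grid(np.zeros((3, 3))), TerrainParams(fit_window=5))


# ---------------------------------------------------------------------------
# Slope and aspect
# ---------------------------------------------------------------------------

class TestSlope:
    def test_flat_is_zero(self):
        s = slope(make_grid(np.full((6, 6), -4.0)))
        assert np.allclose(s.values, 0.0)

    def test_unit_gradient(self):
        s = slope(plane_grid(8, 8, gx=1.0))
        assert np.allclose(s.values[INTERIOR], math.atan(1.0), atol=1e-9)
        assert s.values[INTERIOR] == pytest.approx(0.785398, abs=1e-6)

    def test_steep_plane_one_radian(self):
        s = slope(plane_grid(8, 8, gx=math.tan(1.0)))
        assert np.allclose(s.values[INTERIOR], 1.0, atol=1e-9)

    def test_range(self, variables):
        for key, layer in variables.items():
            if key[2] == "SLOPE":
                v = layer.values[layer.valid_mask]
                assert v.min() >= 0.0 and v.max() < math.pi / 2


class TestAspect:
    def test_north_dipping(self):
        east, north = aspect_components(plane_grid(8, 8, gy=-1.0))  # downslope +y
        assert np.allclose(north.values[INTERIOR], 1.0, atol=1e-9)
        assert np.allclose(east.values[INTERIOR], 0.0, atol=1e-9)

    def test_east_dipping(self):
        east, north = aspect_components(plane_grid(8, 8, gx=-1.0))
        assert np.allclose(east.values[INTERIOR], 1.0, atol=1e-9)

    def test_unit_circle_identity(self, variables):
        east = variables[("ACA", 15, "EAST")]
        north = variables[("ACA", 15, "NORTH")]
        both = east.valid_mask & north.valid_mask
        assert both.any()
        ssq = east.values[both] ** 2 + north.values[both] ** 2
        np.testing.assert_allclose(ssq, 1.0, atol=1e-12)

    def test_flat_cells_nodata(self):
        east, north = aspect_components(make_grid(np.zeros((6, 6))))
        assert east.nodata_mask.all() and north.nodata_mask.all()


# ---------------------------------------------------------------------------
# Curvature
# ---------------------------------------------------------------------------

class TestCurvatures:
    def test_plane_zero(self):
        vcu, hcu = curvatures(plane_grid(7, 7, gx=0.3, gy=0.2))
        assert np.allclose(vcu.values[INTERIOR], 0.0, atol=1e-10)
        assert np.allclose(hcu.values[INTERIOR], 0.0, atol=1e-10)

    def test_concave_channel_floor_positive_vcu(self):
        # sloping surface concave upward along the flow direction
        nr = nc = 9
        xs = np.arange(nc) + 0.5
        X = np.tile(xs, (nr, 1))
        g = make_grid(0.05 * X**2 + 0.5 * X)
        vcu, _ = curvatures(g)
        assert (vcu.values[INTERIOR] > 0).all()

    def test_vcu_matches_symbolic_oracle(self):
        # z = x^2 + 3x: the quadratic fit is exact, so VCU at any cell must
        # equal the symbolic profile curvature there
        import sympy

        x, y = sympy.symbols("x y")
        z = x**2 + 3 * x
        zx, zy = z.diff(x), z.diff(y)
        zxx, zyy, zxy = z.diff(x, 2), z.diff(y, 2), z.diff(x).diff(y)
        g2 = zx**2 + zy**2
        vcu_expr = (zxx * zx**2 + 2 * zxy * zx * zy + zyy * zy**2) / (
            g2 * (1 + g2) ** sympy.Rational(3, 2))
        nr = nc = 9
        xs = np.arange(nc) + 0.5
        X = np.tile(xs, (nr, 1))
        g = make_grid(X**2 + 3 * X)
        vcu, _ = curvatures(g)
        for c in range(2, 7):
            expected = float(vcu_expr.subs({x: xs[c], y: 0}))
            assert vcu.values[4, c] == pytest.approx(expected, rel=1e-9)

    def test_sideward_convex_ridge_positive_hcu(self):
        # ridge along x, cross-section convex: contours bulge outward
        nr = nc = 9
        ys = nr - (np.arange(nr) + 0.5)
        xs = np.arange(nc) + 0.5
        X, Y = np.meshgrid(xs, ys)
        g = make_grid(-0.5 * X - 0.1 * (Y - 4.5) ** 2)
        _, hcu = curvatures(g)
        assert (hcu.values[4, 2:7] > 0).all()


# ---------------------------------------------------------------------------
# VRM
# ---------------------------------------------------------------------------

class TestVrm:
    def test_any_plane_zero(self):
        for gx, gy in ((0.0, 0.0), (0.5, 0.0), (0.3, -0.7)):
            v = vrm(plane_grid(9, 9, gx=gx, gy=gy))
            assert np.allclose(v.values[INTERIOR], 0.0, atol=1e-12)

    def test_rugged_surface_approaches_one(self):
        rng = np.random.default_rng(4)
        g = make_grid(rng.normal(scale=1e4, size=(15, 15)))
        v = vrm(g)
        assert np.nanmax(v.values) > 0.7

    def test_bounds(self, variables):
        for key, layer in variables.items():
            if key[2] == "VRM":
                vals = layer.values[layer.valid_mask]
                assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_matches_vector_sum_oracle(self):
        rng = np.random.default_rng(21)
        vals = rng.normal(size=(7, 7))
        g = make_grid(vals, px=2.0)
        params = TerrainParams(vrm_window=3)
        out = vrm(g, params)
        q = local_quadratic(g, params)
        s = np.arctan(np.hypot(q["zx"], q["zy"]))
        az = np.arctan2(-q["zx"], -q["zy"])
        # direct per-cell sum over the 3x3 window (interior cells only)
        for r in range(2, 5):
            for c in range(2, 5):
                nx = ny = nz = 0.0
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        si, ai = s[r + dr, c + dc], az[r + dr, c + dc]
                        nx += math.sin(si) * math.sin(ai)
                        ny += math.sin(si) * math.cos(ai)
                        nz += math.cos(si)
                expected = 1.0 - math.sqrt(nx**2 + ny**2 + nz**2) / 9.0
                assert out.values[r, c] == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# BPI
# ---------------------------------------------------------------------------

class TestBpi:
    def test_flat_zero(self):
        out = bpi(make_grid(np.full((9, 9), -7.0)))
        assert np.allclose(out.values[out.valid_mask], 0.0)

    def test_single_bump_positive(self):
        vals = np.full((9, 9), -5.0)
        vals[4, 4] = -3.0
        out = bpi(make_grid(vals))
        assert out.values[4, 4] > 0

    def test_matches_enumerated_annulus(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(7, 7))
        px = 1.0
        params = TerrainParams(bpi_inner_r=1.0, bpi_outer_r=2.0)
        out = bpi(make_grid(vals, px=px), params)
        r0, c0 = 3, 3
        annulus = []
        for dr in range(-2, 3):
            for dc in range(-2, 3):
                d = math.hypot(dr, dc)
                if 1.0 < d <= 2.0:
                    annulus.append(vals[r0 + dr, c0 + dc])
        expected = vals[r0, c0] - float(np.mean(annulus))
        assert out.values[r0, c0] == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# SVF
# ---------------------------------------------------------------------------

class TestSvf:
    def test_flat_is_one(self):
        out = svf(make_grid(np.full((12, 12), -3.0)))
        assert np.allclose(out.values, 1.0)

    def test_single_wall_closed_form(self):
        # wall of height 1 one cell to the north, 4 azimuths, pixel 1 m
        vals = np.zeros((9, 9))
        vals[3, :] = 1.0  # east-west wall
        params = TerrainParams(svf_azimuths=4, svf_radius=1)
        out = svf(make_grid(vals, px=1.0), params)
        expected = 1.0 - math.sin(math.pi / 4) / 4.0
        assert out.values[4, 4] == pytest.approx(expected, abs=1e-12)

    def test_deep_pit_approaches_zero(self):
        vals = np.zeros((11, 11))
        vals[5, 5] = -500.0
        params = TerrainParams(svf_azimuths=8, svf_radius=3)
        out = svf(make_grid(vals, px=1.0), params)
        assert out.values[5, 5] < 0.05

    def test_bounds(self, variables):
        for key, layer in variables.items():
            if key[2] == "SVF":
                vals = layer.values[layer.valid_mask]
                assert vals.min() >= 0.0 and vals.max() <= 1.0


# ---------------------------------------------------------------------------
# Translation invariance
# ---------------------------------------------------------------------------

class TestTranslationInvariance:
    def test_attributes_unchanged_depth_shifts(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(scale=2.0, size=(12, 12)) - 5.0
        g1 = make_grid(vals, px=5.0)
        g2 = make_grid(vals + 3.7, px=5.0)
        pairs = [
            (slope(g1).values, slope(g2).values),
            (vrm(g1).values, vrm(g2).values),
            (bpi(g1).values, bpi(g2).values),
            (svf(g1).values, svf(g2).values),
        ]
        e1, n1 = aspect_components(g1)
        e2, n2 = aspect_components(g2)
        v1, h1 = curvatures(g1)
        v2, h2 = curvatures(g2)
        pairs += [(e1.values, e2.values), (n1.values, n2.values),
                  (v1.values, v2.values), (h1.values, h2.values)]
        for a, b in pairs:
            np.testing.assert_allclose(a, b, atol=1e-9, equal_nan=True)


# ---------------------------------------------------------------------------
# Stack assembly
# ---------------------------------------------------------------------------

class TestDeriveAll:
    def test_72_layers(self, variables):
        assert len(variables) == 72

    def test_single_dem_nine_layers(self, dem_stack):
        sub = MultiscaleStack(levels={("DR100", 100): dem_stack[("DR100", 100)]})
        out = derive_all(sub)
        assert len(out) == 9

    def test_keys_exhaustive(self, variables, dem_stack):
        expected = {(src, res, var) for (src, res) in dem_stack.keys()
                    for var in ("DEPTH", "SLOPE", "EAST", "NORTH", "VCU", "HCU",
                                "VRM", "BPI", "SVF")}
        assert set(variables.keys()) == expected

    def test_depth_is_the_dem(self, variables, dem_stack):
        assert np.array_equal(variables[("ACA", 30, "DEPTH")].values,
                              dem_stack[("ACA", 30)].values)


# ---------------------------------------------------------------------------
# Cross-source comparison
# ---------------------------------------------------------------------------

class TestCompareSources:
    def _single_layer_stack(self, grid, src):
        vs = VariableStack()
        vs.layers[(src, int(grid.pixel_size), "DEPTH")] = grid
        return vs

    def test_identical_stacks(self):
        rng = np.random.default_rng(1)
        g = make_grid(rng.normal(size=(10, 10)), px=30.0)
        a = self._single_layer_stack(g, "ACA")
        b = self._single_layer_stack(g.copy(), "DR30")
        rep = compare_sources(a, b, n_points=50, seed=0)
        assert np.allclose(rep["r_s"], 1.0)
        assert rep["flagged"].all()

    def test_monotone_transform(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(10, 10))
        a = self._single_layer_stack(make_grid(vals, px=30.0), "ACA")
        b = self._single_layer_stack(make_grid(np.exp(vals), px=30.0), "DR30")
        rep = compare_sources(a, b, n_points=50, seed=0)
        assert np.allclose(rep["r_s"], 1.0)

    def test_matches_rank_oracle(self):
        rng = np.random.default_rng(3)
        va = rng.normal(size=20)
        vb = rng.normal(size=20)
        a = self._single_layer_stack(make_grid(va.reshape(4, 5), px=30.0), "ACA")
        b = self._single_layer_stack(make_grid(vb.reshape(4, 5), px=30.0), "DR30")
        rep = compare_sources(a, b, n_points=20, seed=0)
        # brute-force Spearman: Pearson correlation of midranks
        ra = stats.rankdata(va)
        rb = stats.rankdata(vb)
        expected = float(np.corrcoef(ra, rb)[0, 1])
        assert rep["r_s"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_sample_size_cap(self, variables):
        rep = compare_sources(variables, variables, n_points=10, seed=1)
        assert (rep["n_points"] <= 10).all()
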