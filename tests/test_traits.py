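import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import least_squares
from scipy.spatial import ConvexHull

from tlsmorph import (
    StemInventory,
    TreeCloud,
    TreeParams,
    branch_ratios,
    canopy_area,
    crown_base,
    dbh,
    fit_circle_taubin,
    graham_hull,
    lai,
    lai_from_profile,
    make_tree,
    percent_cover,
    polygon_area,
    tdr,
    tree_height,
)
from tlsmorph.traits import GapProfile

from conftest import circle_points


def rotate_z(points, angle):
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
    return points @ rot.T


class TestHeight:
    def test_recovers_generator_height(self, standard_tree):
        params, cloud, truth = standard_tree
        assert tree_height(cloud) == pytest.approx(truth.height, abs=params.trunk_point_spacing)

    def test_rotation_invariant(self, standard_tree):
        _, cloud, _ = standard_tree
        rotated = TreeCloud(points=rotate_z(cloud.points, 0.7))
        assert tree_height(rotated) == pytest.approx(tree_height(cloud), abs=1e-9)

    def test_two_points(self):
        cloud = TreeCloud(points=np.array([[0, 0, 0], [0, 0, 5.5]], dtype=float))
        assert tree_height(cloud) == 5.5

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            tree_height(TreeCloud(points=np.array([[0.0, 0.0, 1.0]])))


def geometric_circle_fit(pts, guess):
    """Oracle: iterative orthogonal-distance (geometric) circle fit."""

    def residual(p):
        return np.hypot(pts[:, 0] - p[0], pts[:, 1] - p[1]) - p[2]

    return least_squares(residual, guess).x


class TestTaubinCircle:
    def test_exact_circle_recovered_to_1e9(self):
        pts = circle_points(1.0, 2.0, 0.15, n=100)
        cx, cy, r = fit_circle_taubin(pts)
        assert (cx, cy, r) == pytest.approx((1.0, 2.0, 0.15), abs=1e-9)

    def test_noisy_circle_matches_geometric_fit(self):
        pts = circle_points(1.0, 2.0, 0.15, n=200, noise=0.005, seed=5)
        cx, cy, r = fit_circle_taubin(pts)
        assert r == pytest.approx(0.15, abs=0.005)
        gx, gy, gr = geometric_circle_fit(pts, (cx, cy, r))
        assert abs(r - gr) / gr < 1e-3

    def test_three_points_give_circumcircle(self):
        # right triangle inscribed in a circle: hypotenuse is the diameter
        pts = np.array([[0.0, 0.0], [4.0, 0.0], [0.0, 3.0]])
        cx, cy, r = fit_circle_taubin(pts)
        assert (cx, cy, r) == pytest.approx((2.0, 1.5, 2.5), abs=1e-9)

    def test_partial_arc_nearly_unbiased(self):
        angles = np.linspace(0.0, np.pi / 2, 60)  # quarter arc only
        pts = np.column_stack([0.5 * np.cos(angles), 0.5 * np.sin(angles)])
        _, _, r = fit_circle_taubin(pts)
        assert r == pytest.approx(0.5, abs=1e-9)

    def test_collinear_rejected(self):
        pts = np.column_stack([np.linspace(0, 1, 10), np.linspace(0, 2, 10)])
        with pytest.raises(ValueError, match="collinear"):
            fit_circle_taubin(pts)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_circle_taubin(np.array([[0.0, 0.0], [1.0, 1.0]]))


class TestDbh:
    def test_single_stem_exact(self, standard_tree):
        _, cloud, truth = standard_tree
        d, per_stem = dbh(cloud)
        assert d == pytest.approx(truth.dbh, abs=1e-6)
        assert len(per_stem) == 1

    def test_two_stem_fixture(self):
        cloud, _ = make_tree(TreeParams(stem_diameters_1m=(0.10, 0.06), seed=2))
        d, per_stem = dbh(cloud)
        assert d == pytest.approx(0.10, abs=1e-6)
        assert sorted(per_stem) == pytest.approx([0.06, 0.10], abs=1e-6)

    def test_empty_slice_rejected(self):
        pts = np.array([[0, 0, 0], [0, 0, 0.5], [0, 0, 5.0]], dtype=float)
        with pytest.raises(ValueError, match="breast height"):
            dbh(TreeCloud(points=pts), slice_halfwidth=0.0)


class TestGrahamHull:
    def test_square_with_interior_point(self):
        pts = np.array([[0, 0], [2, 0], [2, 2], [0, 2], [1, 1]], dtype=float)
        hull = graham_hull(pts)
        assert len(hull.vertices) == 4
        assert polygon_area(hull) == pytest.approx(4.0)

    def test_matches_qhull_on_random_sets(self, rng):
        for _ in range(100):
            pts = rng.uniform(-1, 1, size=(200, 2))
            ours = {tuple(v) for v in graham_hull(pts).vertices}
            qhull = {tuple(pts[i]) for i in ConvexHull(pts).vertices}
            assert ours == qhull

    def test_matches_triangle_elimination_oracle(self, rng):
        # brute force: a point is interior iff it lies inside some triangle
        # of three other points; hull vertices are the non-interior points
        def oracle(pts):
            keep = []
            for i, p in enumerate(pts):
                others = np.delete(pts, i, axis=0)
                interior = False
                def cross2(u, v):
                    return u[0] * v[1] - u[1] * v[0]

                for a, b, c in itertools.combinations(range(len(others)), 3):
                    pa, pb, pc = others[a], others[b], others[c]
                    d1 = cross2(pb - pa, p - pa)
                    d2 = cross2(pc - pb, p - pb)
                    d3 = cross2(pa - pc, p - pc)
                    if (d1 >= 0 and d2 >= 0 and d3 >= 0) or (d1 <= 0 and d2 <= 0 and d3 <= 0):
                        interior = True
                        break
                if not interior:
                    keep.append(tuple(p))
            return set(keep)

        for _ in range(10):
            pts = rng.uniform(-1, 1, size=(18, 2))
            assert {tuple(v) for v in graham_hull(pts).vertices} == oracle(pts)

    def test_idempotent(self, rng):
        pts = rng.uniform(size=(50, 2))
        hull = graham_hull(pts)
        again = graham_hull(hull.vertices)
        assert {tuple(v) for v in again.vertices} == {tuple(v) for v in hull.vertices}

    def test_counter_clockwise_and_convex(self, rng):
        verts = graham_hull(rng.uniform(size=(40, 2))).vertices
        rolled = np.roll(verts, -1, axis=0)
        rolled2 = np.roll(verts, -2, axis=0)
        cross = (rolled[:, 0] - verts[:, 0]) * (rolled2[:, 1] - verts[:, 1]) - (
            rolled[:, 1] - verts[:, 1]
        ) * (rolled2[:, 0] - verts[:, 0])
        assert np.all(cross > 0)

    def test_collinear_rejected(self):
        pts = np.column_stack([np.arange(5.0), 2.0 * np.arange(5.0)])
        with pytest.raises(ValueError, match="collinear"):
            graham_hull(pts)


class TestPolygonArea:
    @pytest.mark.parametrize(
        "verts,area",
        [
            ([[0, 0], [1, 0], [0, 1]], 0.5),
            ([[0, 0], [1, 0], [1, 1], [0, 1]], 1.0),
        ],
    )
    def test_known_areas(self, verts, area):
        assert polygon_area(np.asarray(verts, dtype=float)) == pytest.approx(area)

    def test_rigid_motion_invariant(self, rng):
        verts = graham_hull(rng.uniform(size=(30, 2))).vertices
        a0 = polygon_area(verts)
        c, s = np.cos(1.1), np.sin(1.1)
        moved = verts @ np.array([[c, -s], [s, c]]).T + [10.0, -4.0]
        assert polygon_area(moved) == pytest.approx(a0, abs=1e-12)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            polygon_area(np.array([[0.0, 0.0], [1.0, 1.0]]))


class TestCrownBase:
    def test_recovers_generator_crown_base(self, standard_tree):
        _, cloud, truth = standard_tree
        assert abs(crown_base(cloud, layer=0.25) - truth.crown_base) <= 0.25

    def test_crown_reaching_ground(self):
        params = TreeParams(
            height=5.0, crown_base=0.0, dbh=0.15, crown_semi_axes=(2.0, 2.0, 2.5),
            leaf_point_count=20000, seed=6,
        )
        cloud, _ = make_tree(params)
        # the area-threshold detector resolves the base to one layer
        assert crown_base(cloud) <= 0.25

    def test_pure_trunk_warns(self):
        cloud, _ = make_tree(TreeParams(leaf_point_count=0, seed=7))
        with pytest.warns(UserWarning):
            assert crown_base(cloud) == 0.0

    def test_too_short_cloud_rejected(self, rng):
        pts = rng.uniform(0, 0.5, size=(100, 3))
        with pytest.raises(ValueError, match="4 layers"):
            crown_base(TreeCloud(points=pts))


class TestCanopyArea:
    def test_ellipsoid_crown_area(self, standard_tree):
        _, cloud, truth = standard_tree
        ca = canopy_area(cloud, crown_base=3.0)
        assert ca == pytest.approx(truth.ca, rel=0.05)

    def test_layer_thickness_insensitive(self, standard_tree):
        _, cloud, _ = standard_tree
        a = canopy_area(cloud, crown_base=3.0, layer=0.5)
        b = canopy_area(cloud, crown_base=3.0, layer=1.0)
        assert abs(a - b) / a < 0.05

    def test_planar_canopy(self):
        plane = np.column_stack([np.random.default_rng(0).uniform(0, 2, (500, 2)), np.full(500, 4.0)])
        trunk = np.column_stack([np.zeros((10, 2)), np.linspace(0, 3.9, 10)])
        cloud = TreeCloud(points=np.vstack([trunk, plane]))
        ca = canopy_area(cloud, crown_base=3.95)
        hull_area = polygon_area(graham_hull(plane[:, :2]))
        assert ca == pytest.approx(hull_area)

    def test_no_canopy_points_rejected(self, standard_tree):
        _, cloud, _ = standard_tree
        with pytest.raises(ValueError):
            canopy_area(cloud, crown_base=100.0)


class TestLai:
    def test_beer_lambert_arithmetic(self):
        profile = GapProfile(
            zenith_bins=[(0.0, np.exp(-1.0), 100)], clumping=1.0, g_function=0.5
        )
        assert lai_from_profile(profile) == pytest.approx(2.0)

    def test_poisson_medium_recovery(self):
        # leaf-only pancake crown = homogeneous Poisson slab; the analytic
        # attenuation per meter is lambda = N pi r_beam^2 / V, so the
        # Beer-Lambert LAI over slab thickness 2 rz is lambda * 2 rz / G
        rx = ry = 6.0
        rz, base = 0.75, 2.0
        volume = 4.0 / 3.0 * np.pi * rx * ry * rz
        r_beam, lam = 0.02, 0.4
        n = int(lam * volume / (np.pi * r_beam ** 2))
        gen = np.random.default_rng(5)
        dirs = gen.normal(size=(n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pts = dirs * gen.uniform(size=(n, 1)) ** (1.0 / 3.0) * [rx, ry, rz]
        pts[:, 2] += base + rz
        cloud = TreeCloud(points=pts, normalized=True)
        est, profile = lai(
            cloud, (0.0, 0.0, 0.0), zenith_edges=np.radians([0, 10, 20, 30]),
            beam_radius=r_beam,
        )
        analytic = lam * 2.0 * rz / 0.5
        assert est == pytest.approx(analytic, rel=0.15)
        assert all(0.0 < p <= 1.0 for _, p, _ in profile.zenith_bins)

    def test_empty_crown_gives_zero(self, standard_tree):
        _, cloud, _ = standard_tree
        est, profile = lai(cloud, (0.0, 0.0, 0.0), crown_base_z=50.0)
        assert est == 0.0
        assert all(p == 1.0 for _, p, _ in profile.zenith_bins)

    def test_saturated_bins_excluded_then_error(self):
        profile = GapProfile(
            zenith_bins=[(0.0, 0.0, 10), (0.3, 0.5, 10)], clumping=1.0, g_function=0.5
        )
        with pytest.warns(UserWarning, match="saturated"):
            est = lai_from_profile(profile)
        assert est > 0
        with pytest.raises(ValueError, match="saturated"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lai_from_profile(
                    GapProfile(zenith_bins=[(0.0, 0.0, 10)], clumping=1.0, g_function=0.5)
                )


class TestTdr:
    @pytest.mark.parametrize(
        "diameters,expected",
        [
            ((0.10,), 1.0),
            ((0.10, 0.05, 0.05), 6.0),
            ((0.2, 0.2, 0.2, 0.2), 16.0),  # n equal stems -> n^2
        ],
    )
    def test_formula(self, diameters, expected):
        assert tdr(StemInventory(diameters)) == pytest.approx(expected)

    def test_lower_bound_is_stem_count(self, rng):
        for _ in range(20):
            d = tuple(rng.uniform(0.02, 0.4, size=rng.integers(1, 6)))
            value = tdr(StemInventory(d))
            assert value >= len(d) - 1e-12
            assert (value == pytest.approx(1.0)) == (len(d) == 1)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            StemInventory(())


class TestBranchRatios:
    def test_totals_convention(self):
        table = pd.DataFrame(
            {
                "branch_id": ["f1", "f2", "s1", "s2", "s3", "s4"],
                "order": [1, 1, 2, 2, 2, 2],
                "length_m": [2.0, 2.0, 1.0, 1.0, 1.0, 1.0],
                "parent_id": [None, None, "f1", "f1", "f2", "f2"],
            }
        )
        sl_fl, sc_fc = branch_ratios(table)
        assert sl_fl == 1.0 and sc_fc == 2.0

    def test_no_second_order(self):
        table = pd.DataFrame(
            {"branch_id": ["f1"], "order": [1], "length_m": [3.0], "parent_id": [None]}
        )
        assert branch_ratios(table) == (0.0, 0.0)

    def test_duplicate_ids_rejected(self):
        table = pd.DataFrame(
            {
                "branch_id": ["f1", "f1"],
                "order": [1, 2],
                "length_m": [2.0, 1.0],
                "parent_id": [None, "f1"],
            }
        )
        with pytest.raises(ValueError, match="duplicate"):
            branch_ratios(table)


class TestPercentCover:
    def test_known_footprint(self):
        # 16 distinct cells with canopy returns in a 50 x 50 grid
        cells = [(i, j) for i in range(4) for j in range(4)]
        pts = np.array([[0.25 + 0.5 * i, 0.25 + 0.5 * j, 3.0] for i, j in cells])
        cover = percent_cover([TreeCloud(points=pts)])
        assert cover == pytest.approx(16 / 2500 * 100)

    def test_full_cover(self):
        xs = np.arange(0.25, 25.0, 0.5)
        grid = np.array([[x, y, 5.0] for x in xs for y in xs])
        assert percent_cover([TreeCloud(points=grid)]) == 100.0

    def test_min_height_above_all_points(self, standard_tree):
        _, cloud, _ = standard_tree
        assert percent_cover([cloud], min_h=100.0) == 0.0
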