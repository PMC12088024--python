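"""Centerlines, MIS radii, branch metrics and cohort statistics."""

import numpy as np
import pandas as pd
import pytest

from archflow.mesh import structured_tube_mesh
from archflow.vessel_geometry import (Centerline, GeometryError,
                                      branch_metrics, branch_volume,
                                      compare_groups, extract_centerline)

R, L = 0.05, 1.0


@pytest.fixture(scope="module")
def cylinder_mesh():
    return structured_tube_mesh(R, L, h=R / 3, axial_h=L / 24)


@pytest.fixture(scope="module")
def cylinder_centerline(cylinder_mesh):
    return extract_centerline(cylinder_mesh, "inlet", "outlet")


class TestCenterline:
    def test_cylinder_axis_and_radius(self, cylinder_centerline):
        cl = cylinder_centerline
        assert np.abs(cl.points[:, :2]).max() < 0.05 * R
        interior = cl.radii[2:-2]
        assert np.abs(interior - R).max() / R < 0.03

    def test_straight_tortuosity_and_diameter(self, cylinder_centerline,
                                              cylinder_mesh):
        bm = branch_metrics(cylinder_centerline, cylinder_mesh)
        assert bm.tortuosity < 0.01
        assert bm.avg_diameter == pytest.approx(2 * R, rel=0.03)
        assert bm.ellipse_ratio == pytest.approx(1.0, abs=0.05)

    def test_stenosed_min_radius(self):
        m = structured_tube_mesh(R, L, h=R / 3, axial_h=L / 48,
                                 stenosis=(0.5, 0.3, 0.5))
        cl = extract_centerline(m, "inlet", "outlet")
        assert cl.radii.min() == pytest.approx(0.5 * R, rel=0.03)

    def test_elliptical_cross_section_ratio(self):
        m = structured_tube_mesh(R, L, h=R / 5, axial_h=L / 16,
                                 ellipticity=0.5)
        cl = extract_centerline(m, "inlet", "outlet")
        bm = branch_metrics(cl, m)
        assert bm.ellipse_ratio == pytest.approx(0.5, abs=0.05)

    def test_rigid_motion_invariance(self, cylinder_mesh,
                                     cylinder_centerline):
        from archflow.mesh import from_p1, tag_boundaries
        theta = 0.7
        Rm = np.array([[np.cos(theta), -np.sin(theta), 0],
                       [np.sin(theta), np.cos(theta), 0],
                       [0, 0, 1.0]])
        Rx = np.array([[1.0, 0, 0], [0, 0, -1.0], [0, 1.0, 0]])
        Q = Rx @ Rm
        t = np.array([0.3, -0.2, 0.9])
        verts = cylinder_mesh.vertices[:cylinder_mesh.n_p1] @ Q.T + t
        m2 = from_p1(verts, cylinder_mesh.cells[:, :4],
                     element_size=cylinder_mesh.element_size)
        axis = Q @ np.array([0, 0, 1.0])
        lo = t @ axis
        m2 = tag_boundaries(m2, {
            "inlet": lambda c, n: (c @ axis) < lo + 1e-6,
            "outlet": lambda c, n: (c @ axis) > lo + L - 1e-6,
            "wall": lambda c, n: ((c @ axis) >= lo + 1e-6)
                                 & ((c @ axis) <= lo + L - 1e-6)})
        cl2 = extract_centerline(m2, "inlet", "outlet")
        assert cl2.radii[2:-2].mean() == pytest.approx(
            cylinder_centerline.radii[2:-2].mean(), rel=0.01)

    def test_disconnected_endpoints_raise(self, cylinder_mesh):
        with pytest.raises((GeometryError, KeyError)):
            extract_centerline(cylinder_mesh, "inlet", "nonexistent")

    def test_degenerate_centerline_rejected(self):
        cl = Centerline(points=np.zeros((1, 3)), radii=np.zeros(1),
                        source="a", target="b")
        with pytest.raises(GeometryError, match="degenerate"):
            branch_metrics(cl)


class TestSemicircularSegment:
    @pytest.fixture(scope="class")
    def torus_mesh(self):
        """Half-torus tube built from the implicit branch machinery."""
        from skimage.measure import marching_cubes

        from archflow.mesh import tag_boundaries, tetrahedralize
        from archflow.phantoms import Branch, TaggedSurface
        Rc, r = 0.3, 0.05
        th = np.linspace(0, np.pi, 65)
        pts = np.column_stack([Rc * np.cos(th), Rc * np.sin(th),
                               np.zeros_like(th)])
        br = Branch("torus", 1, pts, np.full(len(th), r))

        def sdf(p):
            return np.maximum(br.sdf(p), -np.asarray(p)[:, 1])

        pitch = 0.012
        lo = pts.min(0) - 0.1
        hi = pts.max(0) + 0.1
        axes = [np.arange(lo[d], hi[d] + pitch, pitch) for d in range(3)]
        g = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
        vals = sdf(g.reshape(-1, 3)).reshape(g.shape[:3])
        v, f, _, _ = marching_cubes(vals, 0.0, spacing=(pitch,) * 3)
        surf = TaggedSurface(vertices=v + lo, faces=f,
                             face_tags=np.ones(len(f), dtype=np.int64),
                             tag_names={1: "wall"}, sdf=sdf)
        m = tetrahedralize(surf, target_h=0.016)

        def near(c, x0):
            return (np.abs(c[:, 1]) < 0.01) & (np.abs(c[:, 0] - x0) < 0.1)

        return tag_boundaries(m, {
            "inlet": lambda c, n: near(c, Rc),
            "outlet": lambda c, n: near(c, -Rc),
            "wall": lambda c, n: ~(near(c, Rc) | near(c, -Rc))})

    def test_arc_length_and_tortuosity(self, torus_mesh):
        cl = extract_centerline(torus_mesh, "inlet", "outlet",
                                smooth_window=9)
        bm = branch_metrics(cl, torus_mesh)
        assert bm.length == pytest.approx(np.pi * 0.3, rel=0.02)
        assert bm.tortuosity == pytest.approx(np.pi / 2 - 1, abs=0.02)
        assert bm.mean_curvature == pytest.approx(1 / 0.3, rel=0.25)


class TestBranchVolume:
    def test_cylinder_volume(self):
        m = structured_tube_mesh(R, L, h=R / 6, axial_h=L / 8)
        m.region_tags = np.ones(len(m.cells), dtype=np.int64)
        assert branch_volume(m, 1) == pytest.approx(np.pi * R * R * L,
                                                    rel=0.01)

    def test_halves_sum_to_whole(self, cylinder_mesh):
        m = cylinder_mesh
        cen = m.vertices[m.cells[:, :4]].mean(axis=1)
        m.region_tags = np.where(cen[:, 2] < L / 2, 1, 2)
        total = branch_volume(m, 1) + branch_volume(m, 2)
        assert total == pytest.approx(m.total_volume(), rel=1e-10)

    def test_empty_region_raises(self, cylinder_mesh):
        cylinder_mesh.region_tags = np.ones(len(cylinder_mesh.cells),
                                            dtype=np.int64)
        with pytest.raises(GeometryError, match="empty"):
            branch_volume(cylinder_mesh, 99)


class TestCompareGroups:
    def test_f_equals_t_squared_for_two_groups(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.0, 1.0, 12)
        b = rng.normal(0.5, 1.0, 15)
        tab = pd.DataFrame({"v": np.concatenate([a, b]),
                            "g": ["a"] * 12 + ["b"] * 15})
        res = compare_groups(tab, "v", "g")
        from scipy.stats import ttest_ind
        t, p = ttest_ind(a, b)
        assert res.F == pytest.approx(t ** 2, abs=1e-9)
        assert res.p_value == pytest.approx(p, abs=1e-9)

    def test_matches_manual_sums_of_squares(self):
        # 3 groups x 3 observations, hand-checkable ANOVA arithmetic
        data = {"a": [1.0, 2.0, 3.0], "b": [2.0, 3.0, 4.0],
                "c": [5.0, 6.0, 7.0]}
        rows = [(v, g) for g, vals in data.items() for v in vals]
        tab = pd.DataFrame(rows, columns=["v", "g"])
        grand = tab.v.mean()
        ss_between = sum(3 * (np.mean(v) - grand) ** 2
                         for v in data.values())
        ss_within = sum(((np.array(v) - np.mean(v)) ** 2).sum()
                        for v in data.values())
        F_manual = (ss_between / 2) / (ss_within / 6)
        res = compare_groups(tab, "v", "g")
        assert res.F == pytest.approx(F_manual, abs=1e-12)
        assert res.df_between == 2 and res.df_within == 6
        assert len(res.tukey) == 3

    def test_stars_thresholds(self):
        tab = pd.DataFrame({"v": [1, 2, 1, 2, 10, 11, 10, 11.0],
                            "g": ["a"] * 4 + ["b"] * 4})
        res = compare_groups(tab, "v", "g")
        assert res.stars() == "***"
        assert res.stars(0.03) == "*" and res.stars(0.2) == "ns"

    def test_insufficient_data_raises(self):
        tab = pd.DataFrame({"v": [1.0, 2.0], "g": ["a", "a"]})
        with pytest.raises(GeometryError):
            compare_groups(tab, "v", "g")
        tab2 = pd.DataFrame({"v": [1.0, 2.0, 3.0], "g": ["a", "a", "b"]})
        with pytest.raises(GeometryError):
            compare_groups(tab2, "v", "g")
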