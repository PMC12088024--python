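"""Streamline integration, seeding, classification and ordering scores."""

import numpy as np
import pytest

from archflow.streamlines import (CallableField, FrozenField,
                                  StreamlineBundle, StreamlineError,
                                  classify_by_branch, ordering_analysis,
                                  seed_cross_section, trace_streamlines)
from conftest import L_TUBE, R_TUBE


class TestTraceAnalytic:
    def test_uniform_field_straight_lines(self):
        field = CallableField(lambda p: np.tile([0.0, 0.0, 1.0],
                                                (len(p), 1)))
        seeds = np.array([[0.1, 0.2, 0.0], [0.0, -0.1, 0.0]])
        b = trace_streamlines(field, seeds, step=0.1, max_length=1.0)
        for pl, s in zip(b.polylines, seeds):
            np.testing.assert_allclose(pl[:, :2], np.tile(s[:2],
                                                          (len(pl), 1)),
                                       atol=1e-12)
            assert pl[-1, 2] == pytest.approx(1.0, abs=0.11)

    def test_rk4_circle_drift(self):
        # rigid rotation u = omega x r: orbits are circles of radius 1
        field = CallableField(
            lambda p: np.column_stack([-p[:, 1], p[:, 0],
                                       np.zeros(len(p))]))
        r = 1.0
        step = r / 100
        b = trace_streamlines(field, np.array([[r, 0.0, 0.0]]), step=step,
                              max_length=2 * np.pi * r)
        radii = np.linalg.norm(b.polylines[0][:, :2], axis=1)
        assert np.abs(radii - r).max() / r < 1e-4

    def test_stagnant_seed_terminates_immediately(self):
        field = CallableField(
            lambda p: np.column_stack([np.zeros(len(p)), np.zeros(len(p)),
                                       np.maximum(p[:, 2], 0.0)]))
        b = trace_streamlines(field, np.array([[0.0, 0.0, -1.0],
                                               [0.0, 0.0, 0.5]]),
                              step=0.1, max_length=1.0)
        assert b.termination[0] == "stagnation"
        assert len(b.polylines[0]) == 1
        assert b.termination[1] == "max_length"

    def test_step_validation(self):
        field = CallableField(lambda p: np.ones((len(p), 3)))
        with pytest.raises(StreamlineError):
            trace_streamlines(field, np.zeros((1, 3)), step=0.0,
                              max_length=1.0)

    def test_step_halving_converges(self):
        field = CallableField(
            lambda p: np.column_stack([-p[:, 1], p[:, 0],
                                       0.2 * np.ones(len(p))]))
        seeds = np.array([[1.0, 0.0, 0.0]])
        ends = []
        for step in (0.02, 0.01):
            b = trace_streamlines(field, seeds, step=step, max_length=3.0)
            ends.append(b.polylines[0][-1])
        assert np.linalg.norm(ends[1] - ends[0]) < 1e-3


class TestSeeding:
    def test_seeds_interior_and_deterministic(self, tube_mesh_coarse):
        s1 = seed_cross_section(tube_mesh_coarse, (0, 0, 0.5), (0, 0, 1),
                                50, seed=11)
        s2 = seed_cross_section(tube_mesh_coarse, (0, 0, 0.5), (0, 0, 1),
                                50, seed=11)
        np.testing.assert_array_equal(s1, s2)
        r = np.hypot(s1[:, 0], s1[:, 1])
        assert r.max() < R_TUBE
        np.testing.assert_allclose(s1[:, 2], 0.5, atol=1e-9)

    def test_elliptical_section_moments(self):
        from archflow.mesh import structured_tube_mesh
        m = structured_tube_mesh(R_TUBE, L_TUBE, h=R_TUBE / 5,
                                 axial_h=L_TUBE / 6, ellipticity=0.5)
        seeds = seed_cross_section(m, (0, 0, 0.5), (0, 0, 1), 300, seed=0,
                                   wall_margin=1e-4)
        cov = np.cov(seeds[:, :2].T)
        evals = np.sort(np.linalg.eigvalsh(cov))
        ratio = np.sqrt(evals[0] / evals[1])
        assert ratio == pytest.approx(0.5, abs=0.05)

    def test_plane_outside_lumen_raises(self, tube_mesh_coarse):
        with pytest.raises(StreamlineError):
            seed_cross_section(tube_mesh_coarse, (0, 0, 5.0), (0, 0, 1), 10)


class TestFrozenFieldOracle:
    def test_matches_fine_explicit_euler(self, poiseuille_coarse):
        """RK4 arc-length streamlines vs a brute-force explicit Euler
        tracker at 1/100 of the step on the same frozen field."""
        field = FrozenField(poiseuille_coarse, 0)
        seeds = seed_cross_section(poiseuille_coarse.mesh, (0, 0, 0.2),
                                   (0, 0, 1), 5, seed=2,
                                   wall_margin=0.01)
        step = 0.02
        b = trace_streamlines(field, seeds, step=step, max_length=0.5)
        for pl, seed in zip(b.polylines, seeds):
            x = seed.copy()
            n_fine = int(round(0.5 / (step / 100)))
            for _ in range(n_fine):
                u, ok = field(x[None])
                if not ok[0] or np.linalg.norm(u) < 1e-300:
                    break
                x = x + (step / 100) * u[0] / np.linalg.norm(u)
            assert np.linalg.norm(pl[-1] - x) < 1e-3

    def test_wall_seed_stagnates(self, poiseuille_coarse):
        field = FrozenField(poiseuille_coarse, 0)
        wall_pt = np.array([[R_TUBE * 0.9999, 0.0, 0.5]])
        b = trace_streamlines(field, wall_pt, step=0.02, max_length=1.0)
        assert b.termination[0] in ("stagnation", "left_domain")


class TestClassification:
    def test_majority_arc_length_label(self):
        # synthetic classifier: region = 1 for z<0.5 else 2
        def classify(pts):
            return np.where(pts[:, 2] < 0.5, 1, 2)

        z = np.linspace(0, 0.7, 21)   # 0.5 of arc in region 1, 0.2 in 2
        pl_mixed = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
        bundle = StreamlineBundle(polylines=[pl_mixed],
                                  seed_ids=np.array([0]),
                                  termination=["outlet"])
        labels = classify_by_branch(bundle, classify, [1, 2])
        assert labels[0] == 1

    def test_unvisited_regions_unlabeled(self):
        pl = np.column_stack([np.zeros(5), np.zeros(5),
                              np.linspace(0, 0.4, 5)])
        bundle = StreamlineBundle(polylines=[pl], seed_ids=np.array([0]),
                                  termination=["outlet"])
        labels = classify_by_branch(bundle, lambda p: np.zeros(len(p)),
                                    [1, 2])
        assert labels[0] == -1


class TestOrdering:
    def test_straight_tube_order_preserved(self, poiseuille_coarse):
        field = FrozenField(poiseuille_coarse, 0)
        seeds = seed_cross_section(poiseuille_coarse.mesh, (0, 0, 0.1),
                                   (0, 0, 1), 24, seed=5,
                                   wall_margin=0.005)
        b = trace_streamlines(field, seeds, step=0.02, max_length=2.0,
                              mesh=poiseuille_coarse.mesh)
        rep = ordering_analysis(b, ((0, 0, 0.2), (0, 0, 1)),
                                ((0, 0, 0.8), (0, 0, 1)),
                                lateral_hint=(1, 0, 0))
        assert rep.kendall_tau == pytest.approx(1.0)

    def test_constructed_crossing_detected(self):
        # two stream tubes swapped between the planes: rank correlation < 1
        lines = []
        for x0, x1 in [(-1.0, 1.0), (1.0, -1.0), (0.0, 0.0)]:
            z = np.linspace(0, 1, 11)
            x = x0 + (x1 - x0) * z
            lines.append(np.column_stack([x, np.zeros_like(z), z]))
        bundle = StreamlineBundle(polylines=lines,
                                  seed_ids=np.arange(3),
                                  termination=["outlet"] * 3)
        rep = ordering_analysis(bundle, ((0, 0, 0.05), (0, 0, 1)),
                                ((0, 0, 0.95), (0, 0, 1)),
                                lateral_hint=(1, 0, 0))
        assert rep.kendall_tau < 1.0

    def test_too_few_common_streamlines(self):
        pl = np.column_stack([np.zeros(3), np.zeros(3),
                              np.linspace(0, 1, 3)])
        bundle = StreamlineBundle(polylines=[pl], seed_ids=np.array([0]),
                                  termination=["outlet"])
        with pytest.raises(StreamlineError, match="cross both planes"):
            ordering_analysis(bundle, ((0, 0, 0.1), (0, 0, 1)),
                              ((0, 0, 0.9), (0, 0, 1)))
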