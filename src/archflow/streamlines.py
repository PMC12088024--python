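"""Streamline seeding, integration, branch classification and ordering.

Streamlines are integral curves of a *frozen* velocity snapshot (the
per-phase fields of pulsatile runs), integrated with classical RK4 on the
arc-length-normalized field dx/ds = u/|u| so geometric resolution is
uniform regardless of speed.  Tracing through each aortic arch and
comparing cross-section positions upstream (outflow tract) and downstream
(dorsal aorta) quantifies how well laminar flow preserves the spatial
order of the arch streams: a Kendall rank correlation of the lateral
ordering plus the fraction of branch-adjacency relations preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import kendalltau

from . import fem
from .mesh import WALL, VolumeMesh
from .solver import SolutionSeries


class StreamlineError(ValueError):
    pass


# ---------------------------------------------------------------------------
# velocity fields
# ---------------------------------------------------------------------------

class FrozenField:
    """P2-interpolated velocity snapshot of a stored solution step.

    Evaluation is in mesh coordinates (mm); velocities keep their SI
    magnitude (m/s) -- only the direction matters for streamline geometry.
    """

    def __init__(self, sol: SolutionSeries, time_index: int = -1):
        self.mesh = sol.mesh
        self.u = sol.u[time_index]
        self.locator = fem.CellLocator(self.mesh.vertices, self.mesh.cells)

    def __call__(self, pts: np.ndarray):
        pts = np.atleast_2d(pts)
        cid, lam = self.locator.locate(pts)
        ok = cid >= 0
        out = np.zeros((len(pts), 3))
        if ok.any():
            out[ok] = fem.eval_p2(self.mesh.cells, self.u, cid[ok], lam[ok])
        return out, ok


class CallableField:
    """Adapter for analytic velocity fields u(x); everywhere defined."""

    def __init__(self, func):
        self.func = func

    def __call__(self, pts):
        pts = np.atleast_2d(pts)
        return np.asarray(self.func(pts), float), np.ones(len(pts), bool)


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------

def _plane_basis(normal, lateral_hint=(0.0, 1.0, 0.0)):
    n = np.asarray(normal, float)
    n = n / np.linalg.norm(n)
    h = np.asarray(lateral_hint, float)
    e1 = h - (h @ n) * n
    if np.linalg.norm(e1) < 1e-12:
        h = np.array([1.0, 0.0, 0.0])
        e1 = h - (h @ n) * n
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return n, e1, e2


def seed_cross_section(mesh: VolumeMesh, point, normal, n: int,
                       seed: int = 0, wall_margin: float | None = None
                       ) -> np.ndarray:
    """Quasi-uniform interior seed points on a lumen cross-section (mm).

    Candidates are laid out on a sunflower spiral in the cutting plane
    (deterministically rotated by ``seed``), filtered to points inside the
    mesh and at least ``wall_margin`` from the wall (default: 8% of the
    section's inscribed radius).
    """
    point = np.asarray(point, float)
    nrm, e1, e2 = _plane_basis(normal)
    loc = fem.CellLocator(mesh.vertices, mesh.cells)
    # wall distance via sampled wall facet nodes
    wall_pts = mesh.vertices[np.unique(
        mesh.facets[mesh.facet_tags == WALL].ravel())]
    wall_tree = cKDTree(wall_pts)
    span = np.linalg.norm(mesh.vertices.max(0) - mesh.vertices.min(0))
    rng = np.random.default_rng(seed)
    theta0 = rng.uniform(0, 2 * np.pi)

    def sunflower(m, radius):
        k = np.arange(m) + 0.5
        r = radius * np.sqrt(k / m)
        th = k * np.pi * (3 - np.sqrt(5)) + theta0
        return (point + np.outer(r * np.cos(th), e1)
                + np.outer(r * np.sin(th), e2))

    # probe pass: find the section's extent, then sample it densely
    probe = sunflower(2000, span / 2)
    pin, _ = loc.locate(probe)
    if not (pin >= 0).any():
        raise StreamlineError("plane does not intersect the lumen")
    r_max = 1.1 * np.linalg.norm(probe[pin >= 0] - point, axis=1).max()
    cand = sunflower(max(4000, 40 * n), max(r_max, 1e-12))
    cid, _ = loc.locate(cand)
    inside = cid >= 0
    d, _ = wall_tree.query(cand[inside])
    if wall_margin is None:
        wall_margin = 0.08 * d.max()
    good = cand[inside][d >= wall_margin]
    if len(good) < n:
        raise StreamlineError(
            f"only {len(good)} interior seeds available (requested {n}); "
            "reduce n or wall_margin")
    pick = np.linspace(0, len(good) - 1, n).astype(int)
    return good[pick]


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

@dataclass
class StreamlineBundle:
    polylines: list               # list of (m_i, 3) arrays, mm
    seed_ids: np.ndarray
    termination: list             # outlet | max_length | stagnation | left_domain
    branch_labels: np.ndarray | None = None   # region tag or -1
    step: float = 0.0

    def __len__(self):
        return len(self.polylines)


def trace_streamlines(field, seeds: np.ndarray, step: float,
                      max_length: float, stagnation_tol: float | None = None,
                      outlet_facets: np.ndarray | None = None,
                      mesh: VolumeMesh | None = None) -> StreamlineBundle:
    """RK4 integration of dx/ds = u/|u| from each seed (arc-length step).

    Termination is recorded per streamline: leaving the domain near an
    outlet cap counts as ``outlet`` (requires ``mesh``), otherwise
    ``left_domain``; speeds below ``stagnation_tol`` (default 1e-6 x the
    seed-point peak speed) give ``stagnation``.
    """
    if step <= 0:
        raise StreamlineError("step must be positive")
    seeds = np.atleast_2d(np.asarray(seeds, float))
    ns = len(seeds)
    u0, ok0 = field(seeds)
    speed0 = np.linalg.norm(u0, axis=1)
    if stagnation_tol is None:
        stagnation_tol = 1e-6 * max(speed0.max(), 1e-300)

    outlet_tree = None
    if mesh is not None:
        out_sel = (mesh.facet_tags != WALL)
        if out_sel.any():
            cen, _, _ = mesh.facet_geometry()
            outlet_tree = cKDTree(cen[out_sel])
            outlet_tags = mesh.facet_tags[out_sel]

    n_steps = int(np.ceil(max_length / step))
    x = seeds.copy()
    active = ok0 & (speed0 >= stagnation_tol)
    term = np.array(["max_length"] * ns, dtype=object)
    term[~ok0] = "left_domain"
    term[ok0 & (speed0 < stagnation_tol)] = "stagnation"
    paths = [[seeds[i].copy()] for i in range(ns)]

    def f(pts):
        u, ok = field(pts)
        s = np.linalg.norm(u, axis=1)
        ok = ok & (s >= stagnation_tol)
        d = np.zeros_like(u)
        d[ok] = u[ok] / s[ok, None]
        return d, ok

    for _ in range(n_steps):
        if not active.any():
            break
        idx = np.nonzero(active)[0]
        xa = x[idx]
        k1, ok1 = f(xa)
        k2, ok2 = f(xa + 0.5 * step * k1)
        k3, ok3 = f(xa + 0.5 * step * k2)
        k4, ok4 = f(xa + step * k3)
        ok = ok1 & ok2 & ok3 & ok4
        xn = xa + (step / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        un, okn = field(xn)
        sn = np.linalg.norm(un, axis=1)
        for j, i in enumerate(idx):
            if not ok[j] or not okn[j]:
                # decide between stagnation mid-step and leaving the domain
                uu, _ = field(x[i][None])
                if np.linalg.norm(uu) < stagnation_tol:
                    term[i] = "stagnation"
                else:
                    term[i] = "left_domain"
                    if outlet_tree is not None:
                        d, _ = outlet_tree.query(x[i])
                        if d < 3 * step:
                            term[i] = "outlet"
                active[i] = False
                continue
            x[i] = xn[j]
            paths[i].append(xn[j].copy())
            if sn[j] < stagnation_tol:
                term[i] = "stagnation"
                active[i] = False
    return StreamlineBundle(polylines=[np.array(p) for p in paths],
                            seed_ids=np.arange(ns),
                            termination=list(term), step=step)


# ---------------------------------------------------------------------------
# classification and ordering
# ---------------------------------------------------------------------------

def classify_by_branch(bundle: StreamlineBundle, classify_points,
                       branch_tags, region_names: dict | None = None
                       ) -> np.ndarray:
    """Label each streamline by the branch whose region holds the majority
    of its arc length among ``branch_tags`` (e.g. the six arch regions);
    -1 when the streamline never enters any of them."""
    branch_tags = np.asarray(branch_tags)
    labels = np.full(len(bundle), -1, dtype=np.int64)
    for i, pl in enumerate(bundle.polylines):
        if len(pl) < 2:
            continue
        mid = 0.5 * (pl[:-1] + pl[1:])
        seg = np.linalg.norm(np.diff(pl, axis=0), axis=1)
        reg = np.asarray(classify_points(mid))
        best, best_len = -1, 0.0
        for t in branch_tags:
            ln = seg[reg == t].sum()
            if ln > best_len:
                best, best_len = int(t), ln
        labels[i] = best
    bundle.branch_labels = labels
    return labels


@dataclass
class OrderingReport:
    ids: np.ndarray               # streamlines crossing both planes
    upstream_xy: np.ndarray       # in-plane (lateral, transverse), mm
    downstream_xy: np.ndarray
    branch: np.ndarray            # branch tag per kept streamline
    kendall_tau: float            # lateral-order rank correlation
    adjacency_preserved: float    # fraction of branch neighbor pairs kept
    branch_table: pd.DataFrame    # per-branch lateral centroids and ranks
    split_branches: list = field(default_factory=list)


def _plane_crossing(polyline: np.ndarray, point, normal):
    s = (polyline - point) @ normal
    sign = np.signbit(s)
    hits = np.nonzero(sign[1:] != sign[:-1])[0]
    if len(hits) == 0:
        return None
    i = hits[0]
    t = s[i] / (s[i] - s[i + 1])
    return polyline[i] + t * (polyline[i + 1] - polyline[i])


def ordering_analysis(bundle: StreamlineBundle, upstream_plane,
                      downstream_plane, lateral_hint=(0.0, 1.0, 0.0)
                      ) -> OrderingReport:
    """Compare streamline cross-section positions between two planes.

    Planes are ``(point, normal)`` tuples in mm.  In-plane coordinates use
    the lateral direction (projection of ``lateral_hint``) as first axis,
    so left/right ordering is explicit.  Scores use only streamlines that
    cross both planes.
    """
    p_u, n_u = (np.asarray(a, float) for a in upstream_plane)
    p_d, n_d = (np.asarray(a, float) for a in downstream_plane)
    _, e1u, e2u = _plane_basis(n_u, lateral_hint)
    _, e1d, e2d = _plane_basis(n_d, lateral_hint)
    ids, up, dn = [], [], []
    for i, pl in enumerate(bundle.polylines):
        cu = _plane_crossing(pl, p_u, n_u)
        cd = _plane_crossing(pl, p_d, n_d)
        if cu is None or cd is None:
            continue
        ids.append(i)
        up.append(((cu - p_u) @ e1u, (cu - p_u) @ e2u))
        dn.append(((cd - p_d) @ e1d, (cd - p_d) @ e2d))
    if len(ids) < 2:
        raise StreamlineError(
            f"only {len(ids)} streamlines cross both planes (need >= 2)")
    ids = np.array(ids)
    up = np.array(up)
    dn = np.array(dn)
    tau = float(kendalltau(up[:, 0], dn[:, 0]).statistic)

    labels = (bundle.branch_labels[ids]
              if bundle.branch_labels is not None
              else np.full(len(ids), -1))
    rows = []
    for b in np.unique(labels):
        if b < 0:
            continue
        sel = labels == b
        rows.append((int(b), float(up[sel, 0].mean()),
                     float(dn[sel, 0].mean()), int(sel.sum())))
    table = pd.DataFrame(rows, columns=["branch", "upstream_lateral",
                                        "downstream_lateral", "n"])
    adjacency = 1.0
    split = []
    if len(table) >= 2:
        t = table.sort_values("upstream_lateral", ascending=False)
        t["rank_up"] = np.arange(len(t))
        t = t.sort_values("downstream_lateral", ascending=False)
        t["rank_dn"] = np.arange(len(t))
        t = t.sort_values("rank_up")
        table = t.reset_index(drop=True)
        kept = 0
        pairs = list(zip(table.branch[:-1], table.branch[1:]))
        rdn = dict(zip(table.branch, table.rank_dn))
        for a, b in pairs:
            if abs(rdn[a] - rdn[b]) == 1:
                kept += 1
            else:
                split.append((int(a), int(b)))
        adjacency = kept / len(pairs)
    return OrderingReport(ids=ids, upstream_xy=up, downstream_xy=dn,
                          branch=labels, kendall_tau=tau,
                          adjacency_preserved=float(adjacency),
                          branch_table=table, split_branches=split)
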