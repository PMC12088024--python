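"""Vessel centerlines, maximal-inscribed-sphere radii and branch metrics.

The centerline of a branch is the interior path of maximal inscribed
spheres (MIS) between two boundary caps.  It is computed on the mesh's
interior vertex graph: each edge is weighted by its length divided by the
squared wall distance of its midpoint, so shortest paths are drawn onto
the medial axis; the path is then smoothed and the MIS radius at each
point is its exact distance to the wall triangulation.  Local diameter is
2 x MIS radius, matching how arch diameters are measured in the
developmental literature.

Branch metrics: arc length, tortuosity (arc/chord - 1), min and
arc-length-averaged diameter, Menger curvature, lumen volume, and the
minor/major ratio of elliptical cross-sections.  Cohorts of per-branch
measurements are compared across factors (arch pair, left/right side)
with one-way ANOVA followed by Tukey's HSD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .fem import TET_EDGES
from .mesh import WALL, TriangleProximity, VolumeMesh


class GeometryError(ValueError):
    pass


# ---------------------------------------------------------------------------
# wall distance
# ---------------------------------------------------------------------------

class WallDistance:
    """Exact distance to the wall facet triangulation."""

    def __init__(self, mesh: VolumeMesh, k: int = 24):
        faces = mesh.facets[mesh.facet_tags == WALL][:, :3]
        if len(faces) == 0:
            raise GeometryError("mesh has no wall facets")
        self.prox = TriangleProximity(mesh.vertices[faces], k=k)

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        return self.prox.query(pts)[0]


# ---------------------------------------------------------------------------
# centerline extraction
# ---------------------------------------------------------------------------

@dataclass
class Centerline:
    points: np.ndarray            # (n, 3) mm, ordered source -> target
    radii: np.ndarray             # (n,) MIS radius, mm
    source: str
    target: str
    branch: str = ""

    def arclength(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arclength()[-1])


def _smooth_path(pts: np.ndarray, window: int) -> np.ndarray:
    if window < 3 or len(pts) < window:
        return pts
    if window % 2 == 0:
        window += 1
    half = window // 2
    out = pts.copy()
    for i in range(1, len(pts) - 1):
        lo, hi = max(0, i - half), min(len(pts), i + half + 1)
        out[i] = pts[lo:hi].mean(axis=0)
    return out


def _medialize(pts: np.ndarray, wd: WallDistance, step: float,
               n_iter: int = 6) -> np.ndarray:
    """Pull interior path points onto the medial axis by gradient ascent on
    the wall distance, restricted to the plane normal to the local tangent
    (endpoints stay fixed)."""
    pts = pts.copy()
    eps = 0.25 * step
    for _ in range(n_iter):
        tang = np.gradient(pts, axis=0)
        tang /= np.maximum(np.linalg.norm(tang, axis=1), 1e-300)[:, None]
        grad = np.empty_like(pts)
        for d in range(3):
            e = np.zeros(3)
            e[d] = eps
            grad[:, d] = (wd(pts + e) - wd(pts - e)) / (2 * eps)
        grad -= np.einsum('ij,ij->i', grad, tang)[:, None] * tang
        gn = np.linalg.norm(grad, axis=1)
        move = np.minimum(gn, 1.0)[:, None] * grad / np.maximum(
            gn, 1e-300)[:, None]
        pts[1:-1] += 0.35 * step * move[1:-1]
    return pts


def extract_centerline(mesh: VolumeMesh, source: str, target: str,
                       weight_power: float = 2.0, smooth_window: int = 7,
                       branch: str = "") -> Centerline:
    """Maximal-inscribed-sphere centerline between two tagged caps.

    Dijkstra on the P1 vertex graph with edge weight
    ``len / mean(wall_dist)^weight_power`` finds a path hugging the medial
    axis; the path is then medialized (gradient ascent on wall distance,
    which removes junction corner-cutting), lightly smoothed, and radii
    are re-evaluated as exact wall distances at the final points.
    """
    wd = WallDistance(mesh)
    nv = mesh.n_p1
    verts = mesh.vertices[:nv]
    dist_v = wd(verts)

    edges = np.unique(np.sort(mesh.cells[:, :4][:, TET_EDGES].reshape(-1, 2),
                              axis=1), axis=0)
    elen = np.linalg.norm(verts[edges[:, 0]] - verts[edges[:, 1]], axis=1)
    dmid = 0.5 * (dist_v[edges[:, 0]] + dist_v[edges[:, 1]])
    w = elen / np.maximum(dmid, 1e-9) ** weight_power
    G = coo_matrix((np.concatenate([w, w]),
                    (np.concatenate([edges[:, 0], edges[:, 1]]),
                     np.concatenate([edges[:, 1], edges[:, 0]]))),
                   shape=(nv, nv)).tocsr()

    def cap_center(name):
        tag = mesh.tag_of(name)
        vs = np.unique(mesh.facets[mesh.facet_tags == tag][:, :3].ravel())
        if len(vs) == 0:
            raise GeometryError(f"no facets tagged {name!r}")
        return vs[np.argmax(dist_v[vs])]

    s, t = cap_center(source), cap_center(target)
    dmat, pred = dijkstra(G, indices=s, return_predecessors=True)
    if not np.isfinite(dmat[t]):
        raise GeometryError(f"{source!r} and {target!r} are not connected")
    path = [t]
    while path[-1] != s:
        path.append(pred[path[-1]])
    path = np.array(path[::-1])
    pts = _smooth_path(verts[path], smooth_window)
    pts = _medialize(pts, wd, step=max(mesh.element_size, 1e-6))
    pts = _smooth_path(pts, smooth_window)
    radii = wd(pts)
    return Centerline(points=pts, radii=radii, source=source, target=target,
                      branch=branch)


# ---------------------------------------------------------------------------
# branch metrics
# ---------------------------------------------------------------------------

@dataclass
class BranchMetrics:
    branch: str
    length: float                 # mm
    tortuosity: float             # arc/chord - 1
    min_diameter: float           # mm
    avg_diameter: float           # mm
    mean_curvature: float         # 1/mm, discrete Menger curvature
    volume: float | None          # mm^3 (when a region is supplied)
    ellipse_ratio: float | None   # minor/major of cross-sections

    def as_row(self) -> dict:
        return {
            "branch": self.branch, "length_mm": self.length,
            "tortuosity": self.tortuosity, "min_d_mm": self.min_diameter,
            "avg_d_mm": self.avg_diameter,
            "curvature_per_mm": self.mean_curvature,
            "volume_mm3": self.volume, "ellipse_ratio": self.ellipse_ratio,
        }


def _menger_curvature(pts: np.ndarray, n_samples: int = 12) -> float:
    """Mean three-point (Menger) curvature on an arc-length resampling of
    the path; resampling suppresses mesh-scale zig-zag that would dominate
    the discrete curvature at the raw point spacing."""
    if len(pts) < 3:
        return 0.0
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        return 0.0
    si = np.linspace(0, s[-1], max(8, min(n_samples, len(pts))))
    pts = np.column_stack([np.interp(si, s, pts[:, d]) for d in range(3)])
    a, b, c = pts[:-2], pts[1:-1], pts[2:]
    ab = np.linalg.norm(b - a, axis=1)
    bc = np.linalg.norm(c - b, axis=1)
    ca = np.linalg.norm(a - c, axis=1)
    area2 = np.linalg.norm(np.cross(b - a, c - a), axis=1)
    denom = ab * bc * ca
    kappa = np.where(denom > 1e-300, 2 * area2 / np.maximum(denom, 1e-300), 0.0)
    return float(kappa.mean())


def cross_section_ellipse_ratio(mesh: VolumeMesh, point, tangent,
                                slab: float | None = None) -> float:
    """Minor/major axis ratio of the lumen cross-section at a centerline
    point, from the second moments of interior mesh vertices in a thin slab
    normal to the tangent (vertices sample the section quasi-uniformly)."""
    t = np.asarray(tangent, float)
    t = t / np.linalg.norm(t)
    slab = slab or 1.5 * max(mesh.element_size, 1e-6)
    rel = mesh.vertices[:mesh.n_p1] - np.asarray(point, float)
    axial = rel @ t
    sel = np.abs(axial) < slab / 2
    # keep only points of the local section, not other branches
    inplane = rel[sel] - np.outer(axial[sel], t)
    r = np.linalg.norm(inplane, axis=1)
    local = r < np.quantile(r, 0.2) * 6 if len(r) > 8 else np.ones(len(r), bool)
    pts = inplane[local]
    if len(pts) < 6:
        raise GeometryError("too few vertices in cross-section slab")
    cov = np.cov(pts.T)
    evals = np.sort(np.linalg.eigvalsh(cov))
    # evals[0] ~ 0 (normal direction); uniform ellipse has moments a^2/4, b^2/4
    return float(np.sqrt(max(evals[1], 0.0) / max(evals[2], 1e-300)))


def branch_metrics(cl: Centerline, mesh: VolumeMesh | None = None,
                   region: int | None = None,
                   stations=(0.3, 0.5, 0.7)) -> BranchMetrics:
    """Geometric metrics of one branch from its centerline (and mesh)."""
    if len(cl.points) < 2:
        raise GeometryError("degenerate centerline (< 2 points)")
    s = cl.arclength()
    length = float(s[-1])
    chord = float(np.linalg.norm(cl.points[-1] - cl.points[0]))
    tort = length / max(chord, 1e-300) - 1.0
    d = 2 * cl.radii
    wseg = np.zeros(len(d))
    seg = np.diff(s)
    wseg[:-1] += seg / 2
    wseg[1:] += seg / 2
    avg_d = float((d * wseg).sum() / wseg.sum())
    vol = None
    if mesh is not None and region is not None:
        vol = branch_volume(mesh, region)
    ratio = None
    if mesh is not None:
        ratios = []
        for f in stations:
            i = int(np.searchsorted(s, f * length).clip(1, len(s) - 1))
            tang = cl.points[min(i + 1, len(s) - 1)] - cl.points[i - 1]
            try:
                ratios.append(cross_section_ellipse_ratio(
                    mesh, cl.points[i], tang))
            except GeometryError:
                pass
        ratio = float(np.median(ratios)) if ratios else None
    return BranchMetrics(branch=cl.branch, length=length, tortuosity=tort,
                         min_diameter=float(d.min()), avg_diameter=avg_d,
                         mean_curvature=_menger_curvature(cl.points),
                         volume=vol, ellipse_ratio=ratio)


def branch_volume(mesh: VolumeMesh, region: int) -> float:
    """Lumen volume (mm^3) of one tagged anatomical region."""
    if mesh.region_tags is None:
        raise GeometryError("mesh has no region tags")
    sel = mesh.region_tags == region
    if not sel.any():
        raise GeometryError(f"region {region} is empty")
    return float(mesh.cell_volumes()[sel].sum())


# ---------------------------------------------------------------------------
# cohort statistics
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    factor: str
    levels: list
    F: float
    df_between: int
    df_within: int
    p_value: float
    tukey: pd.DataFrame           # pairwise adjusted p-values

    def stars(self, p: float | None = None) -> str:
        p = self.p_value if p is None else p
        return "***" if p < 0.001 else "**" if p < 0.01 else \
               "*" if p < 0.05 else "ns"


def compare_groups(table: pd.DataFrame, value: str,
                   factor: str) -> GroupComparison:
    """One-way ANOVA + Tukey HSD of ``value`` across the levels of
    ``factor`` (e.g. arch pair II/III/IV, or side L/R)."""
    from scipy.stats import f_oneway
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    groups = [g[value].to_numpy(dtype=float)
              for _, g in table.groupby(factor, sort=True)]
    levels = sorted(table[factor].unique().tolist())
    if len(groups) < 2:
        raise GeometryError("need >= 2 factor levels")
    if any(len(g) < 2 for g in groups):
        raise GeometryError("need >= 2 observations per level")
    F, p = f_oneway(*groups)
    n = sum(len(g) for g in groups)
    res = pairwise_tukeyhsd(table[value].to_numpy(dtype=float),
                            table[factor].to_numpy(), alpha=0.05)
    tk = pd.DataFrame(res.summary().data[1:],
                      columns=[str(c) for c in res.summary().data[0]])
    return GroupComparison(factor=factor, levels=levels, F=float(F),
                           df_between=len(groups) - 1, df_within=n - len(groups),
                           p_value=float(p), tukey=tk)
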