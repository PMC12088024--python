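"""Second-order tetrahedral meshes: data model, generation, tagging, quality.

All coordinates are in millimetres (the natural scale of embryonic
vasculature); the flow solver converts to SI on load.  Cells are
straight-edged 10-node (P2) tetrahedra: 4 corner vertices followed by 6
mid-edge nodes in the canonical edge order of :mod:`archflow.fem`.

Two mesh generators are provided:

* :func:`structured_tube_mesh` -- a high-quality swept mesh of a (possibly
  elliptical / stenosed) straight tube, used for quantitative verification
  against closed-form Poiseuille / Womersley solutions;
* :func:`tetrahedralize` -- fills any watertight triangulated surface with
  tetrahedra by Delaunay triangulation of jittered interior lattice points
  plus the surface vertices, keeping cells whose centroid lies inside the
  lumen.  This is how the curved arch phantoms are meshed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .fem import TET_EDGES, cell_geometry

WALL = 1
INLET = 2
FIRST_OUTLET = 3

# local faces of a tet (outward-oriented), opposite vertex 3,2,1,0 resp.
TET_FACES = ((0, 2, 1), (0, 1, 3), (0, 3, 2), (1, 2, 3))


class MeshError(ValueError):
    pass


# ---------------------------------------------------------------------------
# triangle proximity / containment (no external spatial-index dependency)
# ---------------------------------------------------------------------------

def point_triangle_distance(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Exact distances between paired points (n, 3) and triangles (n, 3, 3)
    (Ericson's region classification, vectorized)."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum('ij,ij->i', ab, ap)
    d2 = np.einsum('ij,ij->i', ac, ap)
    bp = p - b
    d3 = np.einsum('ij,ij->i', ab, bp)
    d4 = np.einsum('ij,ij->i', ac, bp)
    cp = p - c
    d5 = np.einsum('ij,ij->i', ab, cp)
    d6 = np.einsum('ij,ij->i', ac, cp)
    res = np.empty_like(p)
    done = np.zeros(len(p), bool)

    def setres(m, pt):
        m = m & ~done
        res[m] = pt[m]
        done[m] = True

    setres((d1 <= 0) & (d2 <= 0), a)
    setres((d3 >= 0) & (d4 <= d3), b)
    setres((d6 >= 0) & (d5 <= d6), c)
    vc = d1 * d4 - d3 * d2
    m = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    v = d1 / np.where(np.abs(d1 - d3) > 1e-300, d1 - d3, 1.0)
    setres(m, a + v[:, None] * ab)
    vb = d5 * d2 - d1 * d6
    m = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    w = d2 / np.where(np.abs(d2 - d6) > 1e-300, d2 - d6, 1.0)
    setres(m, a + w[:, None] * ac)
    va = d3 * d6 - d5 * d4
    m = (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    denom_bc = (d4 - d3) + (d5 - d6)
    w = (d4 - d3) / np.where(np.abs(denom_bc) > 1e-300, denom_bc, 1.0)
    setres(m, b + w[:, None] * (c - b))
    denom = va + vb + vc
    v = vb / np.where(denom != 0, denom, 1.0)
    w = vc / np.where(denom != 0, denom, 1.0)
    setres(np.ones(len(p), bool), a + v[:, None] * ab + w[:, None] * ac)
    return np.linalg.norm(p - res, axis=1)


class TriangleProximity:
    """Nearest triangle of a soup: KD-tree on centroids + exact distance to
    the k closest candidates."""

    def __init__(self, tris: np.ndarray, k: int = 24):
        self.tris = np.asarray(tris, float)
        self.tree = cKDTree(self.tris.mean(axis=1))
        self.k = min(k, len(self.tris))

    def query(self, pts: np.ndarray):
        pts = np.atleast_2d(np.asarray(pts, float))
        _, idx = self.tree.query(pts, k=self.k)
        idx = np.atleast_2d(idx)
        best = np.full(len(pts), np.inf)
        best_tri = np.zeros(len(pts), dtype=np.int64)
        for j in range(idx.shape[1]):
            d = point_triangle_distance(pts, self.tris[idx[:, j]])
            better = d < best
            best[better] = d[better]
            best_tri[better] = idx[better, j]
        return best, best_tri


def _parity_one_direction(tri, pts, d):
    a = tri[:, 0]
    e1 = tri[:, 1] - a
    e2 = tri[:, 2] - a
    pvec = np.cross(np.broadcast_to(d, e2.shape), e2)       # (m, 3)
    det = np.einsum('mx,mx->m', e1, pvec)
    with np.errstate(divide="ignore"):
        inv = np.where(np.abs(det) > 1e-300, 1.0 / det, 0.0)
    out = np.zeros(len(pts), bool)
    for s in range(0, len(pts), 1024):
        p = pts[s:s + 1024]
        tvec = p[:, None, :] - a[None]                      # (n, m, 3)
        u = np.einsum('nmx,mx->nm', tvec, pvec) * inv
        qvec = np.cross(tvec, np.broadcast_to(e1, tvec.shape))
        v = np.einsum('x,nmx->nm', d, qvec) * inv
        t = np.einsum('mx,nmx->nm', e2, qvec) * inv
        hit = ((np.abs(det) > 1e-300) & (u >= 0) & (v >= 0)
               & (u + v <= 1) & (t > 0))
        out[s:s + 1024] = hit.sum(axis=1) % 2 == 1
    return out


def contains_parity(verts: np.ndarray, faces: np.ndarray,
                    pts: np.ndarray) -> np.ndarray:
    """Point-in-watertight-surface test by ray-crossing parity.

    Three irrational ray directions are cast and majority-voted, which
    makes the test robust to rays grazing shared triangle edges of
    axis-aligned geometry."""
    tri = np.asarray(verts, float)[np.asarray(faces)]
    pts = np.atleast_2d(np.asarray(pts, float))
    dirs = np.array([[0.577350, 0.211325, 0.788675],
                     [-0.356822, 0.934172, 0.0],
                     [0.303531, -0.252647, 0.918696]])
    votes = np.zeros(len(pts), dtype=np.int64)
    for d in dirs:
        votes += _parity_one_direction(tri, pts, d / np.linalg.norm(d))
    return votes >= 2


def tet_volumes(verts: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed tet volumes from the corner vertices (no matrix inversion,
    safe for degenerate cells)."""
    x = verts[np.asarray(tets)[:, :4]]
    return np.einsum('ij,ij->i', np.cross(x[:, 1] - x[:, 0],
                                          x[:, 2] - x[:, 0]),
                     x[:, 3] - x[:, 0]) / 6.0


@dataclass
class MeshQualityReport:
    n_cells: int
    n_vertices: int
    total_volume: float          # mm^3
    min_dihedral_deg: float
    max_dihedral_deg: float
    radius_ratio_max: float
    radius_ratio_hist: np.ndarray
    radius_ratio_bins: np.ndarray

    def __str__(self):  # pragma: no cover - cosmetic
        return (f"MeshQualityReport(cells={self.n_cells}, "
                f"verts={self.n_vertices}, volume={self.total_volume:.6g} mm3, "
                f"dihedral=[{self.min_dihedral_deg:.1f}, "
                f"{self.max_dihedral_deg:.1f}] deg, "
                f"worst radius-ratio={self.radius_ratio_max:.2f})")


@dataclass
class VolumeMesh:
    """Straight-edged P2 tetrahedral mesh with boundary and region tags.

    ``vertices`` holds corner vertices first (``n_p1`` of them) followed by
    mid-edge nodes; P1 (pressure) dofs are exactly the first ``n_p1``
    vertices.  ``facets`` are boundary triangles as 6-node rows
    ``[v0 v1 v2 m01 m12 m02]`` oriented outward.
    """

    vertices: np.ndarray          # (n_nodes, 3) mm
    cells: np.ndarray             # (nc, 10)
    n_p1: int
    facets: np.ndarray            # (nf, 6)
    facet_parent: np.ndarray      # (nf,) cell index
    facet_tags: np.ndarray        # (nf,) int
    facet_names: dict = field(default_factory=dict)   # tag -> name
    region_tags: np.ndarray | None = None             # (nc,) int
    region_names: dict = field(default_factory=dict)  # tag -> name
    element_size: float = 0.0     # characteristic spacing h (mm)
    units: str = "mm"

    # -- derived geometry ---------------------------------------------------
    def cell_volumes(self) -> np.ndarray:
        _, vol = cell_geometry(self.vertices, self.cells)
        return vol

    def total_volume(self) -> float:
        return float(self.cell_volumes().sum())

    def facet_geometry(self):
        """(centroids, outward unit normals, areas) of boundary facets."""
        tri = self.vertices[self.facets[:, :3]]
        c = tri.mean(axis=1)
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        a = 0.5 * np.linalg.norm(n, axis=1)
        with np.errstate(invalid="ignore"):
            n = n / (2 * a)[:, None]
        return c, n, a

    def facets_with_tag(self, tag: int) -> np.ndarray:
        return np.nonzero(self.facet_tags == tag)[0]

    def tag_of(self, name: str) -> int:
        for t, n in self.facet_names.items():
            if n == name:
                return t
        raise KeyError(name)

    def wall_nodes(self) -> np.ndarray:
        """All P2 node indices lying on wall facets (no-slip set)."""
        f = self.facets[self.facet_tags == WALL]
        return np.unique(f.ravel())

    def quality_report(self) -> MeshQualityReport:
        vol = self.cell_volumes()
        rr = radius_ratios(self.vertices, self.cells)
        dmin, dmax = dihedral_range(self.vertices, self.cells)
        bins = np.array([1, 1.5, 2, 3, 5, 10, 20, np.inf])
        hist, _ = np.histogram(rr, bins=bins)
        return MeshQualityReport(
            n_cells=len(self.cells), n_vertices=len(self.vertices),
            total_volume=float(vol.sum()),
            min_dihedral_deg=dmin, max_dihedral_deg=dmax,
            radius_ratio_max=float(rr.max()),
            radius_ratio_hist=hist, radius_ratio_bins=bins)


# ---------------------------------------------------------------------------
# P1 -> P2 promotion and boundary extraction
# ---------------------------------------------------------------------------

def _unique_edges(tets: np.ndarray):
    e = tets[:, TET_EDGES].reshape(-1, 2)
    e = np.sort(e, axis=1)
    uniq, inv = np.unique(e, axis=0, return_inverse=True)
    return uniq, inv.reshape(len(tets), 6)


def promote_to_p2(verts: np.ndarray, tets: np.ndarray):
    """Insert mid-edge nodes: returns (all_nodes, p2_cells, edge_map).

    ``edge_map`` maps a sorted vertex pair (as rows of the unique-edge
    array) to its midpoint node id ``n_p1 + row``.
    """
    uniq, cell_edges = _unique_edges(tets)
    mids = 0.5 * (verts[uniq[:, 0]] + verts[uniq[:, 1]])
    nodes = np.vstack([verts, mids])
    cells = np.hstack([tets, cell_edges + len(verts)])
    return nodes, cells.astype(np.int64), uniq


def orient_cells(verts: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Swap vertices 0/1 of negatively oriented tets."""
    vol = tet_volumes(verts, tets)
    flip = vol < 0
    tets = tets.copy()
    tets[flip, 0], tets[flip, 1] = tets[flip, 1].copy(), tets[flip, 0].copy()
    return tets


def boundary_faces(tets: np.ndarray):
    """Faces appearing in exactly one tet: (faces (nf,3), parent cell ids).

    Faces are returned outward-oriented (normal away from the opposite
    vertex); requires positively oriented cells.
    """
    faces = tets[:, TET_FACES].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    uniq, first, counts = np.unique(key, axis=0, return_index=True,
                                    return_counts=True)
    idx = first[counts == 1]
    return faces[idx], idx // 4


def _edge_midpoint_lookup(edge_array: np.ndarray, n_p1: int):
    lut = {}
    for i, (a, b) in enumerate(edge_array):
        lut[(int(a), int(b))] = n_p1 + i
    def mid(a, b):
        return lut[(a, b)] if a < b else lut[(b, a)]
    return mid


def _facets_p2(faces: np.ndarray, edge_array: np.ndarray, n_p1: int):
    mid = _edge_midpoint_lookup(edge_array, n_p1)
    out = np.empty((len(faces), 6), dtype=np.int64)
    out[:, :3] = faces
    for i, (a, b, c) in enumerate(faces):
        out[i, 3] = mid(int(a), int(b))
        out[i, 4] = mid(int(b), int(c))
        out[i, 5] = mid(int(a), int(c))
    return out


def from_p1(verts: np.ndarray, tets: np.ndarray, element_size: float = 0.0,
            region_tags: np.ndarray | None = None) -> VolumeMesh:
    """Build an (untagged) :class:`VolumeMesh` from a first-order tet mesh."""
    tets = orient_cells(verts, np.asarray(tets, dtype=np.int64))
    nodes, cells, edges = promote_to_p2(verts, tets)
    faces, parents = boundary_faces(tets)
    facets = _facets_p2(faces, edges, len(verts))
    return VolumeMesh(vertices=nodes, cells=cells, n_p1=len(verts),
                      facets=facets, facet_parent=parents,
                      facet_tags=np.zeros(len(facets), dtype=np.int64),
                      region_tags=region_tags,
                      element_size=element_size)


# ---------------------------------------------------------------------------
# quality metrics
# ---------------------------------------------------------------------------

def radius_ratios(verts, cells) -> np.ndarray:
    """Normalized circumradius / (3 * inradius); 1 for the regular tet."""
    x = verts[cells[:, :4]]
    a, b, c, d = x[:, 0], x[:, 1], x[:, 2], x[:, 3]
    vol = np.abs(np.einsum('ij,ij->i', np.cross(b - a, c - a), d - a)) / 6
    # face areas
    areas = np.zeros(len(x))
    for (i, j, k) in TET_FACES:
        areas += 0.5 * np.linalg.norm(
            np.cross(x[:, j] - x[:, i], x[:, k] - x[:, i]), axis=1)
    inr = 3 * vol / np.maximum(areas, 1e-300)
    # circumradius via the Cayley-Menger-free formula
    ba, ca, da = b - a, c - a, d - a
    n1 = np.einsum('ij,ij->i', ba, ba)
    n2 = np.einsum('ij,ij->i', ca, ca)
    n3 = np.einsum('ij,ij->i', da, da)
    num = (n1[:, None] * np.cross(ca, da)
           + n2[:, None] * np.cross(da, ba)
           + n3[:, None] * np.cross(ba, ca))
    circ = np.linalg.norm(num, axis=1) / np.maximum(12 * vol, 1e-300)
    return circ / np.maximum(3 * inr, 1e-300)


def dihedral_range(verts, cells) -> tuple[float, float]:
    x = verts[cells[:, :4]]
    normals = []
    for (i, j, k) in TET_FACES:
        n = np.cross(x[:, j] - x[:, i], x[:, k] - x[:, i])
        n /= np.maximum(np.linalg.norm(n, axis=1), 1e-300)[:, None]
        normals.append(n)
    angs = []
    for p in range(4):
        for q in range(p + 1, 4):
            cosv = np.clip(-np.einsum('ij,ij->i', normals[p], normals[q]),
                           -1, 1)
            angs.append(np.degrees(np.arccos(cosv)))
    angs = np.concatenate(angs)
    return float(angs.min()), float(angs.max())


# ---------------------------------------------------------------------------
# boundary tagging
# ---------------------------------------------------------------------------

def tag_boundaries(mesh: VolumeMesh, rules: dict) -> VolumeMesh:
    """Assign facet tags from named geometric predicates.

    ``rules`` maps a name (``"wall"``, ``"inlet"``, ``"outlet"``,
    ``"outlet_2"``, ...) to ``predicate(centroids, normals) -> bool array``.
    Every boundary facet must be selected by exactly one rule.
    """
    if not rules:
        raise MeshError("no tagging rules given: boundary facets uncovered")
    cen, nor, _ = mesh.facet_geometry()
    tags = np.zeros(len(mesh.facets), dtype=np.int64)
    names = {}
    next_outlet = FIRST_OUTLET
    covered = np.zeros(len(mesh.facets), dtype=bool)
    for name, pred in rules.items():
        sel = np.asarray(pred(cen, nor), dtype=bool)
        dup = sel & covered
        if dup.any():
            raise MeshError(
                f"rule {name!r} re-covers facet at {cen[dup][0]}")
        if name == "wall":
            tag = WALL
        elif name == "inlet":
            tag = INLET
        else:
            tag = next_outlet
            next_outlet += 1
        tags[sel] = tag
        names[tag] = name
        covered |= sel
    if not covered.all():
        raise MeshError(
            f"facet at {cen[~covered][0]} not covered by any rule")
    mesh.facet_tags = tags
    mesh.facet_names = names
    return mesh


def tag_tube_caps(mesh: VolumeMesh, axis=(0, 0, 1), lo=0.0, hi=None,
                  tol: float = 1e-6) -> VolumeMesh:
    """Tag a tube-like mesh: planar caps at ``axis.x = lo`` / ``hi``."""
    ax = np.asarray(axis, float)
    ax = ax / np.linalg.norm(ax)
    if hi is None:
        hi = float(mesh.vertices[:mesh.n_p1] @ ax)  # pragma: no cover
    span = hi - lo
    eps = tol * max(span, 1.0)
    return tag_boundaries(mesh, {
        "inlet": lambda c, n: (c @ ax) < lo + eps,
        "outlet": lambda c, n: (c @ ax) > hi - eps,
        "wall": lambda c, n: ((c @ ax) >= lo + eps) & ((c @ ax) <= hi - eps),
    })


# ---------------------------------------------------------------------------
# structured tube meshes (verification geometry)
# ---------------------------------------------------------------------------

def _disk_points(radius: float, n_rings: int, n_circ: int):
    pts = [(0.0, 0.0)]
    for i in range(1, n_rings + 1):
        r = radius * i / n_rings
        m = max(6, int(round(n_circ * i / n_rings)))
        if i == n_rings:
            m = n_circ
        th = 2 * np.pi * (np.arange(m) + 0.5 * (i % 2)) / m
        pts.extend(zip(r * np.cos(th), r * np.sin(th)))
    return np.array(pts)


_PRISM_ROT = np.array([
    [0, 1, 2, 3, 4, 5],
    [1, 2, 0, 4, 5, 3],
    [2, 0, 1, 5, 3, 4],
    [3, 5, 4, 0, 2, 1],
    [4, 3, 5, 1, 0, 2],
    [5, 4, 3, 2, 1, 0],
])


def _split_prisms(prisms: np.ndarray) -> np.ndarray:
    """Split each 6-node prism into 3 tets with globally consistent quad-face
    diagonals (smallest-global-index rule), so adjacent prisms conform."""
    g = prisms
    slot = np.argmin(g, axis=1)
    perm = _PRISM_ROT[slot]
    h = np.take_along_axis(g, perm, axis=1)
    left = np.minimum(h[:, 1], h[:, 5]) < np.minimum(h[:, 2], h[:, 4])
    tets = np.empty((len(g), 3, 4), dtype=np.int64)
    tets[left, 0] = h[left][:, [0, 1, 2, 5]]
    tets[left, 1] = h[left][:, [0, 1, 5, 4]]
    tets[left, 2] = h[left][:, [0, 4, 5, 3]]
    r = ~left
    tets[r, 0] = h[r][:, [0, 1, 2, 4]]
    tets[r, 1] = h[r][:, [0, 4, 2, 5]]
    tets[r, 2] = h[r][:, [0, 4, 5, 3]]
    return tets.reshape(-1, 4)


def cosine_bump(s: np.ndarray, center: float, width: float) -> np.ndarray:
    """C1 bump: 1 at ``center``, 0 outside ``|s-center| > width/2``."""
    s = np.asarray(s, float)
    w = np.zeros_like(s)
    m = np.abs(s - center) <= width / 2
    w[m] = 0.5 * (1 + np.cos(2 * np.pi * (s[m] - center) / width))
    return w


def structured_tube_mesh(radius: float, length: float, h: float,
                         ellipticity: float = 1.0,
                         stenosis=None,
                         axial_h: float | None = None) -> VolumeMesh:
    """Swept tet mesh of a straight tube along +z, inlet at z=0.

    ``h`` controls the cross-sectional resolution (ring spacing and
    circumferential spacing); ``axial_h`` the layer height (defaults to
    ``h``).  ``stenosis``, if given, is ``(center_fraction, width_fraction,
    severity)`` applied to the radius profile
    ``r(z) = R (1 - severity * bump(z/L))``.
    """
    if radius <= 0 or length <= 0:
        raise MeshError("radius and length must be positive")
    if not (0 < ellipticity <= 1):
        raise MeshError("ellipticity must be in (0, 1]")
    n_r = max(2, int(round(radius / h)))
    n_c = max(12, int(round(2 * np.pi * radius / h)))
    n_z = max(2, int(round(length / (axial_h or h))))
    disk = _disk_points(radius, n_r, n_c)
    tri = Delaunay(disk).simplices
    npts = len(disk)
    # drop degenerate boundary slivers Delaunay may create on co-circular pts
    p = disk[tri]
    u = p[:, 1] - p[:, 0]
    v = p[:, 2] - p[:, 0]
    area2 = np.abs(u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0])
    tri = tri[area2 > 1e-12 * radius ** 2]

    z = np.linspace(0, length, n_z + 1)
    verts = np.empty(((n_z + 1) * npts, 3))
    for k in range(n_z + 1):
        sl = slice(k * npts, (k + 1) * npts)
        verts[sl, 0] = disk[:, 0]
        verts[sl, 1] = disk[:, 1] * ellipticity
        verts[sl, 2] = z[k]
    if stenosis is not None:
        center, width, severity = stenosis
        if not (0 <= severity < 1):
            raise MeshError("stenosis severity must be in [0, 1)")
        scale = 1 - severity * cosine_bump(verts[:, 2] / length, center, width)
        verts[:, 0] *= scale
        verts[:, 1] *= scale
    prisms = np.empty((n_z * len(tri), 6), dtype=np.int64)
    for k in range(n_z):
        sl = slice(k * len(tri), (k + 1) * len(tri))
        prisms[sl, :3] = tri + k * npts
        prisms[sl, 3:] = tri + (k + 1) * npts
    tets = _split_prisms(prisms)
    mesh = from_p1(verts, tets, element_size=h)
    return tag_tube_caps(mesh, (0, 0, 1), 0.0, length)


# ---------------------------------------------------------------------------
# generic tetrahedralization of a watertight surface
# ---------------------------------------------------------------------------

def _largest_component(tets: np.ndarray) -> np.ndarray:
    """Keep only the largest face-connected set of tets: stray fragments of
    the inside/outside filter would carry their own undetermined pressure
    level and make the flow system singular."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components
    faces = np.sort(tets[:, TET_FACES].reshape(-1, 3), axis=1)
    order = np.lexsort(faces.T)
    f = faces[order]
    owner = order // 4
    same = np.all(f[1:] == f[:-1], axis=1)
    a = owner[:-1][same]
    b = owner[1:][same]
    n = len(tets)
    G = coo_matrix((np.ones(len(a)), (a, b)), shape=(n, n))
    ncomp, lab = connected_components(G, directed=False)
    if ncomp > 1:
        keep = lab == np.bincount(lab).argmax()
        warnings.warn(f"discarding {n - keep.sum()} tets in "
                      f"{ncomp - 1} disconnected fragment(s)")
        return tets[keep]
    return tets


def tetrahedralize(surface, target_h: float, seed: int = 0,
                   quality_peel: float = 25.0) -> VolumeMesh:
    """Fill a watertight triangulated surface with P2 tetrahedra.

    Interior lattice points (spacing ``target_h``, lightly jittered for
    Delaunay robustness) are combined with the surface vertices and
    Delaunay-triangulated; tetrahedra whose centroid lies outside the lumen
    are discarded.  Boundary facets inherit the tag of the nearest surface
    triangle.  Boundary slivers with normalized radius-ratio above
    ``quality_peel`` are peeled off (they only dent the boundary by a
    fraction of ``target_h``).

    ``surface`` is an :class:`archflow.phantoms.TaggedSurface` or any object
    with ``vertices``, ``faces``, ``face_tags``, ``tag_names`` and either a
    vectorized ``sdf(points)`` or a ``contains(points)`` method.
    """
    import trimesh

    if target_h <= 0:
        raise MeshError("target_h must be positive")
    tm = trimesh.Trimesh(vertices=np.asarray(surface.vertices, float),
                         faces=np.asarray(surface.faces), process=False)
    if not tm.is_watertight:
        edges = trimesh.grouping.group_rows(tm.edges_sorted, require_count=1)
        raise MeshError(
            f"surface is not watertight: {len(edges)} boundary edges, "
            f"first at {tm.vertices[tm.edges[edges[0]][0]] if len(edges) else '?'}")

    sdf = getattr(surface, "sdf", None)

    def inside(pts, slack=0.0):
        # `slack` admits centroids marginally outside the implicit surface:
        # the triangulated surface is a linear interpolation of it, so tets
        # spanning surface vertices in concave (junction) regions can have
        # centroids slightly past the zero level; culling them dents the
        # boundary inward
        if sdf is not None:
            return sdf(pts) < slack
        return contains_parity(tm.vertices.view(np.ndarray), tm.faces, pts)

    lo, hi = tm.bounds
    rng = np.random.default_rng(seed)
    axes = [np.arange(lo[d] + target_h / 2, hi[d], target_h) for d in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    grid = grid + rng.uniform(-0.12, 0.12, grid.shape) * target_h
    if sdf is not None:
        keep = sdf(grid) < -0.4 * target_h
    else:
        prox = TriangleProximity(tm.vertices.view(np.ndarray)[tm.faces])
        dist, _ = prox.query(grid)
        keep = inside(grid) & (dist > 0.4 * target_h)
    pts = np.vstack([tm.vertices, grid[keep]])

    tets = Delaunay(pts).simplices
    tets = tets[np.abs(tet_volumes(pts, tets)) > 1e-9 * target_h ** 3]
    cen = pts[tets].mean(axis=1)
    tets = tets[inside(cen, slack=0.35 * target_h)]
    if len(tets) == 0:
        raise MeshError("no interior tetrahedra; target_h too coarse?")
    tets = _largest_component(tets)
    tets = orient_cells(pts, tets)

    # peel pathological boundary slivers (small volume AND bad shape only,
    # so legitimately large boundary cells of coarse meshes survive)
    for _ in range(12):
        rr = radius_ratios(pts, tets)
        vol = tet_volumes(pts, tets)
        _, parents = boundary_faces(tets)
        bad = np.zeros(len(tets), dtype=bool)
        bad[parents] = True
        bad &= (rr > quality_peel) & (np.abs(vol) < 0.05 * target_h ** 3)
        if not bad.any():
            break
        tets = tets[~bad]

    # drop vertices unreferenced after filtering/peeling (they would give
    # empty rows, i.e. a structurally singular flow system)
    used = np.unique(tets.ravel())
    remap = np.full(len(pts), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    pts = pts[used]
    tets = remap[tets]

    mesh = from_p1(pts, tets, element_size=target_h)

    # transfer surface tags to boundary facets via nearest surface triangle
    cen, _, _ = mesh.facet_geometry()
    _, tri_id = TriangleProximity(
        tm.vertices.view(np.ndarray)[tm.faces]).query(cen)
    mesh.facet_tags = np.asarray(surface.face_tags)[tri_id]
    mesh.facet_names = dict(surface.tag_names)

    # region tags via the surface's point classifier when available
    classify = getattr(surface, "classify_points", None)
    if classify is not None:
        cell_cen = mesh.vertices[mesh.cells[:, :4]].mean(axis=1)
        mesh.region_tags = np.asarray(classify(cell_cen))
        mesh.region_names = dict(getattr(surface, "region_names", {}))
    return mesh


def refinement_series(surface, h_values, seed: int = 0,
                      mesher=None) -> list[VolumeMesh]:
    """One mesh per ``h`` (strictly decreasing), for convergence studies."""
    h_values = list(h_values)
    if any(b >= a for a, b in zip(h_values, h_values[1:])):
        raise MeshError("h_values must be strictly decreasing")
    mesher = mesher or (lambda h: tetrahedralize(surface, h, seed=seed))
    meshes = [mesher(h) for h in h_values]
    counts = [len(m.cells) for m in meshes]
    if any(b <= a for a, b in zip(counts, counts[1:])):
        warnings.warn(f"cell counts not strictly increasing: {counts}")
    return meshes
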