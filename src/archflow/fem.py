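"""Low-level finite-element kernels for Taylor-Hood (P2-P1) tetrahedra.

Velocity lives in continuous piecewise-quadratic (P2) space, pressure in
continuous piecewise-linear (P1); the pair is inf-sup (LBB) stable, so no
pressure stabilization is required.  Elements are straight-edged: the
geometry map is affine (defined by the four corner vertices), mid-edge
nodes sit at edge midpoints, so all Jacobians are constant per cell and
assembly vectorizes cleanly over cells.

Conventions
-----------
* P2 cell connectivity: ``[v0 v1 v2 v3 | m01 m02 m03 m12 m13 m23]`` where
  ``mab`` is the node at the midpoint of edge (va, vb).
* P2 facet connectivity: ``[v0 v1 v2 | m01 m12 m02]`` (VTK quadratic
  triangle ordering).
* Velocity dofs are component-blocked: ``[ux(0..n2) uy(..) uz(..)]``.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from numpy.polynomial.legendre import leggauss
from scipy.special import roots_jacobi

# canonical edge list of the reference tetrahedron (defines P2 node order)
TET_EDGES = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))
# facet node order: vertices then edge midpoints (0,1), (1,2), (0,2)
TRI_EDGES = ((0, 1), (1, 2), (0, 2))


# ---------------------------------------------------------------------------
# quadrature (conical-product Gauss rules: positive weights, arbitrary order)
# ---------------------------------------------------------------------------

def tet_quadrature(n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Conical-product rule on the reference tetrahedron.

    Exact for polynomials of total degree ``2n - 1``.  Returns barycentric
    points ``(nq, 4)`` and weights summing to 1 (reference volume 1/6 is
    folded into the cell Jacobian elsewhere as ``detJ / 6`` -- here weights
    sum to 1 and are multiplied by cell volume).
    """
    xg, wg = leggauss(n)
    xj1, wj1 = roots_jacobi(n, 1, 0)
    xj2, wj2 = roots_jacobi(n, 2, 0)
    # map from [-1, 1] to [0, 1]
    a, wa = (xj2 + 1) / 2, wj2 / 8  # weight (1-x)^2 absorbed
    b, wb = (xj1 + 1) / 2, wj1 / 4  # weight (1-x)^1 absorbed
    c, wc = (xg + 1) / 2, wg / 2
    pts, wts = [], []
    for i in range(n):
        for j in range(n):
            for k in range(n):
                x = a[i]
                y = b[j] * (1 - x)
                z = c[k] * (1 - x - y)
                pts.append((1 - x - y - z, x, y, z))
                wts.append(wa[i] * wb[j] * wc[k])
    w = np.array(wts)
    return np.array(pts), w / w.sum()


def tri_quadrature(n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Conical-product rule on the reference triangle (barycentric, (nq,3))."""
    xg, wg = leggauss(n)
    xj1, wj1 = roots_jacobi(n, 1, 0)
    a, wa = (xj1 + 1) / 2, wj1 / 4
    c, wc = (xg + 1) / 2, wg / 2
    pts, wts = [], []
    for i in range(n):
        for k in range(n):
            x = a[i]
            y = c[k] * (1 - x)
            pts.append((1 - x - y, x, y))
            wts.append(wa[i] * wc[k])
    w = np.array(wts)
    return np.array(pts), w / w.sum()


# ---------------------------------------------------------------------------
# shape functions in barycentric coordinates
# ---------------------------------------------------------------------------

def shape_p2(lam: np.ndarray) -> np.ndarray:
    """P2 values, ``lam`` (nq, 4) -> (nq, 10)."""
    lam = np.asarray(lam, dtype=float)
    out = np.empty(lam.shape[:-1] + (10,))
    for i in range(4):
        out[..., i] = lam[..., i] * (2 * lam[..., i] - 1)
    for e, (a, b) in enumerate(TET_EDGES):
        out[..., 4 + e] = 4 * lam[..., a] * lam[..., b]
    return out


def dshape_p2(lam: np.ndarray) -> np.ndarray:
    """Derivatives of P2 basis w.r.t. the four barycentric coords: (nq, 10, 4)."""
    lam = np.asarray(lam, dtype=float)
    nq = lam.shape[0]
    d = np.zeros((nq, 10, 4))
    for i in range(4):
        d[:, i, i] = 4 * lam[:, i] - 1
    for e, (a, b) in enumerate(TET_EDGES):
        d[:, 4 + e, a] = 4 * lam[:, b]
        d[:, 4 + e, b] = 4 * lam[:, a]
    return d


def shape_p2_tri(lam: np.ndarray) -> np.ndarray:
    """Quadratic basis on a triangle face, ``lam`` (nq, 3) -> (nq, 6)."""
    lam = np.asarray(lam, dtype=float)
    out = np.empty(lam.shape[:-1] + (6,))
    for i in range(3):
        out[..., i] = lam[..., i] * (2 * lam[..., i] - 1)
    for e, (a, b) in enumerate(TRI_EDGES):
        out[..., 3 + e] = 4 * lam[..., a] * lam[..., b]
    return out


# ---------------------------------------------------------------------------
# per-cell geometry
# ---------------------------------------------------------------------------

def cell_geometry(verts: np.ndarray, tets: np.ndarray):
    """Affine geometry of straight-edged tets.

    Returns ``(grad_lam, vol)`` where ``grad_lam`` is (nc, 4, 3), the spatial
    gradients of the four barycentric coordinates, and ``vol`` (nc,) the
    signed cell volumes (positive for correctly oriented cells).
    """
    x = verts[tets[:, :4]]                      # (nc, 4, 3)
    J = x[:, 1:] - x[:, :1]                     # rows: edge vectors (nc, 3, 3)
    detJ = np.linalg.det(J)
    vol = detJ / 6.0
    Jinv = np.linalg.inv(J)                     # (nc, 3, 3)
    g = np.empty((len(tets), 4, 3))
    g[:, 1:, :] = np.transpose(Jinv, (0, 2, 1))  # grad lam_i = row i of J^-T
    g[:, 0, :] = -g[:, 1:, :].sum(axis=1)
    return g, vol


# ---------------------------------------------------------------------------
# operator assembly
# ---------------------------------------------------------------------------

_CHUNK = 20000


def _accumulate(rows, cols, vals, shape):
    A = sp.coo_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=shape)
    return A.tocsr()


def assemble_stiffness(verts, cells, grad_lam=None, vol=None) -> sp.csr_matrix:
    """Scalar P2 stiffness  K_ij = ∫ ∇N_i · ∇N_j  (one velocity component)."""
    n2 = int(cells.max()) + 1
    if grad_lam is None:
        grad_lam, vol = cell_geometry(verts, cells)
    lam, w = tet_quadrature(2)  # integrand is degree 2
    dN = dshape_p2(lam)         # (nq, 10, 4)
    rows, cols, vals = [], [], []
    for s in range(0, len(cells), _CHUNK):
        sl = slice(s, s + _CHUNK)
        G = grad_lam[sl]                               # (c, 4, 3)
        B = np.einsum('qia,cax->cqix', dN, G)          # (c, nq, 10, 3)
        Ke = np.einsum('q,cqix,cqjx->cij', w, B, B)
        Ke *= vol[sl][:, None, None]
        c = cells[sl]
        rows.append(np.repeat(c, 10, axis=1).ravel())
        cols.append(np.tile(c, (1, 10)).ravel())
        vals.append(Ke.ravel())
    return _accumulate(rows, cols, vals, (n2, n2))


def assemble_mass(verts, cells, grad_lam=None, vol=None) -> sp.csr_matrix:
    """Scalar P2 mass matrix  M_ij = ∫ N_i N_j."""
    n2 = int(cells.max()) + 1
    if vol is None:
        _, vol = cell_geometry(verts, cells)
    lam, w = tet_quadrature(3)  # degree 4 integrand
    N = shape_p2(lam)
    Mref = np.einsum('q,qi,qj->ij', w, N, N)  # same on every cell
    rows, cols, vals = [], [], []
    for s in range(0, len(cells), _CHUNK):
        sl = slice(s, s + _CHUNK)
        Me = Mref[None, :, :] * vol[sl][:, None, None]
        c = cells[sl]
        rows.append(np.repeat(c, 10, axis=1).ravel())
        cols.append(np.tile(c, (1, 10)).ravel())
        vals.append(Me.ravel())
    return _accumulate(rows, cols, vals, (n2, n2))


def assemble_divergence(verts, cells, grad_lam=None, vol=None) -> sp.csr_matrix:
    """Mixed divergence operator  D[q, c*n2 + i] = ∫ lam_q ∂N_i/∂x_c.

    Rows are P1 (vertex) dofs, columns are component-blocked P2 dofs.
    """
    n2 = int(cells.max()) + 1
    nv = int(cells[:, :4].max()) + 1
    if grad_lam is None:
        grad_lam, vol = cell_geometry(verts, cells)
    lam, w = tet_quadrature(2)  # P1 * dP2 -> degree 2
    dN = dshape_p2(lam)
    rows, cols, vals = [], [], []
    for s in range(0, len(cells), _CHUNK):
        sl = slice(s, s + _CHUNK)
        G = grad_lam[sl]
        B = np.einsum('qia,cax->cqix', dN, G)               # (c, q, 10, 3)
        De = np.einsum('q,qp,cqix->cpix', w, lam[:, :4], B)  # (c, 4, 10, 3)
        De *= vol[sl][:, None, None, None]
        cv = cells[sl, :4]
        c2 = cells[sl]
        nc = len(c2)
        r = np.broadcast_to(cv[:, :, None, None], (nc, 4, 10, 3))
        comp = np.arange(3)[None, None, None, :]
        cc = c2[:, None, :, None] + comp * n2
        cc = np.broadcast_to(cc, (nc, 4, 10, 3))
        rows.append(r.ravel())
        cols.append(cc.ravel())
        vals.append(De.ravel())
    return _accumulate(rows, cols, vals, (nv, 3 * n2))


def assemble_convection(verts, cells, w_nodal, grad_lam=None, vol=None) -> sp.csr_matrix:
    """Scalar Oseen convection  C_ij = ∫ N_i (w · ∇N_j) for frozen field w.

    ``w_nodal``: (n2, 3) P2 nodal values of the convective velocity.  The
    same scalar operator applies to each velocity component.
    """
    n2 = int(cells.max()) + 1
    if grad_lam is None:
        grad_lam, vol = cell_geometry(verts, cells)
    lam, w = tet_quadrature(3)
    N = shape_p2(lam)
    dN = dshape_p2(lam)
    rows, cols, vals = [], [], []
    for s in range(0, len(cells), _CHUNK):
        sl = slice(s, s + _CHUNK)
        G = grad_lam[sl]
        B = np.einsum('qia,cax->cqix', dN, G)          # (c, q, 10, 3)
        wq = np.einsum('qi,cix->cqx', N, w_nodal[cells[sl]])
        wdotB = np.einsum('cqx,cqjx->cqj', wq, B)      # (c, q, 10)
        Ce = np.einsum('q,qi,cqj->cij', w, N, wdotB)
        Ce *= vol[sl][:, None, None]
        c = cells[sl]
        rows.append(np.repeat(c, 10, axis=1).ravel())
        cols.append(np.tile(c, (1, 10)).ravel())
        vals.append(Ce.ravel())
    return _accumulate(rows, cols, vals, (n2, n2))


def convection_rhs(verts, cells, u_nodal, grad_lam=None, vol=None) -> np.ndarray:
    """Action  r[c*n2+i] = ∫ N_i (u · ∇u)_c  for a P2 nodal field u (n2, 3).

    Used for fully explicit treatment of the convective term: the result is
    moved to the right-hand side so the system matrix stays constant.
    """
    n2 = int(cells.max()) + 1
    if grad_lam is None:
        grad_lam, vol = cell_geometry(verts, cells)
    # degree-3 rule: mildly under-integrates the degree-5 integrand, which
    # is well below the explicit-in-time lag error of this term and the
    # term itself is a small perturbation at the Reynolds numbers modeled
    lam, w = tet_quadrature(2)
    N = shape_p2(lam)
    dN = dshape_p2(lam)
    out = np.zeros(3 * n2)
    for s in range(0, len(cells), _CHUNK):
        sl = slice(s, s + _CHUNK)
        G = grad_lam[sl]
        un = u_nodal[cells[sl]]                         # (c, 10, 3)
        B = np.einsum('qia,cax->cqix', dN, G)
        uq = np.einsum('qi,cix->cqx', N, un)            # (c, q, 3)
        gradu = np.einsum('ciy,cqix->cqyx', un, B)      # gradu[c,q,y,x] = ∂u_y/∂x_x
        conv = np.einsum('cqx,cqyx->cqy', uq, gradu)    # (u·∇u)_y = u_x ∂u_y/∂x_x
        re = np.einsum('q,qi,cqy->ciy', w, N, conv)
        re *= vol[sl][:, None, None]
        for comp in range(3):
            np.add.at(out, cells[sl].ravel() + comp * n2,
                      re[:, :, comp].ravel())
    return out


def facet_load_vector(verts, facets, values, normals, areas, n2) -> np.ndarray:
    """RHS from a prescribed normal traction  -p_bc n  on boundary facets.

    On a straight-edged quadratic triangle, ∫ N_i dA is 0 at vertices and
    A/3 at each edge midpoint, so only midpoint dofs receive load.
    ``values``: per-facet scalar p_bc; ``normals`` outward unit normals.
    """
    out = np.zeros(3 * n2)
    load = -(values * areas / 3.0)                     # (nf,)
    mids = facets[:, 3:6]                              # (nf, 3) midpoint nodes
    for comp in range(3):
        contrib = load * normals[:, comp]
        np.add.at(out, (mids + comp * n2).ravel(),
                  np.repeat(contrib, 3))
    return out


# ---------------------------------------------------------------------------
# Dirichlet elimination & saddle-point solve helpers
# ---------------------------------------------------------------------------

def apply_dirichlet(A: sp.csr_matrix, dofs: np.ndarray) -> sp.csr_matrix:
    """Zero rows/columns of constrained dofs and put 1 on the diagonal.

    Valid for homogeneous (no-slip) constraints: the RHS entries of the
    constrained dofs must simply be set to zero by the caller.
    """
    n = A.shape[0]
    keep = np.ones(n)
    keep[dofs] = 0.0
    Dk = sp.diags(keep)
    A2 = Dk @ A @ Dk
    diag = np.zeros(n)
    diag[dofs] = 1.0
    return (A2 + sp.diags(diag)).tocsr()


def saddle_matrix(A: sp.csr_matrix, D: sp.csr_matrix,
                  dirichlet: np.ndarray,
                  pin_pressure: np.ndarray | None = None) -> sp.csc_matrix:
    """Monolithic Stokes-type matrix  [[A, -Dᵀ], [D, 0]] with no-slip rows
    eliminated from both the momentum block and the continuity operator.

    ``pin_pressure`` lists pressure dofs to be fixed at zero (isolated or
    stagnant-chamber dofs whose level the equations leave undetermined).
    """
    nu = A.shape[0]
    npr = D.shape[0]
    keep = np.ones(nu)
    keep[dirichlet] = 0.0
    Dk = sp.diags(keep)
    Dc = (D @ Dk).tocsr()          # continuity ignores constrained dofs
    Am = apply_dirichlet(A, dirichlet)
    Gt = (-(Dk @ D.T)).tocsr()     # no pressure force on constrained rows
    # pressure dofs whose continuity row vanished entirely are always pinned
    rowsum = np.asarray(np.abs(Dc).sum(axis=1)).ravel()
    pin = rowsum < 1e-300
    if pin_pressure is not None and len(pin_pressure):
        pin[np.asarray(pin_pressure, dtype=np.int64)] = True
    Sreg = None
    if pin.any():
        keep_p = np.ones(npr)
        keep_p[pin] = 0.0
        Dkp = sp.diags(keep_p)
        Dc = (Dkp @ Dc).tocsr()
        Gt = (Gt @ Dkp).tocsr()
        Sreg = sp.diags(pin.astype(float))
    K = sp.bmat([[Am, Gt], [Dc, Sreg]], format='csc')
    return K


def stagnant_pressure_components(cells: np.ndarray, n_p1: int,
                                 wall_nodes: np.ndarray,
                                 anchored_vertices: np.ndarray) -> np.ndarray:
    """Pressure vertices in flow 'chambers' with no path of unconstrained
    velocity dofs to a traction (cap) boundary.

    Their pressure level is undetermined (e.g. behind a fully no-slip
    choke in a marginally resolved narrow vessel); one representative per
    chamber must be pinned.  Returns the vertex ids to pin.
    """
    from scipy.sparse.csgraph import connected_components

    free = np.ones(int(cells.max()) + 1, dtype=bool)
    free[wall_nodes] = False
    cell_free = free[cells].any(axis=1)
    cv = cells[cell_free][:, :4]
    rows = np.concatenate([cv[:, 0], cv[:, 0], cv[:, 0]])
    cols = np.concatenate([cv[:, 1], cv[:, 2], cv[:, 3]])
    G = sp.coo_matrix((np.ones(len(rows)), (rows, cols)),
                      shape=(n_p1, n_p1))
    ncomp, lab = connected_components(G, directed=False)
    anchored_labels = np.unique(lab[anchored_vertices])
    # vertices of free cells only; others are handled by the empty-row pin
    involved = np.unique(cv.ravel())
    involved = involved[involved < n_p1]
    pins = []
    for comp in np.unique(lab[involved]):
        if comp not in anchored_labels:
            members = involved[lab[involved] == comp]
            pins.append(members[0])
    return np.asarray(pins, dtype=np.int64)


# ---------------------------------------------------------------------------
# point location and field evaluation
# ---------------------------------------------------------------------------

class CellLocator:
    """Locate points in a straight-edged tet mesh (KD-tree + barycentric test)."""

    def __init__(self, verts: np.ndarray, cells: np.ndarray):
        from scipy.spatial import cKDTree
        self.verts = verts
        self.cells = cells
        x = verts[cells[:, :4]]
        self.centroids = x.mean(axis=1)
        self.tree = cKDTree(self.centroids)
        self.x0 = x[:, 0]
        self.Jinv = np.linalg.inv(np.transpose(x[:, 1:] - x[:, :1], (0, 2, 1)))
        # circumscribing search radius per cell
        self.radius = np.linalg.norm(x - self.centroids[:, None, :],
                                     axis=2).max(axis=1)
        self.max_radius = float(self.radius.max())

    def barycentric(self, pts: np.ndarray, cell_ids: np.ndarray) -> np.ndarray:
        """(np, 4) barycentric coordinates of pts w.r.t. the given cells."""
        rel = pts - self.x0[cell_ids]
        xi = np.einsum('nxy,ny->nx', self.Jinv[cell_ids], rel)
        lam = np.empty((len(pts), 4))
        lam[:, 1:] = xi
        lam[:, 0] = 1 - xi.sum(axis=1)
        return lam

    def locate(self, pts: np.ndarray, k: int = 32, tol: float = 1e-9):
        """Return (cell_id, lam) per point; cell_id = -1 when outside."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        n = len(pts)
        found = np.full(n, -1, dtype=np.int64)
        lam_out = np.zeros((n, 4))
        kq = min(k, len(self.centroids))
        _, idx = self.tree.query(pts, k=kq)
        idx = np.atleast_2d(idx)
        pending = np.arange(n)
        for j in range(idx.shape[1]):
            if len(pending) == 0:
                break
            cand = idx[pending, j]
            lam = self.barycentric(pts[pending], cand)
            ok = lam.min(axis=1) >= -tol
            hit = pending[ok]
            found[hit] = cand[ok]
            lam_out[hit] = lam[ok]
            pending = pending[~ok]
        if len(pending):
            # fall back: all cells whose circumsphere could contain the point
            for i in pending:
                near = self.tree.query_ball_point(pts[i], self.max_radius * 1.5)
                if not near:
                    continue
                near = np.asarray(near)
                lam = self.barycentric(np.repeat(pts[i][None], len(near), 0), near)
                best = lam.min(axis=1).argmax()
                if lam[best].min() >= -1e-6:
                    found[i] = near[best]
                    lam_out[i] = lam[best]
        return found, lam_out


def eval_p2(cells, nodal, cell_ids, lam) -> np.ndarray:
    """Evaluate a P2 field (n2,) or (n2, d) at located points."""
    N = shape_p2(lam)                      # (np, 10)
    vals = nodal[cells[cell_ids]]          # (np, 10) or (np, 10, d)
    if vals.ndim == 2:
        return np.einsum('pi,pi->p', N, vals)
    return np.einsum('pi,pid->pd', N, vals)


def eval_p1(cells, nodal, cell_ids, lam) -> np.ndarray:
    """Evaluate a P1 (vertex) field at located points."""
    vals = nodal[cells[cell_ids, :4]]
    if vals.ndim == 2:
        return np.einsum('pi,pi->p', lam, vals)
    return np.einsum('pi,pid->pd', lam, vals)


def eval_grad_p2(verts, cells, nodal, cell_ids, lam) -> np.ndarray:
    """Gradient of a P2 vector field at located points: (np, 3, 3),
    entry [p, i, j] = ∂u_i/∂x_j."""
    grad_lam, _ = cell_geometry(verts, cells[cell_ids])
    # note: cell_geometry recomputes per located cell; fine for modest batches
    dN = dshape_p2(lam)                    # treat each point as its own "q"
    B = np.einsum('pia,pax->pix', dN, grad_lam)
    un = nodal[cells[cell_ids]]            # (np, 10, 3)
    return np.einsum('piy,pix->pyx', un, B)
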