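"""Unsteady incompressible Navier-Stokes solver on Taylor-Hood tetrahedra.

Models blood in the embryonic vasculature as an incompressible Newtonian
fluid (momentum + incompressibility):

    rho Du/Dt + grad p - mu lap u = f,      div u = 0,

with rigid impermeable no-slip walls and pulsatile *pressure* boundary
conditions at the inlet/outlet caps, imposed weakly as a prescribed normal
traction ``(mu du/dn - p n) = -p_bc(t) n`` (the "do-nothing" form, exact
for fully developed flow and permitting flow reversal).

Discretization: P2 velocity / P1 pressure (LBB stable, no stabilization),
backward-Euler time stepping.  The nonlinear convective term is treated
explicitly by default (evaluated at the previous step and moved to the
right-hand side) so the saddle-point matrix is factorized once per run;
at the Reynolds numbers of early embryonic flow (0.1-9) the convective
term is a small, diffusion-dominated perturbation and this is stable at
the default dt.  A semi-implicit Oseen variant and Picard iteration are
available for stiffer regimes.

Units: meshes carry coordinates in mm; the solver converts geometry to
metres on load and works in SI throughout (velocity m/s, pressure Pa).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from . import fem
from .mesh import WALL, VolumeMesh

logger = logging.getLogger("archflow.solver")

MM = 1e-3  # mm -> m


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian blood model. Embryonic chick blood at the modeled stage is
    effectively Newtonian (few circulating erythrocytes)."""
    density: float = 1060.0       # kg/m^3
    viscosity: float = 3.71e-3    # Pa s

    def __post_init__(self):
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be positive")

    @property
    def kinematic_viscosity(self) -> float:
        return self.viscosity / self.density


class PressureWaveform:
    """T-periodic pressure signal (Pa): sinusoid or sampled table.

    Sampled tables are interpolated periodically and piecewise-linearly.
    The default cardiac period is 0.4 s (configurable).
    """

    def __init__(self, *, mean: float = 0.0, amplitude: float = 0.0,
                 period: float = 0.4, phase: float = 0.0,
                 samples: np.ndarray | None = None):
        if samples is not None:
            samples = np.asarray(samples, dtype=float)
            if samples.ndim != 2 or samples.shape[1] != 2 or len(samples) < 2:
                raise ValueError("samples must be an (n, 2) [t_s, p_Pa] table")
            t = samples[:, 0]
            if np.any(np.diff(t) <= 0):
                raise ValueError("sample times must be strictly increasing")
            period = float(t[-1] - t[0])
        if period <= 0:
            raise ValueError("period must be positive")
        self.mean, self.amplitude = float(mean), float(amplitude)
        self.period, self.phase = float(period), float(phase)
        self.samples = samples

    @classmethod
    def constant(cls, p: float, period: float = 0.4) -> "PressureWaveform":
        return cls(mean=p, amplitude=0.0, period=period)

    @classmethod
    def sinusoid(cls, mean: float, amplitude: float, period: float = 0.4,
                 phase: float = 0.0) -> "PressureWaveform":
        return cls(mean=mean, amplitude=amplitude, period=period, phase=phase)

    @classmethod
    def from_csv(cls, path) -> "PressureWaveform":
        """Two-column CSV ``t_s, p_Pa`` covering one period."""
        import pandas as pd
        df = pd.read_csv(path)
        return cls(samples=df.iloc[:, :2].to_numpy(dtype=float))

    def __call__(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        if self.samples is None:
            out = self.mean + self.amplitude * np.sin(
                2 * np.pi * t / self.period + self.phase)
        else:
            ts = self.samples[:, 0]
            tau = ts[0] + np.mod(t - ts[0], self.period)
            out = np.interp(tau, ts, self.samples[:, 1])
        return out if out.ndim else float(out)


@dataclass
class BoundarySpec:
    """Pressure BCs by boundary name; all untagged-by-name boundary facets
    must be walls.  ``body_force`` is a constant acceleration-density vector
    f (N/m^3), zero by default."""
    pressures: dict = field(default_factory=dict)   # name -> PressureWaveform
    body_force: tuple = (0.0, 0.0, 0.0)

    def period(self) -> float:
        periods = [w.period for w in self.pressures.values()]
        return max(periods) if periods else 0.4


@dataclass
class TimeSteppingSpec:
    dt: float = 0.01              # s
    n_cycles: int = 4
    convection: str = "explicit"  # explicit | oseen | picard | none
    picard_tol: float = 1e-8
    picard_max_iter: int = 25
    store_every: int = 1

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.convection not in ("explicit", "oseen", "picard", "none"):
            raise ValueError(f"unknown convection scheme {self.convection!r}")


@dataclass
class SolutionSeries:
    """Velocity/pressure fields at stored time levels.

    ``u`` is (n_times, n_p2_nodes, 3) in m/s; ``p`` is (n_times, n_p1) Pa.
    The mesh reference retains mm coordinates; ``verts_m`` are SI.
    """
    mesh: VolumeMesh
    fluid: FluidProperties
    times: np.ndarray
    u: np.ndarray
    p: np.ndarray
    residuals: np.ndarray | None = None

    @property
    def verts_m(self) -> np.ndarray:
        return self.mesh.vertices * MM

    def index_at(self, t: float) -> int:
        return int(np.argmin(np.abs(self.times - t)))

    def final_cycle(self, period: float) -> np.ndarray:
        """Indices of stored steps in the last full cycle."""
        t1 = self.times[-1]
        return np.nonzero(self.times >= t1 - period - 1e-12)[0]


@dataclass
class DiagnosticsReport:
    times: np.ndarray
    fluxes: dict                 # boundary name -> (n_times,) m^3/s, outward +
    mass_imbalance: np.ndarray   # |sum fluxes| / max |flux|
    peak_velocity: np.ndarray    # m/s
    cfl: np.ndarray
    reynolds: np.ndarray         # based on the inlet equivalent diameter


# ---------------------------------------------------------------------------
# discrete operators bound to a mesh + fluid
# ---------------------------------------------------------------------------

class Discretization:
    """Assembled Taylor-Hood operators for one mesh (SI units)."""

    def __init__(self, mesh: VolumeMesh, fluid: FluidProperties):
        if not mesh.facet_names:
            raise SolverError("mesh has no boundary tags; run tag_boundaries")
        self.mesh = mesh
        self.fluid = fluid
        self.verts = mesh.vertices * MM
        self.cells = mesh.cells
        self.n2 = len(self.verts)
        self.np1 = mesh.n_p1
        self.grad_lam, self.vol = fem.cell_geometry(self.verts, self.cells)
        if np.any(self.vol <= 0):
            raise SolverError("mesh contains non-positively oriented cells")
        self.K = fem.assemble_stiffness(self.verts, self.cells,
                                        self.grad_lam, self.vol)
        self.M = fem.assemble_mass(self.verts, self.cells,
                                   self.grad_lam, self.vol)
        self.D = fem.assemble_divergence(self.verts, self.cells,
                                         self.grad_lam, self.vol)
        wall = mesh.wall_nodes()
        self.dirichlet = np.concatenate(
            [wall + c * self.n2 for c in range(3)])
        cap_verts = np.unique(
            mesh.facets[mesh.facet_tags != WALL][:, :3].ravel())
        self.pin_pressure = fem.stagnant_pressure_components(
            self.cells, self.np1, wall, cap_verts)
        if len(self.pin_pressure):
            logger.warning(
                "%d stagnant pressure chamber(s) pinned: the mesh is too "
                "coarse to resolve flow through the narrowest passages",
                len(self.pin_pressure))
        cen, nor, area = mesh.facet_geometry()
        self.facet_normals = nor
        self.facet_areas = area * MM ** 2
        self.ndof = 3 * self.n2 + self.np1

    def momentum_matrix(self, dt: float | None, w_nodal=None) -> sp.csr_matrix:
        A1 = self.fluid.viscosity * self.K
        if dt is not None:
            A1 = A1 + (self.fluid.density / dt) * self.M
        A = sp.block_diag([A1] * 3).tocsr()
        if w_nodal is not None:
            C = fem.assemble_convection(self.verts, self.cells, w_nodal,
                                        self.grad_lam, self.vol)
            A = A + self.fluid.density * sp.block_diag([C] * 3).tocsr()
        return A

    def factorize(self, A: sp.csr_matrix):
        Ksys = fem.saddle_matrix(A, self.D, self.dirichlet,
                                 self.pin_pressure)
        self._Ksys = Ksys
        return splu(Ksys, permc_spec="MMD_AT_PLUS_A",
                    options=dict(SymmetricMode=True, DiagPivotThresh=0.01))

    def pressure_rhs(self, bcs: BoundarySpec, t: float) -> np.ndarray:
        rhs = np.zeros(3 * self.n2)
        for name, wave in bcs.pressures.items():
            tag = self.mesh.tag_of(name)
            sel = self.mesh.facet_tags == tag
            if not sel.any():
                raise SolverError(f"no facets tagged {name!r}")
            pv = float(wave(t))
            rhs += fem.facet_load_vector(
                self.verts, self.mesh.facets[sel],
                np.full(sel.sum(), pv), self.facet_normals[sel],
                self.facet_areas[sel], self.n2)
        f = np.asarray(bcs.body_force, dtype=float)
        if np.any(f != 0.0):
            msum = np.asarray(self.M.sum(axis=1)).ravel()
            for c in range(3):
                rhs[c * self.n2:(c + 1) * self.n2] += f[c] * msum
        return rhs

    def check_boundary_cover(self, bcs: BoundarySpec):
        tags = {self.mesh.tag_of(n) for n in bcs.pressures}
        tags.add(WALL)
        present = set(np.unique(self.mesh.facet_tags).tolist())
        missing = present - tags
        if missing:
            names = [self.mesh.facet_names.get(t, t) for t in missing]
            raise SolverError(
                f"boundary regions without wall/pressure condition: {names}")

    def solve_saddle(self, lu, rhs_mom: np.ndarray, label="") -> np.ndarray:
        rhs = np.zeros(self.ndof)
        rhs[:3 * self.n2] = rhs_mom
        rhs[self.dirichlet] = 0.0
        x = lu.solve(rhs)
        nrm = np.linalg.norm(rhs)
        if nrm > 0:
            res = np.linalg.norm(self._Ksys @ x - rhs) / nrm
            if res > 1e-10:                       # one refinement pass
                x = x + lu.solve(rhs - self._Ksys @ x)
                res = np.linalg.norm(self._Ksys @ x - rhs) / nrm
            if res > 1e-8:
                raise SolverError(f"linear solve {label}: residual {res:.2e}")
        return x

    def split(self, x: np.ndarray):
        u = x[:3 * self.n2].reshape(3, self.n2).T.copy()
        p = x[3 * self.n2:]
        return u, p


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------

def steady_solve(mesh: VolumeMesh, fluid: FluidProperties, bcs: BoundarySpec,
                 convection: str = "picard", tol: float = 1e-8,
                 max_iter: int = 25, t: float = 0.0) -> SolutionSeries:
    """Steady Stokes (``convection='none'``) or Navier-Stokes via Picard.

    Boundary pressures are evaluated at time ``t``.  Returns a one-snapshot
    :class:`SolutionSeries` so all post-processing applies uniformly.
    """
    disc = Discretization(mesh, fluid)
    disc.check_boundary_cover(bcs)
    rhs = disc.pressure_rhs(bcs, t)
    lu = disc.factorize(disc.momentum_matrix(None))
    x = disc.solve_saddle(lu, rhs, "stokes")
    u, p = disc.split(x)
    if convection != "none":
        history = []
        for it in range(max_iter):
            lu = disc.factorize(disc.momentum_matrix(None, w_nodal=u))
            x = disc.solve_saddle(lu, rhs, f"picard {it}")
            u_new, p = disc.split(x)
            unorm = np.linalg.norm(u_new)
            delta = np.linalg.norm(u_new - u) / max(unorm, 1e-300)
            history.append(delta)
            u = u_new
            logger.debug("picard %d: delta=%.3e", it, delta)
            if delta < tol:
                break
        else:
            raise SolverError(
                f"Picard did not converge in {max_iter} iterations; "
                f"delta history: {['%.2e' % d for d in history]}")
    return SolutionSeries(mesh=mesh, fluid=fluid, times=np.array([t]),
                          u=u[None], p=p[None])


def simulate(mesh: VolumeMesh, fluid: FluidProperties, bcs: BoundarySpec,
             ts: TimeSteppingSpec = None) -> SolutionSeries:
    """Pulsatile simulation over ``n_cycles`` cardiac cycles from rest.

    Runs backward Euler at fixed ``dt``; all accepted steps are stored
    (subject to ``store_every``).  Start-up transients decay within the
    first cycles; analyze the final cycle.
    """
    ts = ts or TimeSteppingSpec()
    disc = Discretization(mesh, fluid)
    disc.check_boundary_cover(bcs)
    period = bcs.period()
    n_steps = int(round(ts.n_cycles * period / ts.dt))
    rho, dt = fluid.density, ts.dt

    u = np.zeros((disc.n2, 3))
    p = np.zeros(disc.np1)
    times = [0.0]
    us, ps, residuals = [u.copy()], [p.copy()], [0.0]

    lu = None
    if ts.convection in ("explicit", "none"):
        lu = disc.factorize(disc.momentum_matrix(dt))
    Mrho = (rho / dt) * disc.M
    logger.info("simulate: %d steps of dt=%g s (%d cycles of T=%g s), "
                "%d dofs, convection=%s", n_steps, dt, ts.n_cycles, period,
                disc.ndof, ts.convection)
    for step in range(1, n_steps + 1):
        t = step * dt
        rhs = disc.pressure_rhs(bcs, t)
        for c in range(3):
            rhs[c * disc.n2:(c + 1) * disc.n2] += Mrho @ u[:, c]
        if ts.convection == "explicit":
            rhs -= rho * fem.convection_rhs(disc.verts, disc.cells, u,
                                            disc.grad_lam, disc.vol)
        if ts.convection in ("explicit", "none"):
            x = disc.solve_saddle(lu, rhs, f"step {step}")
            u, p = disc.split(x)
        elif ts.convection == "oseen":
            lu = disc.factorize(disc.momentum_matrix(dt, w_nodal=u))
            x = disc.solve_saddle(lu, rhs, f"step {step}")
            u, p = disc.split(x)
        else:  # picard
            w = u.copy()
            for it in range(ts.picard_max_iter):
                lu = disc.factorize(disc.momentum_matrix(dt, w_nodal=w))
                x = disc.solve_saddle(lu, rhs, f"step {step} picard {it}")
                u_new, p = disc.split(x)
                delta = (np.linalg.norm(u_new - w)
                         / max(np.linalg.norm(u_new), 1e-300))
                w = u_new
                if delta < ts.picard_tol:
                    break
            u = w
        if step % ts.store_every == 0 or step == n_steps:
            times.append(t)
            us.append(u.copy())
            ps.append(p.copy())
            residuals.append(0.0)
        if step % 40 == 0:
            logger.info("  step %d/%d t=%.3f s max|u|=%.3e m/s",
                        step, n_steps, t, np.abs(u).max())
    return SolutionSeries(mesh=mesh, fluid=fluid, times=np.array(times),
                          u=np.array(us), p=np.array(ps),
                          residuals=np.array(residuals))


# ---------------------------------------------------------------------------
# diagnostics and sampling
# ---------------------------------------------------------------------------

def boundary_flux(sol: SolutionSeries, tag: int) -> np.ndarray:
    """Outward volumetric flux (m^3/s) through a tagged boundary, per stored
    time.  Exact for the discrete P2 field (vertex basis functions have zero
    facet integral; midpoints carry A/3)."""
    mesh = sol.mesh
    sel = mesh.facets_with_tag(tag)
    if len(sel) == 0:
        return np.zeros(len(sol.times))
    _, nor, _ = mesh.facet_geometry()
    areas = mesh.facet_geometry()[2][sel] * MM ** 2
    mids = mesh.facets[sel][:, 3:6]
    un = np.einsum('tnmx,nx->tnm', sol.u[:, mids, :], nor[sel])
    return (un.sum(axis=2) * areas / 3.0).sum(axis=1)


def diagnostics(sol: SolutionSeries) -> DiagnosticsReport:
    """Mass balance, peak velocity, CFL and Reynolds number per stored step."""
    mesh = sol.mesh
    if len(sol.times) == 0:
        raise SolverError("empty solution series")
    fluxes = {}
    for tag, name in mesh.facet_names.items():
        if tag == WALL:
            continue
        fluxes[name] = boundary_flux(sol, tag)
    q = np.stack(list(fluxes.values()))
    maxflux = np.abs(q).max(axis=0)
    imbalance = np.abs(q.sum(axis=0)) / np.maximum(maxflux, 1e-300)
    speed = np.linalg.norm(sol.u, axis=2)
    peak = speed.max(axis=1)
    dt = np.median(np.diff(sol.times)) if len(sol.times) > 1 else 1.0
    h = max(sol.mesh.element_size, 1e-12) * MM
    cfl = peak * dt / h
    # Reynolds from the mean speed at the inlet cap and its equivalent diameter
    try:
        inlet = mesh.tag_of("inlet")
        area = mesh.facet_geometry()[2][mesh.facets_with_tag(inlet)].sum() * MM ** 2
        diam = 2 * np.sqrt(area / np.pi)
        ubar = np.abs(fluxes.get("inlet", np.zeros(len(sol.times)))) / area
        re = sol.fluid.density * ubar * diam / sol.fluid.viscosity
    except KeyError:
        re = np.zeros(len(sol.times))
    return DiagnosticsReport(times=sol.times, fluxes=fluxes,
                             mass_imbalance=imbalance, peak_velocity=peak,
                             cfl=cfl, reynolds=re)


def sample_line(sol: SolutionSeries, p0, p1, n: int,
                t: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Velocity magnitude (m/s) at ``n`` equally spaced points on a segment.

    ``p0``, ``p1`` in mm (mesh coordinates).  Returns (points_mm, |u|).
    Raises if any sample point falls outside the mesh.
    """
    idx = sol.index_at(t if t is not None else sol.times[-1])
    pts = np.linspace(np.asarray(p0, float), np.asarray(p1, float), n)
    loc = fem.CellLocator(sol.mesh.vertices, sol.mesh.cells)
    cid, lam = loc.locate(pts)
    if np.any(cid < 0):
        bad = int(np.nonzero(cid < 0)[0][0])
        raise SolverError(f"sample point {bad} at {pts[bad]} is outside mesh")
    uv = fem.eval_p2(sol.mesh.cells, sol.u[idx], cid, lam)
    return pts, np.linalg.norm(uv, axis=1)
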