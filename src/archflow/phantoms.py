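"""Parametric synthetic lumen geometries and landmark cohorts.

These phantoms emulate the embryonic aortic-arch anatomy at the stage where
three bilateral arch pairs (AA II, III, IV) connect a curved outflow tract
(OFT) to the dorsal aorta (DA): elliptical arch cross-sections, per-branch
radii and lengths, controllable stenoses, and optional cranial outlets on
the AA II pair.  They stand in for image-derived lumen segmentations so the
whole meshing / flow / geometry / morphometrics pipeline is testable with
known ground truth.

Anatomical frame (units mm): +x runs cranial -> caudal along the OFT, the
midsagittal mirror plane is y = 0 (left = +y), +z is dorsal.  Arch
centerlines are circular arcs in parasagittal planes x = const; the pairs
are mirror images.  Default dimensions are order-of-magnitude consistent
with reported arch diameters at this stage (tenths of a millimetre) and
follow the observed pattern: AA III is the shortest and widest pair, AA IV
the narrowest.

Straight and stenosed tubes are triangulated directly (exact radii - used
for convergence oracles); the branched phantom is built as the union of
capsule signed-distance fields and surfaced with marching cubes, which
guarantees a watertight manifold for any non-self-intersecting parameter
set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .mesh import FIRST_OUTLET, INLET, WALL


class PhantomError(ValueError):
    pass


# ---------------------------------------------------------------------------
# surface container
# ---------------------------------------------------------------------------

@dataclass
class TaggedSurface:
    """Watertight triangulated lumen surface with boundary-role face tags.

    ``face_tags``: wall / inlet / outlet ids per triangle (see
    :mod:`archflow.mesh` constants); ``sdf`` (optional) is a vectorized
    signed distance (negative inside) used for fast containment tests;
    ``classify_points`` (optional) maps interior points to anatomical
    region tags named in ``region_names``.
    """
    vertices: np.ndarray
    faces: np.ndarray
    face_tags: np.ndarray
    tag_names: dict
    sdf: object = None
    classify_points: object = None
    region_names: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def as_trimesh(self):
        import trimesh
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces,
                               process=False)

    def is_watertight(self) -> bool:
        return bool(self.as_trimesh().is_watertight)

    def enclosed_volume(self) -> float:
        return float(abs(self.as_trimesh().volume))


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TubeSpec:
    """Straight (elliptic) cylinder: semi-axes ``radius`` (major) and
    ``ellipticity * radius`` (minor, along y before rotation to ``axis``)."""
    radius: float = 0.05              # mm
    length: float = 1.0               # mm
    ellipticity: float = 1.0          # minor/major in (0, 1]
    axis: tuple = (0.0, 0.0, 1.0)
    circumferential_resolution: int = 48
    axial_resolution: int = 32

    def validate(self):
        if self.radius <= 0:
            raise PhantomError("radius must be positive")
        if self.length <= 0:
            raise PhantomError("length must be positive")
        if not (0 < self.ellipticity <= 1):
            raise PhantomError("ellipticity must be in (0, 1]")
        if self.circumferential_resolution < 8:
            raise PhantomError("circumferential_resolution must be >= 8")
        if self.axial_resolution < 4:
            raise PhantomError("axial_resolution must be >= 4")
        if np.linalg.norm(self.axis) == 0:
            raise PhantomError("axis must be a nonzero vector")


@dataclass(frozen=True)
class StenosisSpec:
    """Cosine-tapered (C1) radial constriction: r(s) = R (1 - severity w(s))
    with a bump w supported on |s - center| <= width/2, s = axial fraction."""
    center_fraction: float = 0.5
    width_fraction: float = 0.3
    severity: float = 0.5

    def validate(self):
        if not (0 < self.center_fraction < 1):
            raise PhantomError("center_fraction must be in (0, 1)")
        if not (0 < self.width_fraction < 1):
            raise PhantomError("width_fraction must be in (0, 1)")
        if not (0 <= self.severity < 1):
            raise PhantomError("severity must be in [0, 1): a fully "
                               "occluded vessel has no flow domain")


def _bump(s, center, width):
    s = np.asarray(s, float)
    w = np.zeros_like(s)
    m = np.abs(s - center) <= width / 2
    w[m] = 0.5 * (1 + np.cos(2 * np.pi * (s[m] - center) / width))
    return w


# ---------------------------------------------------------------------------
# straight / stenosed tubes (exact parametric triangulation)
# ---------------------------------------------------------------------------

def _rotation_to(axis) -> np.ndarray:
    """Rotation matrix taking +z to ``axis`` (Rodrigues)."""
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, a)
    c = float(z @ a)
    if np.linalg.norm(v) < 1e-14:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1 + c)


def make_stenosed_tube(spec: TubeSpec,
                       sten: StenosisSpec | None = None) -> TaggedSurface:
    """Capped elliptic cylinder with an optional stenosis; outward-oriented,
    watertight; caps tagged inlet (z=0) / outlet (z=L), side tagged wall."""
    spec.validate()
    if sten is not None:
        sten.validate()
    nc, na = spec.circumferential_resolution, spec.axial_resolution
    R, L, e = spec.radius, spec.length, spec.ellipticity
    th = 2 * np.pi * np.arange(nc) / nc
    zs = np.linspace(0, L, na + 1)
    scale = np.ones(na + 1)
    if sten is not None:
        scale = 1 - sten.severity * _bump(zs / L, sten.center_fraction,
                                          sten.width_fraction)
    verts = np.empty(((na + 1) * nc + 2, 3))
    for j, z in enumerate(zs):
        sl = slice(j * nc, (j + 1) * nc)
        verts[sl, 0] = R * scale[j] * np.cos(th)
        verts[sl, 1] = e * R * scale[j] * np.sin(th)
        verts[sl, 2] = z
    i_c0 = (na + 1) * nc       # inlet cap center
    i_c1 = i_c0 + 1            # outlet cap center
    verts[i_c0] = (0, 0, 0)
    verts[i_c1] = (0, 0, L)

    faces, tags = [], []
    for j in range(na):
        for k in range(nc):
            k1 = (k + 1) % nc
            a, b = j * nc + k, j * nc + k1
            c, d = (j + 1) * nc + k, (j + 1) * nc + k1
            faces += [(a, b, d), (a, d, c)]   # outward for CCW rings
            tags += [WALL, WALL]
    for k in range(nc):
        k1 = (k + 1) % nc
        faces.append((i_c0, k1, k))           # inlet cap, normal -z
        tags.append(INLET)
        base = na * nc
        faces.append((i_c1, base + k, base + k1))  # outlet cap, normal +z
        tags.append(FIRST_OUTLET)
    Rm = _rotation_to(spec.axis)
    verts = verts @ Rm.T

    def sdf(p):
        """Approximate signed distance (exact sign) of the capped tube."""
        q = np.atleast_2d(np.asarray(p, float)) @ Rm
        zq = np.clip(q[:, 2], 0.0, L)
        sc = np.ones_like(zq)
        if sten is not None:
            sc = 1 - sten.severity * _bump(zq / L, sten.center_fraction,
                                           sten.width_fraction)
        radial = np.sqrt(q[:, 0] ** 2 + (q[:, 1] / e) ** 2) - R * sc
        return np.maximum.reduce([radial, -q[:, 2], q[:, 2] - L])

    return TaggedSurface(vertices=verts, faces=np.array(faces),
                         face_tags=np.array(tags),
                         tag_names={WALL: "wall", INLET: "inlet",
                                    FIRST_OUTLET: "outlet"},
                         sdf=sdf)


def make_straight_tube(spec: TubeSpec) -> TaggedSurface:
    """Capped straight tube (stenosis-free special case)."""
    return make_stenosed_tube(spec, None)


# ---------------------------------------------------------------------------
# branched arch phantom (SDF union + marching cubes)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArchSpec:
    """One bilateral arch pair.  ``bulge`` is the lateral apex excursion of
    the circular-arc centerline (larger bulge = longer arch); ``radius`` the
    tube radius at the arch midline.  Ellipticity squashes the cross-section
    along the parasagittal-plane normal, leaving the long axis in-plane."""
    label: str
    radius: float                 # mm
    bulge: float                  # mm
    ellipticity: float = 0.8
    stenosis: StenosisSpec | None = None

    def validate(self):
        if self.radius <= 0 or self.bulge <= 0:
            raise PhantomError(f"{self.label}: radius and bulge must be > 0")
        if not (0 < self.ellipticity <= 1):
            raise PhantomError(f"{self.label}: ellipticity must be in (0,1]")
        if self.stenosis is not None:
            self.stenosis.validate()


def default_arch_pairs() -> tuple:
    # AA III shortest (small bulge) and widest; AA IV narrowest -- the
    # pattern reported for this developmental stage.
    return (ArchSpec("AA_II", radius=0.068, bulge=0.28, ellipticity=0.85),
            ArchSpec("AA_III", radius=0.080, bulge=0.20, ellipticity=0.85),
            ArchSpec("AA_IV", radius=0.060, bulge=0.28, ellipticity=0.85))


@dataclass(frozen=True)
class ArchPhantomSpec:
    oft_radius: float = 0.12
    oft_stenosis: StenosisSpec | None = None
    da_radius: float = 0.10
    arch_pairs: tuple = field(default_factory=default_arch_pairs)
    cranial_outlets: bool = False
    cranial_radius: float = 0.035
    pitch: float = 0.015          # marching-cubes grid spacing, mm
    mirror: bool = False
    seed: int = 0

    def validate(self):
        if len(self.arch_pairs) != 3:
            raise PhantomError("exactly 3 bilateral arch pairs are expected "
                               "at this stage")
        for a in self.arch_pairs:
            a.validate()
        if self.oft_radius <= 0 or self.da_radius <= 0:
            raise PhantomError("OFT/DA radii must be positive")
        if self.oft_stenosis is not None:
            self.oft_stenosis.validate()
        if self.pitch <= 0:
            raise PhantomError("pitch must be positive")


# geometric layout constants (mm)
_X_STATIONS = (0.25, 0.45, 0.65)
_Z_DA = 0.5
_OFT_SPAN = (-0.08, 0.70)       # clipped to x >= 0 by the inlet cap
_DA_SPAN = (0.18, 1.06)         # clipped to x <= 1.0 by the outlet cap
_OFT_RISE = 0.05
_X_OUT = 1.0
_CRANIAL_CLIP = 0.02

# region tags
REGION_OFT, REGION_DA = 10, 11
REGION_NAMES_BASE = {REGION_OFT: "OFT", REGION_DA: "DA"}


@dataclass
class Branch:
    """Capsule tube around a polyline with per-point radius; optionally
    squashed along ``e_axis`` (minor semi-axis = ellipticity * radius)."""
    name: str
    region: int
    points: np.ndarray            # (n, 3)
    radii: np.ndarray             # (n,)
    ellipticity: float = 1.0
    e_axis: np.ndarray | None = None
    cap: tuple | None = None      # (point, outward_normal) clip plane

    def arclength(self) -> np.ndarray:
        d = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(d)])

    def sdf(self, pts: np.ndarray) -> np.ndarray:
        p = np.asarray(pts, float)
        if self.ellipticity < 1.0 and self.e_axis is not None:
            ax = self.e_axis / np.linalg.norm(self.e_axis)
            comp = p @ ax
            ref = self.points[0] @ ax
            p = p + np.outer(comp - ref, ax) * (1.0 / self.ellipticity - 1.0)
            # centerline assumed to lie in the plane comp == ref
        a = self.points[:-1]
        b = self.points[1:]
        ab = b - a
        ab2 = np.einsum('ij,ij->i', ab, ab)
        # distance to the nearest axis point minus the radius *there*: this
        # realizes the surface of revolution r(s) exactly, whereas a union
        # of capsules would let wide segments swallow steep constrictions
        best = np.full(len(p), np.inf)
        best_r = np.zeros(len(p))
        for i in range(len(a)):
            t = np.clip(((p - a[i]) @ ab[i]) / max(ab2[i], 1e-300), 0, 1)
            close = a[i] + t[:, None] * ab[i]
            r = self.radii[i] + t * (self.radii[i + 1] - self.radii[i])
            d = np.linalg.norm(p - close, axis=1)
            m = d < best
            best[m] = d[m]
            best_r[m] = r[m]
        best = best - best_r
        if self.cap is not None:
            p0, n = self.cap
            best = np.maximum(best, (pts - p0) @ n)
        return best


def _arc_points(z0: float, z1: float, bulge: float, n: int = 33) -> np.ndarray:
    """Circular arc in the (y, z) plane from (0, z0) to (0, z1) with apex at
    y = bulge, sampled with n points (returned as (n, 2) [y, z])."""
    zm, h = (z0 + z1) / 2, (z1 - z0) / 2
    yc = (bulge ** 2 - h ** 2) / (2 * bulge)
    Rarc = bulge - yc
    th0 = np.arctan2(z0 - zm, -yc)
    th1 = np.arctan2(z1 - zm, -yc)
    # sweep from th0 to th1 passing through the apex angle 0
    if th0 < 0 <= th1 or True:
        th0 = np.mod(th0, 2 * np.pi) - 2 * np.pi     # negative side
        th1 = np.mod(th1, 2 * np.pi)                 # positive side
    th = np.linspace(th0, th1, n)
    return np.column_stack([yc + Rarc * np.cos(th), zm + Rarc * np.sin(th)])


def _oft_z(x: np.ndarray) -> np.ndarray:
    x0, x1 = 0.0, _OFT_SPAN[1]
    return _OFT_RISE * np.sin(np.pi * np.clip((x - x0) / (x1 - x0), 0, 1))


def build_branches(spec: ArchPhantomSpec) -> list[Branch]:
    spec.validate()
    branches = []
    # outflow tract (gently curved, optional stenosis)
    xo = np.linspace(*_OFT_SPAN, 49)
    oft_pts = np.column_stack([xo, np.zeros_like(xo), _oft_z(xo)])
    s = (xo - _OFT_SPAN[0]) / (_OFT_SPAN[1] - _OFT_SPAN[0])
    r = np.full_like(xo, spec.oft_radius)
    if spec.oft_stenosis is not None:
        st = spec.oft_stenosis
        r *= 1 - st.severity * _bump(s, st.center_fraction, st.width_fraction)
    branches.append(Branch("OFT", REGION_OFT, oft_pts, r,
                           cap=(np.array([0.0, 0.0, 0.0]),
                                np.array([-1.0, 0.0, 0.0]))))
    # dorsal aorta
    xd = np.linspace(*_DA_SPAN, 45)
    da_pts = np.column_stack([xd, np.zeros_like(xd), np.full_like(xd, _Z_DA)])
    branches.append(Branch("DA", REGION_DA, da_pts,
                           np.full_like(xd, spec.da_radius),
                           cap=(np.array([_X_OUT, 0.0, _Z_DA]),
                                np.array([1.0, 0.0, 0.0]))))
    # arch pairs
    tag = 21
    for k, (arch, xs) in enumerate(zip(spec.arch_pairs, _X_STATIONS)):
        z0 = float(_oft_z(np.array([xs]))[0])
        yz = _arc_points(z0, _Z_DA, arch.bulge)
        sfrac = np.linspace(0, 1, len(yz))
        rr = np.full(len(yz), arch.radius)
        if arch.stenosis is not None:
            st = arch.stenosis
            rr *= 1 - st.severity * _bump(sfrac, st.center_fraction,
                                          st.width_fraction)
        for side, sgn in (("L", +1.0), ("R", -1.0)):
            pts = np.column_stack([np.full(len(yz), xs), sgn * yz[:, 0],
                                   yz[:, 1]])
            branches.append(Branch(f"{arch.label}_{side}", tag, pts, rr,
                                   ellipticity=arch.ellipticity,
                                   e_axis=np.array([1.0, 0.0, 0.0])))
            tag += 1
    # optional cranial outlets from the AA II apices
    if spec.cranial_outlets:
        arch2 = spec.arch_pairs[0]
        z0 = float(_oft_z(np.array([_X_STATIONS[0]]))[0])
        zm = (z0 + _Z_DA) / 2
        for side, sgn in (("L", +1.0), ("R", -1.0)):
            apex = np.array([_X_STATIONS[0], sgn * arch2.bulge, zm])
            end = np.array([_CRANIAL_CLIP - 0.06, sgn * arch2.bulge, zm])
            pts = np.linspace(apex, end, 17)
            branches.append(Branch(
                f"cranial_{side}", tag, pts,
                np.full(17, spec.cranial_radius),
                cap=(np.array([_CRANIAL_CLIP, sgn * arch2.bulge, zm]),
                     np.array([-1.0, 0.0, 0.0]))))
            tag += 1
    if spec.mirror:
        for b in branches:
            b.points = b.points * np.array([1.0, -1.0, 1.0])
            if b.cap is not None:
                p0, n = b.cap
                b.cap = (p0 * np.array([1.0, -1.0, 1.0]),
                         n * np.array([1.0, -1.0, 1.0]))
    return branches


def _union_sdf(branches):
    def sdf(pts):
        pts = np.atleast_2d(np.asarray(pts, float))
        best = np.full(len(pts), np.inf)
        for b in branches:
            best = np.minimum(best, b.sdf(pts))
        return best
    return sdf


def _check_self_intersection(branches):
    """Distinct non-adjacent branches must not overlap away from the shared
    OFT / DA trunks: sample each centerline against the others' tubes."""
    trunk = {"OFT", "DA"}
    for i, bi in enumerate(branches):
        for bj in branches[i + 1:]:
            if bi.name in trunk or bj.name in trunk:
                continue
            if bi.name.rsplit("_", 1)[0] == bj.name.rsplit("_", 1)[0]:
                continue  # the two sides of one pair meet at y = 0 junctions
            names = {bi.name, bj.name}
            for side in ("L", "R"):
                if names == {f"AA_II_{side}", f"cranial_{side}"}:
                    break  # cranial outlets branch off the AA II apices
            else:
                side = None
            if side is not None:
                continue
            interior = bi.points[3:-3]
            if len(interior) and (bj.sdf(interior) < bi.radii.min()).any():
                raise PhantomError(
                    f"branches {bi.name!r} and {bj.name!r} self-intersect; "
                    "reduce radii or bulges")


def make_arch_phantom(spec: ArchPhantomSpec | None = None) -> TaggedSurface:
    """Watertight branched lumen surface with region classifier and SDF.

    Topology: OFT inlet -> 3 bilateral arch pairs -> DA outlet (+2 cranial
    outlets in the case-2 variant).  Returned surface carries ``sdf``,
    ``classify_points`` and ``region_names`` for meshing and analysis;
    ``metadata`` records cap planes and suggested analysis stations.
    """
    from skimage.measure import marching_cubes

    spec = spec or ArchPhantomSpec()
    branches = build_branches(spec)
    _check_self_intersection(branches)
    sdf = _union_sdf(branches)

    pts_all = np.vstack([b.points for b in branches])
    rmax = max(float(b.radii.max()) for b in branches)
    lo = pts_all.min(axis=0) - (rmax + 4 * spec.pitch)
    hi = pts_all.max(axis=0) + (rmax + 4 * spec.pitch)
    axes = [np.arange(lo[d], hi[d] + spec.pitch, spec.pitch)
            for d in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    shape = grid.shape[:3]
    vals = sdf(grid.reshape(-1, 3)).reshape(shape)
    verts, faces, _, _ = marching_cubes(vals, level=0.0, spacing=(spec.pitch,) * 3)
    verts = verts + lo

    # tag cap faces; everything else is wall
    tri = verts[faces]
    cen = tri.mean(axis=1)
    nrm = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    nl = np.linalg.norm(nrm, axis=1)
    nrm = nrm / np.maximum(nl, 1e-300)[:, None]
    tags = np.full(len(faces), WALL)
    tag_names = {WALL: "wall"}
    caps = []
    next_out = FIRST_OUTLET
    for b in branches:
        if b.cap is None:
            continue
        p0, n = b.cap
        if b.name == "OFT":
            t, nm = INLET, "inlet"
        elif b.name == "DA":
            t, nm = next_out, "outlet"
            next_out += 1
        else:
            t, nm = next_out, f"outlet_{b.name}"
            next_out += 1
        onplane = np.abs((cen - p0) @ n) < 0.8 * spec.pitch
        aligned = nrm @ n > 0.5
        near = np.linalg.norm(np.cross(cen - p0, n), axis=1) < 2.5 * rmax
        tags[onplane & aligned & near] = t
        tag_names[t] = nm
        caps.append({"name": nm, "point": p0.tolist(),
                     "normal": n.tolist()})

    region_names = {b.region: b.name for b in branches}
    # merge the pair label for display, keep side-resolved names
    branch_list = branches

    def classify_points(pts):
        pts = np.atleast_2d(np.asarray(pts, float))
        d = np.stack([b.sdf(pts) for b in branch_list])
        return np.array([branch_list[i].region for i in d.argmin(axis=0)])

    mirror_y = -1.0 if spec.mirror else 1.0
    surface = TaggedSurface(
        vertices=verts, faces=faces, face_tags=tags, tag_names=tag_names,
        sdf=sdf, classify_points=classify_points, region_names=region_names,
        metadata={
            "caps": caps,
            "seed_plane": {"point": [0.06, 0.0, float(_oft_z(np.array([0.06]))[0])],
                           "normal": [1.0, 0.0, 0.0]},
            "upstream_plane": {"point": [0.10, 0.0, float(_oft_z(np.array([0.10]))[0])],
                               "normal": [1.0, 0.0, 0.0]},
            "downstream_plane": {"point": [0.90, 0.0, _Z_DA],
                                 "normal": [1.0, 0.0, 0.0]},
            "arch_labels": [a.label for a in spec.arch_pairs],
            "mirror_y": mirror_y,
            "spec": spec,
        })
    surface.branches = branch_list
    return surface


# ---------------------------------------------------------------------------
# landmark cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LandmarkPopulationSpec:
    """Synthetic cohort: template + sum_k s_k mode_k + isotropic noise,
    s_k ~ N(0, mode_sds[k]^2); ``n_outliers`` specimens additionally have
    one arch's landmarks collapsed onto the adjacent arch path ("missing
    arch" analogue -- landmark count is preserved, as required for GPA)."""
    template: np.ndarray | None = None   # (n_lm, 3); default phantom set
    n_specimens: int = 8
    mode_vectors: tuple = ()             # each (n_lm, 3)
    mode_sds: tuple = ()
    isotropic_noise_sd: float = 0.002    # mm
    n_outliers: int = 0
    seed: int = 0

    def validate(self):
        if self.n_specimens < 2:
            raise PhantomError("need at least 2 specimens")
        if len(self.mode_vectors) != len(self.mode_sds):
            raise PhantomError("mode_vectors and mode_sds length mismatch")
        if self.isotropic_noise_sd < 0:
            raise PhantomError("noise sd must be >= 0")
        if not (0 <= self.n_outliers <= self.n_specimens):
            raise PhantomError("n_outliers out of range")


def default_landmark_template(n_lm: int = 275,
                              spec: ArchPhantomSpec | None = None):
    """Pseudolandmarks along the phantom's branch centerlines (OFT, six
    arches, DA).  Returns (template (n_lm, 3), labels (n_lm,) of branch
    names) in a deterministic order."""
    branches = build_branches(spec or ArchPhantomSpec())
    weights = np.array([b.arclength()[-1] for b in branches])
    counts = np.maximum(4, np.round(n_lm * weights / weights.sum()).astype(int))
    while counts.sum() > n_lm:
        counts[np.argmax(counts)] -= 1
    while counts.sum() < n_lm:
        counts[np.argmin(counts)] += 1
    pts, labels = [], []
    for b, c in zip(branches, counts):
        s = b.arclength()
        si = np.linspace(0, s[-1], c)
        for d in range(3):
            pts.append(np.interp(si, s, b.points[:, d]))
        labels += [b.name] * c
    arr = np.column_stack([np.concatenate(pts[d::3]) for d in range(3)])
    return arr, np.array(labels)


def default_mode_vectors(template: np.ndarray, labels: np.ndarray):
    """Two smooth, interpretable variation modes: a lateral (y) shift of the
    OFT landmarks and a cranio-caudal (x) stretch of the DA landmarks."""
    m1 = np.zeros_like(template)
    m1[labels == "OFT", 1] = 1.0
    m2 = np.zeros_like(template)
    sel = labels == "DA"
    x = template[sel, 0]
    m2[sel, 0] = (x - x.mean()) / max(np.ptp(x), 1e-9)
    return (m1, m2)


def _orthonormalize(modes, n_lm):
    flat = [np.asarray(m, float).reshape(-1) for m in modes]
    out = []
    for v in flat:
        if len(v) != 3 * n_lm:
            raise PhantomError("mode vector landmark count mismatch")
        w = v - np.mean(v.reshape(-1, 3), axis=0)[None, :].repeat(n_lm, 0).reshape(-1)
        for u in out:
            w = w - (w @ u) * u
        n = np.linalg.norm(w)
        if n < 1e-12:
            raise PhantomError("mode vectors are linearly dependent")
        out.append(w / n)
    return [v.reshape(n_lm, 3) for v in out]


def make_landmark_population(spec: LandmarkPopulationSpec):
    """Generate a :class:`~archflow.morphometrics.LandmarkCohort`."""
    from .morphometrics import LandmarkCohort

    spec.validate()
    if spec.template is None:
        template, labels = default_landmark_template()
    else:
        template = np.asarray(spec.template, float)
        labels = np.array([""] * len(template))
    n_lm = len(template)
    modes = _orthonormalize(spec.mode_vectors, n_lm) if spec.mode_vectors else []
    rng = np.random.default_rng(spec.seed)
    specimens = []
    for i in range(spec.n_specimens):
        x = template.copy()
        for m, sd in zip(modes, spec.mode_sds):
            x += rng.normal(0.0, sd) * m
        if spec.isotropic_noise_sd > 0:
            x += rng.normal(0.0, spec.isotropic_noise_sd, x.shape)
        specimens.append(x)
    outlier = np.zeros(spec.n_specimens, dtype=bool)
    if spec.n_outliers:
        if spec.template is not None:
            raise PhantomError("missing-arch outliers require the default "
                               "phantom-derived template (labeled branches)")
        sel = labels == "AA_II_L"
        target = labels == "AA_III_L"
        for i in range(spec.n_specimens - spec.n_outliers, spec.n_specimens):
            x = specimens[i]
            # collapse the left AA II landmarks onto the adjacent (AA III)
            # arch path: nearest-point projection, count preserved
            path = x[target]
            d = np.linalg.norm(x[sel][:, None, :] - path[None, :, :], axis=2)
            specimens[i] = x.copy()
            specimens[i][sel] = path[d.argmin(axis=1)]
            outlier[i] = True
    ids = [f"specimen_{i:03d}" for i in range(spec.n_specimens)]
    return LandmarkCohort(specimens=np.array(specimens), ids=ids,
                          outlier=outlier, labels=labels)
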