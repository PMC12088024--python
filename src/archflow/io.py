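"""Mesh, surface, field and landmark I/O in standard interchange formats.

Volume meshes: VTU (ASCII XML, VTK quadratic tetra), Gmsh MSH 4.1, and
XDMF (XML + HDF5 heavy data).  Boundary-facet tags ride in a JSON sidecar
(``<stem>.tags.json``) for VTU/XDMF -- both formats carry only volume
cells -- while MSH stores them natively as physical surface groups.
Surfaces: STL (binary, via trimesh) and VTP PolyData with per-face tag
arrays.  Landmarks: 3D Slicer FCSV (one file per specimen) and a combined
long-format CSV.  Write -> read round-trips are bit-exact for the XML/HDF5
formats (floats serialized at full precision).
"""

from __future__ import annotations

import json
import warnings
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .mesh import VolumeMesh, from_p1
from .morphometrics import LandmarkCohort

# node-order permutations from the internal edge order
# internal edges: (0,1),(0,2),(0,3),(1,2),(1,3),(2,3) at slots 4..9
_VTK_PERM = np.array([0, 1, 2, 3, 4, 7, 5, 6, 8, 9])   # VTK quadraticTetra
_GMSH_PERM = np.array([0, 1, 2, 3, 4, 7, 5, 6, 9, 8])  # Gmsh tetra10
VTK_QUAD_TETRA = 24
VTK_TETRA = 10


class IOError_(ValueError):
    pass


def _fmt_floats(a: np.ndarray) -> str:
    return "\n".join(" ".join(repr(float(x)) for x in row)
                     for row in np.atleast_2d(a))


def _fmt_ints(a: np.ndarray) -> str:
    return "\n".join(" ".join(str(int(x)) for x in np.atleast_1d(row))
                     for row in np.atleast_2d(a))


# ---------------------------------------------------------------------------
# facet-tag sidecar (VTU / XDMF)
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".tags.json")


def _write_sidecar(mesh: VolumeMesh, path: Path):
    data = {
        "n_p1": int(mesh.n_p1),
        "element_size": float(mesh.element_size),
        "units": mesh.units,
        "facet_vertices": mesh.facets[:, :3].tolist(),
        "facet_tags": mesh.facet_tags.tolist(),
        "facet_names": {str(k): v for k, v in mesh.facet_names.items()},
        "region_names": {str(k): v for k, v in mesh.region_names.items()},
    }
    _sidecar_path(path).write_text(json.dumps(data))


def _apply_sidecar(mesh: VolumeMesh, path: Path):
    sc = _sidecar_path(path)
    if not sc.exists():
        return mesh
    data = json.loads(sc.read_text())
    mesh.element_size = data.get("element_size", 0.0)
    mesh.units = data.get("units", "mm")
    mesh.facet_names = {int(k): v for k, v in data["facet_names"].items()}
    mesh.region_names = {int(k): v for k, v in data["region_names"].items()}
    lut = {tuple(sorted(f)): t for f, t in zip(data["facet_vertices"],
                                               data["facet_tags"])}
    tags = np.zeros(len(mesh.facets), dtype=np.int64)
    for i, f in enumerate(mesh.facets[:, :3]):
        tags[i] = lut.get(tuple(sorted(int(v) for v in f)), 0)
    mesh.facet_tags = tags
    return mesh


# ---------------------------------------------------------------------------
# VTU
# ---------------------------------------------------------------------------

def write_vtu(mesh: VolumeMesh, path):
    path = Path(path)
    nc = len(mesh.cells)
    cells_vtk = mesh.cells[:, _VTK_PERM]
    parts = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        '<UnstructuredGrid>',
        f'<Piece NumberOfPoints="{len(mesh.vertices)}" NumberOfCells="{nc}">',
        '<Points><DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        _fmt_floats(mesh.vertices),
        '</DataArray></Points>',
        '<Cells>',
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        _fmt_ints(cells_vtk),
        '</DataArray>',
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        _fmt_ints(10 * np.arange(1, nc + 1)),
        '</DataArray>',
        '<DataArray type="UInt8" Name="types" format="ascii">',
        _fmt_ints(np.full(nc, VTK_QUAD_TETRA)),
        '</DataArray>',
        '</Cells>',
    ]
    if mesh.region_tags is not None:
        parts += ['<CellData Scalars="region">',
                  '<DataArray type="Int64" Name="region" format="ascii">',
                  _fmt_ints(mesh.region_tags),
                  '</DataArray></CellData>']
    parts += ['</Piece></UnstructuredGrid></VTKFile>']
    path.write_text("\n".join(parts))
    _write_sidecar(mesh, path)


def read_vtu(path) -> VolumeMesh:
    path = Path(path)
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as e:
        raise IOError_(f"malformed VTU {path}: {e}") from None
    piece = root.find(".//Piece")
    arrays = {}
    for da in piece.iter("DataArray"):
        name = da.get("Name") or "points"
        arrays[name] = np.fromstring(da.text.replace("\n", " "), sep=" ")
    verts = arrays["points"].reshape(-1, 3)
    types = arrays["types"].astype(int)
    conn = arrays["connectivity"].astype(np.int64)
    region = arrays.get("region")
    if np.all(types == VTK_QUAD_TETRA):
        cells_vtk = conn.reshape(-1, 10)
        inv = np.argsort(_VTK_PERM)
        cells = cells_vtk[:, inv]
        n_p1 = int(cells[:, :4].max()) + 1
        mesh = VolumeMesh.__new__(VolumeMesh)
        rebuilt = _rebuild_from_cells(verts, cells, n_p1)
    elif np.all(types == VTK_TETRA):
        warnings.warn(f"{path.name}: first-order tetrahedra promoted to P2 "
                      "by mid-edge insertion")
        rebuilt = from_p1(verts, conn.reshape(-1, 4))
    else:
        raise IOError_(f"{path}: unsupported VTK cell types "
                       f"{sorted(set(types.tolist()))}")
    if region is not None:
        rebuilt.region_tags = region.astype(np.int64)
    return _apply_sidecar(rebuilt, path)


def _rebuild_from_cells(verts, cells, n_p1) -> VolumeMesh:
    """Reconstruct facet structure from P2 cells (deterministic)."""
    from .mesh import boundary_faces, _facets_p2, _unique_edges
    tets = cells[:, :4]
    faces, parents = boundary_faces(tets)
    # recover the edge array implied by the stored midpoint ids
    edge_lut = {}
    from .fem import TET_EDGES
    for c in cells:
        for e, (a, b) in enumerate(TET_EDGES):
            key = (min(c[a], c[b]), max(c[a], c[b]))
            edge_lut[key] = c[4 + e]
    facets = np.empty((len(faces), 6), dtype=np.int64)
    facets[:, :3] = faces
    for i, (a, b, c_) in enumerate(faces):
        facets[i, 3] = edge_lut[(min(a, b), max(a, b))]
        facets[i, 4] = edge_lut[(min(b, c_), max(b, c_))]
        facets[i, 5] = edge_lut[(min(a, c_), max(a, c_))]
    return VolumeMesh(vertices=verts, cells=cells, n_p1=n_p1,
                      facets=facets, facet_parent=parents,
                      facet_tags=np.zeros(len(facets), dtype=np.int64))


# ---------------------------------------------------------------------------
# Gmsh MSH 4.1 (ASCII)
# ---------------------------------------------------------------------------

def write_msh(mesh: VolumeMesh, path):
    path = Path(path)
    out = ["$MeshFormat", "4.1 0 8", "$EndMeshFormat"]
    # physical names: surfaces (dim 2) for facet tags, volumes (dim 3) for regions
    regions = (sorted(set(mesh.region_tags.tolist()))
               if mesh.region_tags is not None else [1])
    phys = []
    for t, n in sorted(mesh.facet_names.items()):
        phys.append((2, t, n))
    for r in regions:
        phys.append((3, 1000 + r, mesh.region_names.get(r, f"region_{r}")))
    out += ["$PhysicalNames", str(len(phys))]
    out += [f'{d} {t} "{n}"' for d, t, n in phys]
    out += ["$EndPhysicalNames"]
    # entities: one surface per facet tag, one volume per region
    stags = sorted(set(mesh.facet_tags.tolist()))
    out += ["$Entities", f"0 0 {len(stags)} {len(regions)}"]
    for t in stags:
        out.append(f"{t} 0 0 0 0 0 0 1 {t} 0")
    for r in regions:
        out.append(f"{r} 0 0 0 0 0 0 1 {1000 + r} 0")
    out += ["$EndEntities"]
    nv = len(mesh.vertices)
    out += ["$Nodes", f"1 {nv} 1 {nv}", f"3 1 0 {nv}"]
    out += [str(i + 1) for i in range(nv)]
    out += [" ".join(repr(float(x)) for x in v)
            for v in mesh.vertices]
    out += ["$EndNodes"]
    # elements: boundary triangles (type 9) per surface entity,
    # volume tet10 (type 11) per region entity
    # element ids encode the original facet/cell indices so that reading
    # restores the exact ordering (round-trip identity)
    blocks = []
    nf = len(mesh.facets)
    for t in stags:
        sel = np.nonzero(mesh.facet_tags == t)[0]
        lines = [f"{i + 1} " + " ".join(map(str, mesh.facets[i] + 1))
                 for i in sel]
        blocks.append((2, t, 9, lines))
    rt = (mesh.region_tags if mesh.region_tags is not None
          else np.ones(len(mesh.cells), dtype=int))
    for r in regions:
        sel = np.nonzero(rt == r)[0]
        lines = [f"{nf + i + 1} "
                 + " ".join(map(str, mesh.cells[i][_GMSH_PERM] + 1))
                 for i in sel]
        blocks.append((3, r, 11, lines))
    ne = sum(len(b[3]) for b in blocks)
    out += ["$Elements", f"{len(blocks)} {ne} 1 {ne}"]
    for dim, ent, etype, lines in blocks:
        out.append(f"{dim} {ent} {etype} {len(lines)}")
        out += lines
    out += ["$EndElements"]
    path.write_text("\n".join(out) + "\n")


def read_msh(path) -> VolumeMesh:
    path = Path(path)
    lines = path.read_text().splitlines()
    sec = {}
    i = 0
    while i < len(lines):
        if lines[i].startswith("$") and not lines[i].startswith("$End"):
            name = lines[i][1:]
            j = i + 1
            while j < len(lines) and not lines[j].startswith("$End"):
                j += 1
            sec[name] = lines[i + 1:j]
            i = j + 1
        else:
            i += 1
    if "MeshFormat" not in sec or not sec["MeshFormat"][0].startswith("4.1"):
        raise IOError_(f"{path}: not a Gmsh 4.1 ASCII file")
    if "PhysicalNames" not in sec:
        raise IOError_(f"{path}: missing $PhysicalNames (boundary and "
                       "region groups are required)")
    phys = {}
    for ln in sec["PhysicalNames"][1:]:
        d, t, n = ln.split(maxsplit=2)
        phys[(int(d), int(t))] = n.strip('"')
    # entity -> physical tag
    ent_phys = {}
    hdr = sec["Entities"][0].split()
    np_, nc_, ns_, nv_ = map(int, hdr)
    idx = 1 + np_ + nc_
    for ln in sec["Entities"][idx:idx + ns_]:
        f = ln.split()
        ent_phys[(2, int(f[0]))] = int(f[8]) if int(f[7]) else 0
    for ln in sec["Entities"][idx + ns_: idx + ns_ + nv_]:
        f = ln.split()
        ent_phys[(3, int(f[0]))] = int(f[8]) if int(f[7]) else 0
    # nodes
    hdr = sec["Nodes"][0].split()
    nblocks = int(hdr[0])
    total = int(hdr[1])
    pos = 1
    coords = np.empty((total + 1, 3))       # 1-based gmsh ids
    for _ in range(nblocks):
        bh = sec["Nodes"][pos].split()
        n = int(bh[3])
        ids = [int(x) for x in sec["Nodes"][pos + 1: pos + 1 + n]]
        for k, ln in enumerate(sec["Nodes"][pos + 1 + n: pos + 1 + 2 * n]):
            coords[ids[k]] = [float(x) for x in ln.split()[:3]]
        pos += 1 + 2 * n
    # elements
    hdr = sec["Elements"][0].split()
    nblocks = int(hdr[0])
    pos = 1
    tris, tri_tags, tets10, tets4, cell_regions, eids = [], [], [], [], [], []
    for _ in range(nblocks):
        dim, ent, etype, n = map(int, sec["Elements"][pos].split())
        ptag = ent_phys.get((dim, ent), 0)
        for ln in sec["Elements"][pos + 1: pos + 1 + n]:
            parts = ln.split()
            ids = [int(x) for x in parts[1:]]
            if etype == 9:
                tris.append(ids)
                tri_tags.append(ptag)
            elif etype == 11:
                tets10.append(ids)
                cell_regions.append(ptag - 1000)
                eids.append(int(parts[0]))
            elif etype == 4:
                tets4.append(ids)
                cell_regions.append(ptag - 1000)
                eids.append(int(parts[0]))
        pos += 1 + n
    if eids:   # restore the writer's cell ordering via element ids
        order = np.argsort(eids)
        cell_regions = [cell_regions[i] for i in order]
        if tets10:
            tets10 = [tets10[i] for i in order]
        if tets4:
            tets4 = [tets4[i] for i in order]
    if not tets10 and not tets4:
        raise IOError_(f"{path}: no tetrahedral elements")
    if tets4:
        warnings.warn(f"{path.name}: first-order tetrahedra promoted to P2")
        verts = coords[1:]
        mesh = from_p1(verts, np.array(tets4) - 1)
        mesh.region_tags = np.array(cell_regions, dtype=np.int64)
        return mesh
    cells_gmsh = np.array(tets10) - 1
    inv = np.argsort(_GMSH_PERM)
    cells = cells_gmsh[:, inv]
    verts = coords[1:]
    n_p1 = int(cells[:, :4].max()) + 1
    mesh = _rebuild_from_cells(verts, cells, n_p1)
    mesh.region_tags = np.array(cell_regions, dtype=np.int64)
    mesh.region_names = {t - 1000: n for (d, t), n in phys.items() if d == 3}
    # facet tags from the stored surface elements
    lut = {}
    for f, t in zip(tris, tri_tags):
        lut[tuple(sorted(f[:3]))] = t
    tags = np.zeros(len(mesh.facets), dtype=np.int64)
    for i, f in enumerate(mesh.facets[:, :3] + 1):
        tags[i] = lut.get(tuple(sorted(int(v) for v in f)), 0)
    mesh.facet_tags = tags
    mesh.facet_names = {t: n for (d, t), n in phys.items() if d == 2}
    return mesh


# ---------------------------------------------------------------------------
# XDMF (XML + HDF5)
# ---------------------------------------------------------------------------

def write_xdmf(mesh: VolumeMesh, path):
    import h5py
    path = Path(path)
    h5path = path.with_suffix(".h5")
    with h5py.File(h5path, "w") as h5:
        h5["geometry"] = mesh.vertices
        h5["topology"] = mesh.cells[:, _VTK_PERM]
        if mesh.region_tags is not None:
            h5["region"] = mesh.region_tags
    nc = len(mesh.cells)
    attr = ""
    if mesh.region_tags is not None:
        attr = (f'<Attribute Name="region" Center="Cell">'
                f'<DataItem Dimensions="{nc}" Format="HDF">'
                f'{h5path.name}:/region</DataItem></Attribute>')
    path.write_text(f"""<?xml version="1.0"?>
<Xdmf Version="3.0"><Domain><Grid Name="mesh">
<Topology TopologyType="Tetrahedron_10" NumberOfElements="{nc}">
<DataItem Dimensions="{nc} 10" Format="HDF">{h5path.name}:/topology</DataItem>
</Topology>
<Geometry GeometryType="XYZ">
<DataItem Dimensions="{len(mesh.vertices)} 3" Format="HDF">{h5path.name}:/geometry</DataItem>
</Geometry>
{attr}
</Grid></Domain></Xdmf>
""")
    _write_sidecar(mesh, path)


def read_xdmf(path) -> VolumeMesh:
    import h5py
    path = Path(path)
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as e:
        raise IOError_(f"malformed XDMF {path}: {e}") from None
    with h5py.File(path.with_suffix(".h5"), "r") as h5:
        verts = h5["geometry"][...]
        cells_vtk = h5["topology"][...]
        region = h5["region"][...] if "region" in h5 else None
    cells = cells_vtk[:, np.argsort(_VTK_PERM)]
    mesh = _rebuild_from_cells(verts, cells, int(cells[:, :4].max()) + 1)
    if region is not None:
        mesh.region_tags = region.astype(np.int64)
    return _apply_sidecar(mesh, path)


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

_WRITERS = {"vtu": write_vtu, "msh": write_msh, "xdmf": write_xdmf}
_READERS = {"vtu": read_vtu, "msh": read_msh, "xdmf": read_xdmf}


def write_mesh(mesh: VolumeMesh, path, fmt: str | None = None):
    fmt = (fmt or Path(path).suffix.lstrip(".")).lower()
    if fmt not in _WRITERS:
        raise IOError_(f"unknown mesh format {fmt!r} "
                       f"(supported: {sorted(_WRITERS)})")
    _WRITERS[fmt](mesh, path)


def read_mesh(path, fmt: str | None = None) -> VolumeMesh:
    fmt = (fmt or Path(path).suffix.lstrip(".")).lower()
    if fmt == "stl":
        raise IOError_("STL holds surfaces, not volume meshes; "
                       "tetrahedralize it first")
    if fmt not in _READERS:
        raise IOError_(f"unknown mesh format {fmt!r} "
                       f"(supported: {sorted(_READERS)})")
    return _READERS[fmt](path)


# ---------------------------------------------------------------------------
# surfaces
# ---------------------------------------------------------------------------

def write_stl(surface, path):
    surface.as_trimesh().export(Path(path), file_type="stl")


def write_vtp(surface_or_polylines, path, point_data=None, cell_data=None):
    """VTP PolyData: a TaggedSurface (polys + face tags) or a list of
    polylines (lines), with optional named data arrays."""
    path = Path(path)
    if hasattr(surface_or_polylines, "faces"):
        s = surface_or_polylines
        pts, polys = s.vertices, s.faces
        lines = None
        cell_data = dict(cell_data or {}, tag=s.face_tags)
    else:
        pls = [np.asarray(p, float) for p in surface_or_polylines]
        pts = np.vstack(pls) if pls else np.zeros((0, 3))
        offs, conn, start = [], [], 0
        for p in pls:
            conn.extend(range(start, start + len(p)))
            start += len(p)
            offs.append(start)
        lines = (np.array(conn), np.array(offs))
        polys = None
    n_cells = len(polys) if polys is not None else (len(lines[1]) if lines else 0)
    parts = ['<?xml version="1.0"?>',
             '<VTKFile type="PolyData" version="0.1" byte_order="LittleEndian">',
             '<PolyData>',
             f'<Piece NumberOfPoints="{len(pts)}" '
             f'NumberOfVerts="0" NumberOfLines="{len(lines[1]) if lines else 0}" '
             f'NumberOfStrips="0" NumberOfPolys="{len(polys) if polys is not None else 0}">',
             '<Points><DataArray type="Float64" NumberOfComponents="3" format="ascii">',
             _fmt_floats(pts), '</DataArray></Points>']
    if point_data:
        parts.append('<PointData>')
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            ncomp = 1 if arr.ndim == 1 else arr.shape[1]
            parts += [f'<DataArray type="Float64" Name="{name}" '
                      f'NumberOfComponents="{ncomp}" format="ascii">',
                      _fmt_floats(arr.reshape(len(arr), -1)), '</DataArray>']
        parts.append('</PointData>')
    if cell_data:
        parts.append('<CellData>')
        for name, arr in cell_data.items():
            parts += [f'<DataArray type="Int64" Name="{name}" format="ascii">',
                      _fmt_ints(np.asarray(arr)), '</DataArray>']
        parts.append('</CellData>')
    if polys is not None:
        parts += ['<Polys>',
                  '<DataArray type="Int64" Name="connectivity" format="ascii">',
                  _fmt_ints(polys),
                  '</DataArray>',
                  '<DataArray type="Int64" Name="offsets" format="ascii">',
                  _fmt_ints(3 * np.arange(1, len(polys) + 1)),
                  '</DataArray>', '</Polys>']
    if lines is not None and len(lines[1]):
        parts += ['<Lines>',
                  '<DataArray type="Int64" Name="connectivity" format="ascii">',
                  _fmt_ints(lines[0]),
                  '</DataArray>',
                  '<DataArray type="Int64" Name="offsets" format="ascii">',
                  _fmt_ints(lines[1]),
                  '</DataArray>', '</Lines>']
    parts += ['</Piece></PolyData></VTKFile>']
    path.write_text("\n".join(parts))


# ---------------------------------------------------------------------------
# landmarks (3D Slicer FCSV + combined CSV)
# ---------------------------------------------------------------------------

def write_fcsv(landmarks: np.ndarray, path, ids=None):
    path = Path(path)
    lines = ["# Markups fiducial file version = 4.11",
             "# CoordinateSystem = LPS",
             "# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID"]
    for i, (x, y, z) in enumerate(np.asarray(landmarks, float)):
        label = ids[i] if ids is not None else f"LM_{i + 1}"
        lines.append(f"{i + 1},{repr(float(x))},"
                     f"{repr(float(y))},{repr(float(z))},"
                     f"0,0,0,1,1,1,0,{label},,")
    path.write_text("\n".join(lines) + "\n")


def read_fcsv(path) -> np.ndarray:
    pts = []
    for ln in Path(path).read_text().splitlines():
        if ln.startswith("#") or not ln.strip():
            continue
        f = ln.split(",")
        pts.append([float(f[1]), float(f[2]), float(f[3])])
    if not pts:
        raise IOError_(f"{path}: no fiducial rows")
    return np.array(pts)


def write_cohort(cohort: LandmarkCohort, directory, combined_csv=True):
    """One FCSV per specimen plus a combined long-format CSV."""
    import pandas as pd
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for sid, lm in zip(cohort.ids, cohort.specimens):
        write_fcsv(lm, directory / f"{sid}.fcsv")
    if combined_csv:
        rows = []
        for sid, lm in zip(cohort.ids, cohort.specimens):
            for j, (x, y, z) in enumerate(lm):
                rows.append((sid, j, x, y, z))
        pd.DataFrame(rows, columns=["specimen", "landmark_id", "x", "y", "z"]
                     ).to_csv(directory / "cohort.csv", index=False)


def read_cohort(source) -> LandmarkCohort:
    """Load a cohort from a directory of FCSV files or a combined CSV."""
    import pandas as pd
    source = Path(source)
    if source.is_dir():
        files = sorted(source.glob("*.fcsv"))
        if not files:
            csv = source / "cohort.csv"
            if csv.exists():
                return read_cohort(csv)
            raise IOError_(f"{source}: no .fcsv files")
        specs = [read_fcsv(f) for f in files]
        counts = {len(s) for s in specs}
        if len(counts) != 1:
            raise IOError_(f"landmark count mismatch across specimens: "
                           f"{sorted(counts)}")
        return LandmarkCohort(specimens=np.array(specs),
                              ids=[f.stem for f in files])
    df = pd.read_csv(source)
    ids = sorted(df["specimen"].unique().tolist())
    specs = [df[df.specimen == s].sort_values("landmark_id")[
        ["x", "y", "z"]].to_numpy(dtype=float) for s in ids]
    counts = {len(s) for s in specs}
    if len(counts) != 1:
        raise IOError_("landmark count mismatch across specimens")
    return LandmarkCohort(specimens=np.array(specs), ids=ids)
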