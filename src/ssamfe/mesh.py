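"""Tetrahedral mesh container, geometry predicates, quality metrics and file I/O.

Coordinate convention used throughout the package: right-handed frame in mm,
x = medio-lateral, y = antero-posterior (the projection axis of the coronal
plane), z = proximo-distal with the femoral head towards +z.
"""

from __future__ import annotations

import logging
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "TetMesh",
    "DensityField",
    "Sphere",
    "element_volumes",
    "element_centroids",
    "surface_facets",
    "face_adjacency",
    "mean_ratio_quality",
    "circumscribing_sphere",
    "read_mesh",
    "write_mesh",
]


@dataclass
class TetMesh:
    """Linear tetrahedral mesh.

    Parameters
    ----------
    nodes : (N, 3) float array
        Node coordinates in mm.
    elements : (M, 4) int array
        Node indices of each tetrahedron.
    node_sets, element_sets : dict[str, ndarray]
        Optional region tags, e.g. ``"distal_cut"`` or ``"neck"``.

    Elements with negative signed volume are re-oriented on construction
    (last two nodes swapped); the count is logged.
    """

    nodes: np.ndarray
    elements: np.ndarray
    node_sets: dict = field(default_factory=dict)
    element_sets: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=float)
        self.elements = np.ascontiguousarray(self.elements, dtype=np.int64)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise ValueError("nodes must be (N, 3)")
        if self.elements.ndim != 2 or self.elements.shape[1] != 4:
            raise ValueError("elements must be (M, 4)")
        if self.elements.size:
            if self.elements.min() < 0 or self.elements.max() >= len(self.nodes):
                raise ValueError("element node index out of range")
            distinct = np.array(
                [len(set(e)) == 4 for e in self.elements], dtype=bool
            )
            if not distinct.all():
                bad = int(np.flatnonzero(~distinct)[0])
                raise ValueError(f"element {bad} repeats a node index")
            vols = _signed_volumes(self.nodes, self.elements)
            neg = vols < 0
            if neg.any():
                logger.info("re-orienting %d negative-volume elements", neg.sum())
                self.elements[neg] = self.elements[neg][:, [0, 1, 3, 2]]
            used = np.zeros(len(self.nodes), dtype=bool)
            used[self.elements.ravel()] = True
            n_unused = int((~used).sum())
            if n_unused:
                logger.warning("%d unreferenced nodes in mesh", n_unused)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def copy(self) -> "TetMesh":
        return TetMesh(
            self.nodes.copy(),
            self.elements.copy(),
            {k: np.asarray(v).copy() for k, v in self.node_sets.items()},
            {k: np.asarray(v).copy() for k, v in self.element_sets.items()},
        )


@dataclass
class DensityField:
    """Per-element density in g/cm^3 riding on a :class:`TetMesh`.

    ``kind`` tags the calibration the values live in: ``"rho_qct"``
    (dipotassium-phosphate equivalent radiological density), ``"rho_ash"``
    or ``"rho_app"`` (wet apparent).
    """

    values: np.ndarray
    kind: str = "rho_app"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if (self.values < 0).any():
            raise ValueError("densities must be non-negative")
        if self.kind not in ("rho_qct", "rho_ash", "rho_app"):
            raise ValueError(f"unknown density kind {self.kind!r}")


@dataclass
class Sphere:
    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.radius < 0:
            raise ValueError("radius must be >= 0")

    def contains(self, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        """Closed-ball membership (boundary points count)."""
        d = np.linalg.norm(np.atleast_2d(points) - self.center, axis=1)
        return d <= self.radius + tol


def _signed_volumes(nodes: np.ndarray, elements: np.ndarray) -> np.ndarray:
    p = nodes[elements]
    return np.linalg.det(p[:, 1:] - p[:, :1]) / 6.0


def element_volumes(mesh: TetMesh) -> np.ndarray:
    """Per-element volume in mm^3 (|det|/6). Degenerate elements report 0."""
    v = np.abs(_signed_volumes(mesh.nodes, mesh.elements))
    degenerate = v < 1e-14
    if degenerate.any():
        logger.warning("%d degenerate (zero-volume) elements", degenerate.sum())
        v = np.where(degenerate, 0.0, v)
    return v


def element_centroids(mesh: TetMesh) -> np.ndarray:
    return mesh.nodes[mesh.elements].mean(axis=1)


_FACE_LOCAL = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])


def _all_facets(elements: np.ndarray) -> np.ndarray:
    """(4M, 3) facet array; row 4*e+f is local face f of element e,
    wound outward for a positively oriented element."""
    return elements[:, _FACE_LOCAL].reshape(-1, 3)


def surface_facets(mesh: TetMesh):
    """Boundary triangles of a tet mesh.

    Returns
    -------
    facets : (F, 3) int array
        Boundary triangles, wound with outward normals.
    surface_elements : (K,) int array
        Elements owning at least one boundary facet.
    surface_nodes : (L,) int array
        Nodes on any boundary facet.

    Raises
    ------
    ValueError
        If a facet is shared by more than two elements (non-manifold).
    """
    facets = _all_facets(mesh.elements)
    keys = np.sort(facets, axis=1)
    _, inv, counts = np.unique(
        keys, axis=0, return_inverse=True, return_counts=True
    )
    if (counts > 2).any():
        bad = np.flatnonzero(counts[inv] > 2)[0]
        raise ValueError(
            f"non-manifold facet {tuple(keys[bad])} shared by >2 elements"
        )
    boundary = counts[inv] == 1
    bfacets = facets[boundary]
    owner = np.flatnonzero(boundary) // 4
    surface_elements = np.unique(owner)
    surface_nodes = np.unique(bfacets)
    return bfacets, surface_elements, surface_nodes


def face_adjacency(mesh: TetMesh) -> list[np.ndarray]:
    """Face-adjacent neighbours of every element (elements sharing a triangle)."""
    facets = np.sort(_all_facets(mesh.elements), axis=1)
    order = np.lexsort(facets.T[::-1])
    owner = order // 4
    sf = facets[order]
    same = (sf[1:] == sf[:-1]).all(axis=1)
    nbrs: list[list[int]] = [[] for _ in range(mesh.n_elements)]
    for i in np.flatnonzero(same):
        a, b = int(owner[i]), int(owner[i + 1])
        nbrs[a].append(b)
        nbrs[b].append(a)
    return [np.asarray(n, dtype=np.int64) for n in nbrs]


def mean_ratio_quality(mesh: TetMesh) -> np.ndarray:
    """Mean-ratio tetrahedron shape quality in [0, 1].

    eta = 12 (3V)^(2/3) / sum(edge length^2); 1 for the regular tetrahedron,
    0 for degenerate. Invariant under rigid motion and uniform scaling.
    Elements with non-positive volume score 0.
    """
    p = mesh.nodes[mesh.elements]
    v = np.linalg.det(p[:, 1:] - p[:, :1]) / 6.0
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    l2 = sum(((p[:, a] - p[:, b]) ** 2).sum(axis=1) for a, b in pairs)
    with np.errstate(divide="ignore", invalid="ignore"):
        eta = 12.0 * np.cbrt(3.0 * np.maximum(v, 0.0)) ** 2 / l2
    return np.where((v > 0) & (l2 > 0), np.minimum(eta, 1.0), 0.0)


# ---------------------------------------------------------------- miniball ---


def _sphere_from(points: np.ndarray) -> Sphere | None:
    """Exact sphere through 0..4 points (circumsphere of the affine hull)."""
    pts = np.atleast_2d(points)
    k = len(pts)
    if k == 0:
        return Sphere(np.zeros(3), 0.0)
    if k == 1:
        return Sphere(pts[0], 0.0)
    a = pts[1:] - pts[0]
    # center = pts[0] + a^T x with a a x = |a|^2 / 2 (least-norm solution
    # keeps the center in the affine hull => smallest such sphere)
    g = a @ a.T
    b = 0.5 * (a * a).sum(axis=1)
    try:
        sol = np.linalg.lstsq(g, b, rcond=None)[0]
    except np.linalg.LinAlgError:  # pragma: no cover
        return None
    if np.linalg.matrix_rank(g, tol=1e-9 * max(1.0, g.max())) < k - 1:
        return None
    c = pts[0] + sol @ a
    r = float(np.linalg.norm(pts - c, axis=1).max())
    return Sphere(c, r)


def _welzl(points: list, boundary: list) -> Sphere:
    if not points or len(boundary) == 4:
        s = _sphere_from(np.array(boundary)) if boundary else Sphere(np.zeros(3), 0.0)
        if s is None:
            s = _sphere_from(np.array(boundary[:-1]))
        return s
    p = points[0]
    s = _welzl(points[1:], boundary)
    if s is not None and np.linalg.norm(p - s.center) <= s.radius + 1e-12 * (1 + s.radius):
        return s
    return _welzl(points[1:], boundary + [p])


def circumscribing_sphere(points: np.ndarray) -> Sphere:
    """Smallest enclosing sphere of a small point set (Welzl's algorithm).

    All points lie inside or on the returned sphere to 1e-9 mm; the sphere is
    minimal (supported by 2-4 of the points, or degenerate).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    s = _welzl([p for p in pts], [])
    # guard: numerical support failures inflate minimally
    d = np.linalg.norm(pts - s.center, axis=1).max()
    if d > s.radius:
        s = Sphere(s.center, float(d))
    return s


# --------------------------------------------------------------------- I/O ---


def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".vtk",):
        return "vtk"
    if suffix in (".vtu",):
        return "vtu"
    if suffix in (".inp",):
        return "inp"
    raise ValueError(f"cannot infer mesh format from {path.name!r}")


def write_mesh(
    mesh: TetMesh,
    path,
    density: DensityField | None = None,
    fmt: str | None = None,
) -> None:
    """Write a tet mesh (optionally with per-element density) to disk.

    Supported formats: VTK legacy ASCII (``.vtk``), VTK XML unstructured grid
    (``.vtu``, ascii), Abaqus ``.inp`` (NODE / ELEMENT C3D4 / ELSET subset;
    density not representable, dropped with a warning).
    """
    path = Path(path)
    fmt = _detect_format(path, fmt)
    if fmt == "vtk":
        _write_vtk(mesh, path, density)
    elif fmt == "vtu":
        _write_vtu(mesh, path, density)
    elif fmt == "inp":
        if density is not None:
            logger.warning("Abaqus .inp subset cannot carry density; dropped")
        _write_inp(mesh, path)
    else:
        raise ValueError(f"unsupported mesh format {fmt!r}")


def read_mesh(path, fmt: str | None = None):
    """Read a tet mesh; returns ``(TetMesh, DensityField | None)``."""
    path = Path(path)
    fmt = _detect_format(path, fmt)
    if fmt == "vtk":
        return _read_vtk(path)
    if fmt == "vtu":
        return _read_vtu(path)
    if fmt == "inp":
        return _read_inp(path), None
    raise ValueError(f"unsupported mesh format {fmt!r}")


def _write_vtk(mesh: TetMesh, path: Path, density: DensityField | None) -> None:
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 2.0\n")
        f.write("ssamfe tet mesh; mm; x=ML y=AP z=PD\n")
        f.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(f, mesh.nodes, fmt="%.12g")
        f.write(f"CELLS {mesh.n_elements} {5 * mesh.n_elements}\n")
        cells = np.column_stack(
            [np.full(mesh.n_elements, 4, dtype=np.int64), mesh.elements]
        )
        np.savetxt(f, cells, fmt="%d")
        f.write(f"CELL_TYPES {mesh.n_elements}\n")
        np.savetxt(f, np.full(mesh.n_elements, 10, dtype=np.int64), fmt="%d")
        if density is not None or mesh.element_sets:
            f.write(f"CELL_DATA {mesh.n_elements}\n")
        if density is not None:
            f.write(f"SCALARS density_{density.kind} double 1\n")
            f.write("LOOKUP_TABLE default\n")
            np.savetxt(f, density.values, fmt="%.12g")
        for name, idx in mesh.element_sets.items():
            mask = np.zeros(mesh.n_elements, dtype=np.int64)
            mask[np.asarray(idx, dtype=np.int64)] = 1
            f.write(f"SCALARS elset_{name} int 1\nLOOKUP_TABLE default\n")
            np.savetxt(f, mask, fmt="%d")
        if mesh.node_sets:
            f.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, idx in mesh.node_sets.items():
                mask = np.zeros(mesh.n_nodes, dtype=np.int64)
                mask[np.asarray(idx, dtype=np.int64)] = 1
                f.write(f"SCALARS nset_{name} int 1\nLOOKUP_TABLE default\n")
                np.savetxt(f, mask, fmt="%d")


def _read_vtk(path: Path):
    tokens = iter(Path(path).read_text().split())
    nodes = elements = None
    density = None
    elsets: dict = {}
    nsets: dict = {}
    tok_list = list(tokens)
    i = 0

    def take(n):
        nonlocal i
        out = tok_list[i : i + n]
        i += n
        return out

    while i < len(tok_list):
        t = tok_list[i].upper()
        if t == "POINTS":
            n = int(tok_list[i + 1])
            i += 3
            nodes = np.array(take(3 * n), dtype=float).reshape(n, 3)
        elif t == "CELLS":
            m = int(tok_list[i + 1])
            total = int(tok_list[i + 2])
            i += 3
            raw = np.array(take(total), dtype=np.int64).reshape(m, -1)
            if raw.shape[1] != 5 or (raw[:, 0] != 4).any():
                raise ValueError("unsupported cell type: only 4-node tets")
            elements = raw[:, 1:]
        elif t == "CELL_TYPES":
            m = int(tok_list[i + 1])
            i += 2
            types = np.array(take(m), dtype=int)
            if (types != 10).any():
                raise ValueError("unsupported cell type (expected VTK_TETRA=10)")
        elif t == "SCALARS":
            name = tok_list[i + 1]
            i += 4  # SCALARS name type ncomp
            if tok_list[i].upper() == "LOOKUP_TABLE":
                i += 2
            count = len(elements) if not name.startswith("nset_") else len(nodes)
            vals = np.array(take(count), dtype=float)
            if name.startswith("density_"):
                density = DensityField(vals, kind=name[len("density_"):])
            elif name.startswith("elset_"):
                elsets[name[len("elset_"):]] = np.flatnonzero(vals > 0.5)
            elif name.startswith("nset_"):
                nsets[name[len("nset_"):]] = np.flatnonzero(vals > 0.5)
        else:
            i += 1
    if nodes is None or elements is None:
        raise ValueError(f"{path}: not a VTK unstructured tet mesh")
    if density is None:
        logger.warning("%s: no density array found, mesh only", path)
    return TetMesh(nodes, elements, nsets, elsets), density


def _write_vtu(mesh: TetMesh, path: Path, density: DensityField | None) -> None:
    def arr(parent, name, data, dtype):
        da = ET.SubElement(
            parent,
            "DataArray",
            type=dtype,
            Name=name,
            NumberOfComponents=str(data.shape[1] if data.ndim == 2 else 1),
            format="ascii",
        )
        da.text = "\n".join(
            " ".join(f"{x:.12g}" for x in np.atleast_1d(row))
            for row in np.atleast_2d(data)
        )
        return da

    root = ET.Element(
        "VTKFile", type="UnstructuredGrid", version="0.1", byte_order="LittleEndian"
    )
    grid = ET.SubElement(root, "UnstructuredGrid")
    piece = ET.SubElement(
        grid,
        "Piece",
        NumberOfPoints=str(mesh.n_nodes),
        NumberOfCells=str(mesh.n_elements),
    )
    pts = ET.SubElement(piece, "Points")
    arr(pts, "Points", mesh.nodes, "Float64")
    cells = ET.SubElement(piece, "Cells")
    arr(cells, "connectivity", mesh.elements.ravel(), "Int64")
    arr(cells, "offsets", np.arange(1, mesh.n_elements + 1) * 4, "Int64")
    arr(cells, "types", np.full(mesh.n_elements, 10), "Int64")
    if density is not None:
        cd = ET.SubElement(piece, "CellData")
        arr(cd, f"density_{density.kind}", density.values, "Float64")
    ET.ElementTree(root).write(path, xml_declaration=True)


def _read_vtu(path: Path):
    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")
    arrays = {}
    for da in piece.iter("DataArray"):
        if da.get("format", "ascii") != "ascii":
            raise ValueError("only ascii .vtu supported")
        arrays[da.get("Name")] = np.array((da.text or "").split(), dtype=float)
    nodes = arrays["Points"].reshape(-1, 3)
    types = arrays["types"].astype(int)
    if (types != 10).any():
        raise ValueError("unsupported cell type (expected VTK_TETRA=10)")
    elements = arrays["connectivity"].astype(np.int64).reshape(-1, 4)
    density = None
    for name, vals in arrays.items():
        if name and name.startswith("density_"):
            density = DensityField(vals, kind=name[len("density_"):])
    if density is None:
        logger.warning("%s: no density array found, mesh only", path)
    return TetMesh(nodes, elements), density


def _write_inp(mesh: TetMesh, path: Path) -> None:
    with open(path, "w") as f:
        f.write("*HEADING\nssamfe tet mesh; mm; x=ML y=AP z=PD\n*NODE\n")
        for i, (x, y, z) in enumerate(mesh.nodes, start=1):
            f.write(f"{i}, {x:.12g}, {y:.12g}, {z:.12g}\n")
        f.write("*ELEMENT, TYPE=C3D4\n")
        for i, e in enumerate(mesh.elements + 1, start=1):
            f.write(f"{i}, {e[0]}, {e[1]}, {e[2]}, {e[3]}\n")
        for name, idx in mesh.element_sets.items():
            f.write(f"*ELSET, ELSET={name}\n")
            ids = np.asarray(idx, dtype=np.int64) + 1
            for chunk in np.array_split(ids, max(1, len(ids) // 8)):
                f.write(", ".join(str(int(v)) for v in chunk) + "\n")


def _read_inp(path: Path) -> TetMesh:
    nodes: dict[int, list[float]] = {}
    elements: dict[int, list[int]] = {}
    elsets: dict[str, list[int]] = {}
    section = None
    current_set = None
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("**"):
            continue
        if line.startswith("*"):
            kw = line.split(",")[0].strip().upper()
            if kw == "*NODE":
                section = "node"
            elif kw == "*ELEMENT":
                m = re.search(r"TYPE\s*=\s*(\S+)", line, re.IGNORECASE)
                etype = m.group(1).upper().rstrip(",") if m else ""
                if not etype.startswith("C3D4"):
                    raise ValueError(f"unsupported element type {etype!r}")
                section = "element"
            elif kw == "*ELSET":
                m = re.search(r"ELSET\s*=\s*(\S+)", line, re.IGNORECASE)
                current_set = m.group(1).rstrip(",") if m else "elset"
                elsets.setdefault(current_set, [])
                section = "elset"
            else:
                section = None
            continue
        parts = [p for p in line.replace(",", " ").split() if p]
        if section == "node":
            nodes[int(parts[0])] = [float(v) for v in parts[1:4]]
        elif section == "element":
            elements[int(parts[0])] = [int(v) for v in parts[1:5]]
        elif section == "elset" and current_set is not None:
            elsets[current_set].extend(int(v) for v in parts)
    node_ids = sorted(nodes)
    remap = {nid: k for k, nid in enumerate(node_ids)}
    coords = np.array([nodes[nid] for nid in node_ids])
    elem_ids = sorted(elements)
    eremap = {eid: k for k, eid in enumerate(elem_ids)}
    conn = np.array([[remap[n] for n in elements[eid]] for eid in elem_ids])
    esets = {
        name: np.array(sorted(eremap[e] for e in ids), dtype=np.int64)
        for name, ids in elsets.items()
    }
    return TetMesh(coords, conn, element_sets=esets)
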