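"""Conforming 1D and 2D simplicial meshes, built-in generators, quality
metrics and text-format I/O (Triangle .node/.ele, Gmsh MSH 2.2, legacy VTK).

Coordinates are in cm throughout.  Triangles are stored counter-clockwise;
edges are identified by their sorted vertex pair and carry a global
orientation from the lower to the higher vertex index, which is what makes
odd (direction-sensitive) edge modes continuous across elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

__all__ = [
    "Mesh",
    "MeshQuality",
    "build_interval_mesh",
    "build_square_mesh",
    "build_square_with_holes_mesh",
    "mesh_quality",
    "read_mesh",
    "write_triangle",
    "read_triangle",
    "read_gmsh",
    "write_vtk",
]

_LOCAL_EDGES = np.array([(0, 1), (1, 2), (0, 2)])


class MeshError(ValueError):
    pass


@dataclass
class Mesh:
    """A conforming simplicial mesh.

    Attributes
    ----------
    dim : 1 or 2
    vertices : (V, dim) float array, cm
    elements : (T, dim+1) int array; CCW in 2D
    edges : (E, 2) int array of sorted vertex pairs (2D only)
    element_edges : (T, 3) indices into ``edges`` for local edges
        (0,1), (1,2), (0,2) of each element (2D only)
    boundary_tags : dict name -> array of boundary edge indices (2D) or
        vertex indices (1D)
    """

    dim: int
    vertices: np.ndarray
    elements: np.ndarray
    boundary_tags: dict = field(default_factory=dict)
    edges: np.ndarray | None = None
    element_edges: np.ndarray | None = None

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        if self.vertices.ndim == 1:
            self.vertices = self.vertices[:, None]
        self.elements = np.ascontiguousarray(self.elements, dtype=np.int64)
        if self.dim == 2:
            self._orient_ccw()
            self._build_edges()

    # -- derived structure -------------------------------------------------
    def _orient_ccw(self):
        v = self.vertices
        t = self.elements
        a = v[t[:, 1]] - v[t[:, 0]]
        b = v[t[:, 2]] - v[t[:, 0]]
        signed = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
        flip = signed < 0
        if flip.any():
            self.elements[flip, 1], self.elements[flip, 2] = \
                self.elements[flip, 2].copy(), self.elements[flip, 1].copy()

    def _build_edges(self):
        t = self.elements
        raw = np.sort(t[:, _LOCAL_EDGES].reshape(-1, 2), axis=1)
        self.edges, inv = np.unique(raw, axis=0, return_inverse=True)
        self.element_edges = inv.reshape(-1, 3)
        counts = np.bincount(inv, minlength=len(self.edges))
        self.edge_element_count = counts
        self.boundary_edges = np.nonzero(counts == 1)[0]

    # -- basic quantities --------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def n_edges(self) -> int:
        return 0 if self.edges is None else len(self.edges)

    def element_diameters(self) -> np.ndarray:
        """diam of each element: segment length (1D) / longest edge (2D)."""
        v, t = self.vertices, self.elements
        if self.dim == 1:
            return np.abs(v[t[:, 1], 0] - v[t[:, 0], 0])
        lengths = [np.linalg.norm(v[t[:, b]] - v[t[:, a]], axis=1)
                   for a, b in _LOCAL_EDGES]
        return np.max(lengths, axis=0)

    def element_areas(self) -> np.ndarray:
        v, t = self.vertices, self.elements
        if self.dim == 1:
            return self.element_diameters()
        a = v[t[:, 1]] - v[t[:, 0]]
        b = v[t[:, 2]] - v[t[:, 0]]
        return 0.5 * (a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0])

    def circumdiameters(self) -> np.ndarray:
        """2 x circumradius per element (equals diam in 1D)."""
        if self.dim == 1:
            return self.element_diameters()
        v, t = self.vertices, self.elements
        ea = np.linalg.norm(v[t[:, 2]] - v[t[:, 1]], axis=1)
        eb = np.linalg.norm(v[t[:, 2]] - v[t[:, 0]], axis=1)
        ec = np.linalg.norm(v[t[:, 1]] - v[t[:, 0]], axis=1)
        area = self.element_areas()
        return ea * eb * ec / (2.0 * area)

    def mean_element_diameter(self) -> float:
        """Arithmetic mean of element circumdiameters (table label)."""
        return float(self.circumdiameters().mean())

    def element_centroids(self) -> np.ndarray:
        return self.vertices[self.elements].mean(axis=1)

    # -- validation --------------------------------------------------------
    def validate(self):
        """Raise MeshError on conformity / orientation violations."""
        if self.dim == 1:
            h = self.vertices[self.elements[:, 1], 0] - self.vertices[self.elements[:, 0], 0]
            if (h <= 0).any():
                raise MeshError("1D elements must be ordered left-to-right")
            return
        areas = self.element_areas()
        if (areas <= 0).any():
            raise MeshError(f"non-positive element area at {int(np.argmin(areas))}")
        bad = np.nonzero(self.edge_element_count > 2)[0]
        if bad.size:
            raise MeshError(f"edge {int(bad[0])} shared by >2 elements (non-conforming)")


@dataclass(frozen=True)
class MeshQuality:
    """Quasiuniformity metrics: h = max diam, Q = h / min diam,
    R = max diam/(inscribed-ball diameter)."""

    h: float
    Q: float
    R: float


def mesh_quality(mesh: Mesh) -> MeshQuality:
    diam = mesh.element_diameters()
    if (diam <= 0).any():
        raise MeshError(f"degenerate element {int(np.argmin(diam))}")
    h = float(diam.max())
    Q = float(h / diam.min())
    if mesh.dim == 1:
        R = float(Q * 0 + (diam / diam).max())  # rho == h in 1D
        return MeshQuality(h=h, Q=Q, R=1.0)
    v, t = mesh.vertices, mesh.elements
    ea = np.linalg.norm(v[t[:, 2]] - v[t[:, 1]], axis=1)
    eb = np.linalg.norm(v[t[:, 2]] - v[t[:, 0]], axis=1)
    ec = np.linalg.norm(v[t[:, 1]] - v[t[:, 0]], axis=1)
    area = mesh.element_areas()
    if (area <= 0).any():
        raise MeshError(f"degenerate element {int(np.argmin(area))}")
    rho = 4.0 * area / (ea + eb + ec)  # inradius diameter = 2*Area/s
    return MeshQuality(h=h, Q=Q, R=float((diam / rho).max()))


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def build_interval_mesh(length: float, h: float) -> Mesh:
    """Uniform mesh of [0, length] with round(length/h) segments."""
    if length <= 0 or h <= 0 or h > length:
        raise ValueError("need 0 < h <= length")
    n = int(round(length / h))
    x = np.linspace(0.0, length, n + 1)
    elems = np.column_stack([np.arange(n), np.arange(1, n + 1)])
    return Mesh(dim=1, vertices=x, elements=elems,
                boundary_tags={"left": np.array([0]), "right": np.array([n])})


def _hex_lattice(side: float, a: float, rng, jitter: float = 0.12):
    """Jittered hexagonal lattice strictly inside [0,side]^2 plus exact
    boundary points with spacing ~a."""
    dy = a * np.sqrt(3.0) / 2.0
    pts = []
    ny = int(np.floor(side / dy))
    for j in range(1, ny + 1):
        y = j * dy
        if y > side - 0.45 * a:
            continue
        off = 0.5 * a if j % 2 else 0.0
        xs = np.arange(off if off else a, side, a)
        xs = xs[(xs > 0.45 * a) & (xs < side - 0.45 * a)]
        for x in xs:
            pts.append((x, y))
    pts = np.array(pts) if pts else np.zeros((0, 2))
    if len(pts):
        pts = pts + jitter * a * rng.uniform(-1.0, 1.0, size=pts.shape)
    nb = max(1, int(round(side / a)))
    s = np.linspace(0.0, side, nb + 1)
    bottom = np.column_stack([s, np.zeros_like(s)])
    top = np.column_stack([s, np.full_like(s, side)])
    left = np.column_stack([np.zeros(nb - 1), s[1:-1]])
    right = np.column_stack([np.full(nb - 1, side), s[1:-1]])
    return np.vstack([bottom, top, left, right, pts])


def _tag_square_boundary(mesh: Mesh, side: float, tol: float = 1e-9):
    v, e = mesh.vertices, mesh.edges
    mids = 0.5 * (v[e[:, 0]] + v[e[:, 1]])
    tags = {}
    onb = mesh.boundary_edges
    m = mids[onb]
    tags["bottom"] = onb[np.abs(m[:, 1]) < tol]
    tags["top"] = onb[np.abs(m[:, 1] - side) < tol]
    tags["left"] = onb[np.abs(m[:, 0]) < tol]
    tags["right"] = onb[np.abs(m[:, 0] - side) < tol]
    return tags


def build_square_mesh(side: float, target_h: float, seed: int = 0) -> Mesh:
    """Unstructured Delaunay triangulation of [0,side]^2 with mean element
    (circum)diameter within 15% of ``target_h``.  Deterministic per seed."""
    if not 0 < target_h < side:
        raise ValueError("need 0 < target_h < side")
    a = target_h / 1.24  # initial lattice spacing guess; refined below
    for _ in range(2):
        rng = np.random.default_rng(seed)
        pts = _hex_lattice(side, a, rng)
        tri = Delaunay(pts)
        mesh = Mesh(dim=2, vertices=tri.points, elements=tri.simplices)
        a *= target_h / mesh.mean_element_diameter()
    mesh.boundary_tags = _tag_square_boundary(mesh, side)
    mesh.validate()
    return mesh


def build_square_with_holes_mesh(side: float,
                                 holes=None,
                                 target_h: float = 0.05,
                                 seed: int = 0) -> Mesh:
    """Triangulation of [0,side]^2 minus circular holes, graded finer near
    the hole boundaries, which are tagged "hole0", "hole1", ...

    ``holes`` is a list of ((cx, cy), radius); the defaults mimic two blood
    vessels crossing the tissue slab.
    """
    if holes is None:
        holes = [((0.32 * side, 0.60 * side), 0.08 * side),
                 ((0.68 * side, 0.34 * side), 0.10 * side)]
    for (c, r) in holes:
        if not (r < c[0] < side - r and r < c[1] < side - r):
            raise ValueError(f"hole at {c} not strictly inside the square")
    for i, (c1, r1) in enumerate(holes):
        for c2, r2 in holes[i + 1:]:
            if np.hypot(c1[0] - c2[0], c1[1] - c2[1]) <= r1 + r2:
                raise ValueError("holes overlap")

    rng = np.random.default_rng(seed)
    a = target_h / 1.24
    pts = _hex_lattice(side, a, rng)
    # several concentric fine rings: elements graded smaller near the holes
    # so the rule-based fibre directions resolve the flow around them
    n_layers = 4
    ring_pts = []
    excl = []
    for (c, r) in holes:
        hf = min(0.5 * a, r / 10.0)
        for k in range(n_layers):
            rr = r + k * hf
            n = max(16, int(np.ceil(2.0 * np.pi * rr / hf)))
            th = (np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
                  + np.pi * k / n)  # stagger successive rings
            ring_pts.append(np.column_stack([c[0] + rr * np.cos(th),
                                             c[1] + rr * np.sin(th)]))
        excl.append(r + (n_layers - 0.45) * hf)
    ring = np.vstack(ring_pts)
    keep = np.ones(len(pts), bool)
    for (c, r), re_ in zip(holes, excl):
        d = np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1])
        keep &= d > re_ + 0.5 * a
    allpts = np.vstack([pts[keep], ring])
    tri = Delaunay(allpts)
    cent = allpts[tri.simplices].mean(axis=1)
    inside_hole = np.zeros(len(cent), bool)
    for (c, r) in holes:
        inside_hole |= np.hypot(cent[:, 0] - c[0], cent[:, 1] - c[1]) < r
    elems = tri.simplices[~inside_hole]
    used = np.unique(elems)
    remap = -np.ones(len(allpts), np.int64)
    remap[used] = np.arange(len(used))
    mesh = Mesh(dim=2, vertices=allpts[used], elements=remap[elems])
    tags = _tag_square_boundary(mesh, side)
    v, e = mesh.vertices, mesh.edges
    for k, (c, r) in enumerate(holes):
        d0 = np.abs(np.hypot(v[e[:, 0], 0] - c[0], v[e[:, 0], 1] - c[1]) - r)
        d1 = np.abs(np.hypot(v[e[:, 1], 0] - c[0], v[e[:, 1], 1] - c[1]) - r)
        on_circle = (d0 < 1e-8) & (d1 < 1e-8)
        tags[f"hole{k}"] = np.nonzero(on_circle & (mesh.edge_element_count == 1))[0]
    mesh.boundary_tags = tags
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# I/O: Triangle .node/.ele, Gmsh MSH 2.2 ASCII, legacy VTK ASCII
# ---------------------------------------------------------------------------

def write_triangle(mesh: Mesh, basename: str):
    """Write Triangle-style 1-indexed .node and .ele files."""
    v, t = mesh.vertices, mesh.elements
    with open(basename + ".node", "w") as f:
        f.write(f"{len(v)} 2 0 0\n")
        for i, (x, y) in enumerate(v, start=1):
            f.write(f"{i} {float(x)!r} {float(y)!r}\n")
    with open(basename + ".ele", "w") as f:
        f.write(f"{len(t)} 3 0\n")
        for i, tri in enumerate(t, start=1):
            f.write(f"{i} {tri[0] + 1} {tri[1] + 1} {tri[2] + 1}\n")


def _tokens(path):
    with open(path) as f:
        for ln, line in enumerate(f, start=1):
            line = line.split("#", 1)[0].strip()
            if line:
                yield ln, line.split()


def read_triangle(basename: str) -> Mesh:
    """Read Triangle .node/.ele (1-indexed; attribute columns ignored)."""
    toks = _tokens(basename + ".node")
    ln, hdr = next(toks)
    try:
        nv, dim = int(hdr[0]), int(hdr[1])
    except (ValueError, IndexError):
        raise MeshError(f"{basename}.node:{ln}: malformed header")
    if dim != 2:
        raise MeshError(f"{basename}.node:{ln}: only 2D supported")
    verts = np.empty((nv, 2))
    for i in range(nv):
        ln, t = next(toks)
        try:
            verts[int(t[0]) - 1] = (float(t[1]), float(t[2]))
        except (ValueError, IndexError):
            raise MeshError(f"{basename}.node:{ln}: malformed vertex line")
    toks = _tokens(basename + ".ele")
    ln, hdr = next(toks)
    nt, npe = int(hdr[0]), int(hdr[1])
    if npe != 3:
        raise MeshError(f"{basename}.ele:{ln}: only 3-node triangles supported")
    elems = np.empty((nt, 3), np.int64)
    for i in range(nt):
        ln, t = next(toks)
        try:
            elems[int(t[0]) - 1] = [int(t[1]) - 1, int(t[2]) - 1, int(t[3]) - 1]
        except (ValueError, IndexError):
            raise MeshError(f"{basename}.ele:{ln}: malformed element line")
    return Mesh(dim=2, vertices=verts, elements=elems)


def read_gmsh(path: str) -> Mesh:
    """Read a Gmsh MSH 2.2 ASCII file (triangles only)."""
    with open(path) as f:
        lines = f.read().splitlines()
    i = 0

    def expect(tag):
        nonlocal i
        while i < len(lines) and not lines[i].strip():
            i += 1
        if i >= len(lines) or lines[i].strip() != tag:
            raise MeshError(f"{path}:{i + 1}: expected {tag}")
        i += 1

    expect("$MeshFormat")
    ver = lines[i].split()[0]
    if not ver.startswith("2."):
        raise MeshError(f"{path}:{i + 1}: unsupported MSH version {ver}")
    i += 1
    expect("$EndMeshFormat")
    expect("$Nodes")
    nv = int(lines[i]); i += 1
    verts = np.empty((nv, 2))
    ids = {}
    for k in range(nv):
        t = lines[i].split(); i += 1
        ids[int(t[0])] = k
        verts[k] = (float(t[1]), float(t[2]))
    expect("$EndNodes")
    expect("$Elements")
    ne = int(lines[i]); i += 1
    tris = []
    for _ in range(ne):
        t = lines[i].split(); i += 1
        etype = int(t[1])
        ntags = int(t[2])
        conn = [int(x) for x in t[3 + ntags:]]
        if etype == 2:
            tris.append([ids[c] for c in conn])
        elif etype in (1, 15):
            continue  # boundary lines / points: geometric info only
        else:
            raise MeshError(f"{path}:{i}: unsupported element type {etype}")
    expect("$EndElements")
    if not tris:
        raise MeshError(f"{path}: no triangles found")
    return Mesh(dim=2, vertices=verts, elements=np.array(tris, np.int64))


def read_mesh(path: str, fmt: str) -> Mesh:
    if fmt == "triangle_node_ele":
        base = path
        for suf in (".node", ".ele"):
            if base.endswith(suf):
                base = base[: -len(suf)]
        return read_triangle(base)
    if fmt == "gmsh_msh2":
        return read_gmsh(path)
    raise ValueError(f"unknown mesh format {fmt!r}")


def write_vtk(mesh: Mesh, fields: dict, path: str):
    """Legacy VTK ASCII output with named point-data arrays (e.g. "Vm")."""
    v, t = mesh.vertices, mesh.elements
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nhpmono output\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {len(v)} double\n")
        for p in v:
            x = p[0]
            y = p[1] if mesh.dim == 2 else 0.0
            f.write(f"{float(x)!r} {float(y)!r} 0.0\n")
        npe = mesh.dim + 1
        f.write(f"CELLS {len(t)} {len(t) * (npe + 1)}\n")
        for tri in t:
            f.write(" ".join([str(npe)] + [str(int(c)) for c in tri]) + "\n")
        f.write(f"CELL_TYPES {len(t)}\n")
        ct = "5" if mesh.dim == 2 else "3"
        f.write("\n".join([ct] * len(t)) + "\n")
        if fields:
            f.write(f"POINT_DATA {len(v)}\n")
            for name, data in fields.items():
                data = np.asarray(data, float).reshape(len(v), -1)
                if data.shape[1] == 1:
                    f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    for val in data[:, 0]:
                        f.write(f"{float(val)!r}\n")
                else:
                    f.write(f"VECTORS {name} double\n")
                    for row in data:
                        vals = list(row) + [0.0] * (3 - len(row))
                        f.write(f"{float(vals[0])!r} {float(vals[1])!r} {float(vals[2])!r}\n")
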