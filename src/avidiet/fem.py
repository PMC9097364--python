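"""Minimal 2D plane-strain linear-elastic solver (constant-strain triangles).

Implements the comparative jaw-model protocol: two isotropic materials
(bone E = 7000 MPa, rhamphotheca E = 3000 MPa, both nu = 0.35), a single
resultant muscle force at the attachment node, an articular pin (both
translations fixed), a bite node fixed vertically, and square-root-of-area
load scaling that makes strain fields of geometrically similar models
identical.  Units: mm, N, MPa; strains are dimensionless, reported as
microstrain where noted.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.linalg import splu
from scipy.spatial import Delaunay
from shapely.geometry import Point, Polygon as _ShapelyPolygon

from .errors import MaterialError, MeshError, SolverError

__all__ = [
    "Material",
    "BONE",
    "RHAMPHOTHECA",
    "PlaneMesh",
    "LoadCase",
    "FEResult",
    "plane_strain_matrix",
    "solve",
    "scale_load",
    "base_load",
    "build_jaw_model",
    "write_mesh",
    "read_mesh",
]

#: default reference muscle-load magnitude (N) for the smallest model
DEFAULT_BASE_LOAD_N = 6.0

#: default muscle-force angle from the horizontal (deg)
DEFAULT_ATTACH_ANGLE_DEG = 45.0


@dataclass(frozen=True)
class Material:
    """Linear-elastic isotropic material: Young's modulus (MPa), Poisson ratio."""

    E: float
    nu: float
    name: str = ""

    def __post_init__(self):
        if self.E <= 0:
            raise MaterialError(f"Young's modulus must be positive, got {self.E}")
        if not (0.0 <= self.nu < 0.5):
            raise MaterialError(f"Poisson ratio must satisfy 0 <= nu < 0.5, got {self.nu}")


BONE = Material(E=7000.0, nu=0.35, name="bone")
RHAMPHOTHECA = Material(E=3000.0, nu=0.35, name="rhamphotheca")


def plane_strain_matrix(mat: Material) -> np.ndarray:
    """Plane-strain constitutive matrix D (3x3, Voigt order xx, yy, xy)."""
    E, nu = mat.E, mat.nu
    c = E / ((1.0 + nu) * (1.0 - 2.0 * nu))
    return c * np.array([
        [1.0 - nu, nu, 0.0],
        [nu, 1.0 - nu, 0.0],
        [0.0, 0.0, (1.0 - 2.0 * nu) / 2.0],
    ])


class PlaneMesh:
    """Triangle mesh with per-element material ids.

    ``nodes``: (n, 2) coordinates in mm. ``triangles``: (m, 3) node indices,
    counter-clockwise. ``materials``: length-m sequence of material-id strings.
    """

    def __init__(self, nodes, triangles, materials):
        self.nodes = np.asarray(nodes, dtype=float)
        self.triangles = np.asarray(triangles, dtype=int)
        self.materials = np.asarray(materials, dtype=object)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 2:
            raise MeshError("nodes must be an (n, 2) array")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise MeshError("triangles must be an (m, 3) array")
        if len(self.materials) != len(self.triangles):
            raise MeshError("one material id required per triangle")
        areas = self.signed_areas()
        if np.any(areas <= 0):
            bad = int(np.argmin(areas))
            raise MeshError(
                f"triangle {bad} has non-positive signed area {areas[bad]:.3e} "
                "(vertices must be counter-clockwise)")
        used = np.unique(self.triangles)
        if used.min() < 0 or used.max() >= len(self.nodes):
            raise MeshError("triangle references node out of range")
        if len(used) != len(self.nodes):
            raise MeshError("mesh contains orphan nodes")

    def signed_areas(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        return 0.5 * ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                      - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))

    @property
    def areas(self) -> np.ndarray:
        return self.signed_areas()

    def total_area(self) -> float:
        return float(self.signed_areas().sum())

    def nearest_node(self, point) -> int:
        d = np.linalg.norm(self.nodes - np.asarray(point, dtype=float), axis=1)
        return int(np.argmin(d))

    def scaled(self, factor: float) -> "PlaneMesh":
        return PlaneMesh(self.nodes * factor, self.triangles, self.materials)


@dataclass
class LoadCase:
    """Point loads plus fixed degrees of freedom.

    The jaw protocol uses a force at the muscle-attachment node, a pinned
    articular node (both translations) and a bite node fixed vertically.
    ``extra_loads``/``extra_fixed`` admit generic boundary conditions (patch
    and beam verification tests).
    """

    load_node: int | None = None
    force: tuple[float, float] = (0.0, 0.0)
    pin_node: int | None = None
    bite_node: int | None = None
    extra_loads: dict[int, tuple[float, float]] = field(default_factory=dict)
    extra_fixed: dict[int, tuple[bool, bool]] = field(default_factory=dict)

    @classmethod
    def from_magnitude(cls, load_node: int, magnitude: float, angle_deg: float,
                       pin_node: int, bite_node: int) -> "LoadCase":
        """Force given as magnitude and angle (deg) from the horizontal."""
        a = math.radians(angle_deg)
        return cls(load_node=load_node,
                   force=(magnitude * math.cos(a), magnitude * math.sin(a)),
                   pin_node=pin_node, bite_node=bite_node)

    def validate(self, n_nodes: int) -> None:
        named = [n for n in (self.load_node, self.pin_node, self.bite_node) if n is not None]
        for n in named + list(self.extra_loads) + list(self.extra_fixed):
            if not (0 <= n < n_nodes):
                raise MeshError(f"node {n} out of range")
        if self.load_node is not None and self.pin_node is not None:
            if len({self.load_node, self.pin_node, self.bite_node}) < 3:
                raise MeshError("load, pin and bite nodes must be distinct")

    def assemble(self, n_nodes: int):
        loads = np.zeros(2 * n_nodes)
        if self.load_node is not None:
            loads[2 * self.load_node] += self.force[0]
            loads[2 * self.load_node + 1] += self.force[1]
        for n, (fx, fy) in self.extra_loads.items():
            loads[2 * n] += fx
            loads[2 * n + 1] += fy
        fixed = np.zeros(2 * n_nodes, dtype=bool)
        if self.pin_node is not None:
            fixed[2 * self.pin_node] = fixed[2 * self.pin_node + 1] = True
        if self.bite_node is not None:
            fixed[2 * self.bite_node + 1] = True
        for n, (fx, fy) in self.extra_fixed.items():
            if fx:
                fixed[2 * n] = True
            if fy:
                fixed[2 * n + 1] = True
        return loads, fixed


@dataclass
class FEResult:
    """Nodal displacements plus per-element strain measures."""

    displacements: np.ndarray          # (n, 2)
    strains: np.ndarray                # (m, 3) eps_xx, eps_yy, gamma_xy
    principal_microstrain: np.ndarray  # (m,) max in-plane principal strain, x1e6
    element_areas: np.ndarray          # (m,) mm^2
    reactions: np.ndarray              # (n, 2) forces at constrained dofs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "element": np.arange(len(self.strains)),
            "area_mm2": self.element_areas,
            "eps_xx": self.strains[:, 0],
            "eps_yy": self.strains[:, 1],
            "gamma_xy": self.strains[:, 2],
            "e1_max_in_plane_ue": self.principal_microstrain,
        })


def _element_b_matrix(p: np.ndarray, area: float) -> np.ndarray:
    """Strain-displacement matrix for a constant-strain triangle."""
    (x1, y1), (x2, y2), (x3, y3) = p
    b1, b2, b3 = y2 - y3, y3 - y1, y1 - y2
    c1, c2, c3 = x3 - x2, x1 - x3, x2 - x1
    B = np.array([
        [b1, 0, b2, 0, b3, 0],
        [0, c1, 0, c2, 0, c3],
        [c1, b1, c2, b2, c3, b3],
    ]) / (2.0 * area)
    return B


def solve(mesh: PlaneMesh, materials: dict[str, Material], case: LoadCase) -> FEResult:
    """Assemble, eliminate constrained dofs, and solve the linear system.

    Per-element strain is B u; the reported principal strain is
    (exx+eyy)/2 + sqrt(((exx-eyy)/2)^2 + (gxy/2)^2), in microstrain.
    """
    case.validate(len(mesh.nodes))
    n = len(mesh.nodes)
    areas = mesh.signed_areas()
    missing = sorted(set(mesh.materials) - set(materials))
    if missing:
        raise MeshError(f"no material definition for ids: {missing}")
    D_by_id = {mid: plane_strain_matrix(mat) for mid, mat in materials.items()}

    rows, cols, vals = [], [], []
    B_all = np.empty((len(mesh.triangles), 3, 6))
    for e, tri in enumerate(mesh.triangles):
        p = mesh.nodes[tri]
        B = _element_b_matrix(p, areas[e])
        B_all[e] = B
        Ke = areas[e] * B.T @ D_by_id[mesh.materials[e]] @ B
        dofs = np.array([2 * tri[0], 2 * tri[0] + 1,
                         2 * tri[1], 2 * tri[1] + 1,
                         2 * tri[2], 2 * tri[2] + 1])
        rows.extend(np.repeat(dofs, 6))
        cols.extend(np.tile(dofs, 6))
        vals.extend(Ke.ravel())
    K = coo_matrix((vals, (rows, cols)), shape=(2 * n, 2 * n)).tocsr()

    loads, fixed = case.assemble(n)
    free = ~fixed
    if free.sum() == 0:
        raise SolverError("all degrees of freedom constrained")
    Kff = K[free][:, free].tocsc()
    try:
        lu = splu(Kff)
    except RuntimeError as exc:
        raise SolverError(f"singular system: {exc}") from exc
    udiag = np.abs(lu.U.diagonal())
    if udiag.min() <= 1e-10 * udiag.max():
        raise SolverError(
            "singular system: constraints leave rigid-body modes "
            f"(pivot ratio {udiag.min() / udiag.max():.2e})")
    u_free = lu.solve(loads[free])
    if not np.all(np.isfinite(u_free)):
        raise SolverError("singular system: constraints leave rigid-body modes")

    u = np.zeros(2 * n)
    u[free] = u_free
    residual = K @ u - loads
    reactions = np.where(fixed, residual, 0.0).reshape(n, 2)

    strains = np.empty((len(mesh.triangles), 3))
    for e, tri in enumerate(mesh.triangles):
        dofs = np.array([2 * tri[0], 2 * tri[0] + 1,
                         2 * tri[1], 2 * tri[1] + 1,
                         2 * tri[2], 2 * tri[2] + 1])
        strains[e] = B_all[e] @ u[dofs]
    exx, eyy, gxy = strains[:, 0], strains[:, 1], strains[:, 2]
    e1 = (exx + eyy) / 2.0 + np.sqrt(((exx - eyy) / 2.0) ** 2 + (gxy / 2.0) ** 2)
    return FEResult(
        displacements=u.reshape(n, 2),
        strains=strains,
        principal_microstrain=e1 * 1e6,
        element_areas=areas,
        reactions=reactions,
    )


def base_load(config: dict | None = None) -> float:
    """Reference muscle-load magnitude (N); configurable, default 6 N."""
    if config and "base_load_n" in config:
        return float(config["base_load_n"])
    return DEFAULT_BASE_LOAD_N


def scale_load(F_ref: float, area_ref: float, area_target: float,
               exponent: float = 0.5) -> float:
    """Load giving the same strain state on a geometrically similar model.

    For plane models of unit thickness, stress scales as F/length and area as
    length^2, so constant stress state requires F proportional to sqrt(area).
    """
    if area_ref <= 0 or area_target <= 0:
        raise ValueError("areas must be positive")
    return F_ref * (area_target / area_ref) ** exponent


# ---------------------------------------------------------------------------
# Jaw model construction


def _polygon_band_fraction(poly: _ShapelyPolygon, x: float, y: float,
                           rham_fraction: float) -> bool:
    """True when (x, y) lies in the dorsal band of local dorsoventral thickness."""
    from shapely.geometry import LineString

    minx, miny, maxx, maxy = poly.bounds
    vertical = LineString([(x, miny - 1.0), (x, maxy + 1.0)])
    inter = poly.intersection(vertical)
    if inter.is_empty:
        return False
    ys = []
    geoms = getattr(inter, "geoms", [inter])
    for g in geoms:
        ys.extend(np.asarray(g.coords)[:, 1])
    lo, hi = min(ys), max(ys)
    if hi <= lo:
        return False
    return y > hi - rham_fraction * (hi - lo)


def triangulate_polygon(outline, target_h: float,
                        required_points=()) -> tuple[np.ndarray, np.ndarray]:
    """Mesh a simple polygon: resampled boundary + interior grid + Delaunay.

    Triangles whose centroid falls outside the polygon are discarded, which
    also handles concave outlines.  ``required_points`` are injected verbatim
    so loads/constraints land on actual nodes.
    """
    poly = _ShapelyPolygon(outline)
    if not poly.is_valid or poly.area <= 0:
        raise MeshError("outline is not a valid simple polygon")
    pts = []
    boundary = np.asarray(poly.exterior.coords)  # closed ring
    for a, b in zip(boundary[:-1], boundary[1:]):
        seg = np.linalg.norm(b - a)
        nseg = max(1, int(math.ceil(seg / target_h)))
        for k in range(nseg):
            pts.append(a + (b - a) * (k / nseg))
    pts = np.asarray(pts)

    minx, miny, maxx, maxy = poly.bounds
    dx = target_h
    dy = target_h * math.sqrt(3.0) / 2.0
    interior = []
    row = 0
    y = miny + dy
    while y < maxy - 0.25 * dy:
        x0 = minx + (dx / 2.0 if row % 2 else dx)
        x = x0
        while x < maxx:
            pt = Point(x, y)
            if poly.contains(pt) and poly.exterior.distance(pt) > 0.35 * target_h:
                interior.append((x, y))
            x += dx
        y += dy
        row += 1

    req = np.asarray(required_points, dtype=float).reshape(-1, 2)
    all_pts = [pts]
    if len(interior):
        interior = np.asarray(interior)
        if len(req):
            keep = np.ones(len(interior), dtype=bool)
            for rp in req:
                keep &= np.linalg.norm(interior - rp, axis=1) > 0.5 * target_h
            interior = interior[keep]
        all_pts.append(interior)
    if len(req):
        all_pts.append(req)
    points = np.vstack(all_pts)
    # deduplicate within tolerance
    scale = max(maxx - minx, maxy - miny)
    rounded = np.round(points / (1e-9 * scale)).astype(np.int64)
    _, keep_idx = np.unique(rounded, axis=0, return_index=True)
    points = points[np.sort(keep_idx)]

    tri = Delaunay(points)
    simplices = []
    for s in tri.simplices:
        p = points[s]
        cx, cy = p.mean(axis=0)
        area = 0.5 * ((p[1, 0] - p[0, 0]) * (p[2, 1] - p[0, 1])
                      - (p[2, 0] - p[0, 0]) * (p[1, 1] - p[0, 1]))
        if abs(area) < 1e-12 * scale * scale:
            continue
        if not poly.contains(Point(cx, cy)):
            continue
        simplices.append(s if area > 0 else s[[0, 2, 1]])
    if not simplices:
        raise MeshError("triangulation produced no interior triangles")
    simplices = np.asarray(simplices, dtype=int)
    used = np.unique(simplices)
    remap = -np.ones(len(points), dtype=int)
    remap[used] = np.arange(len(used))
    return points[used], remap[simplices]


def build_jaw_model(
    outline,
    rham_fraction: float,
    attach_point,
    attach_angle_deg: float = DEFAULT_ATTACH_ANGLE_DEG,
    bite_point=None,
    pin_point=None,
    target_h: float | None = None,
    load_magnitude: float | None = None,
) -> tuple[PlaneMesh, LoadCase]:
    """Triangulate a jaw outline and attach the standard comparative load case.

    Elements whose centroid lies in the dorsal band occupying
    ``rham_fraction`` of the local dorsoventral thickness are labelled
    rhamphotheca, the rest bone.  The muscle force acts at the attachment node
    at ``attach_angle_deg`` from the horizontal; the pin node is fixed in both
    axes and the bite node vertically.
    """
    if not (0.0 <= rham_fraction <= 1.0):
        raise ValueError("rham_fraction must lie in [0, 1]")
    poly = _ShapelyPolygon(outline)
    if target_h is None:
        target_h = math.sqrt(poly.area) / 15.0
    required = [p for p in (attach_point, bite_point, pin_point) if p is not None]
    for p in required:
        if poly.exterior.distance(Point(p)) > 1e-6 * math.sqrt(poly.area) \
                and not poly.contains(Point(p)):
            raise MeshError(f"point {p} lies outside the outline")
    nodes, tris = triangulate_polygon(outline, target_h, required_points=required)
    mats = []
    for t in tris:
        cx, cy = nodes[t].mean(axis=0)
        if rham_fraction > 0 and _polygon_band_fraction(poly, cx, cy, rham_fraction):
            mats.append("rhamphotheca")
        else:
            mats.append("bone")
    mesh = PlaneMesh(nodes, tris, mats)
    mag = base_load() if load_magnitude is None else load_magnitude
    case = LoadCase.from_magnitude(
        load_node=mesh.nearest_node(attach_point),
        magnitude=mag,
        angle_deg=attach_angle_deg,
        pin_node=mesh.nearest_node(pin_point) if pin_point is not None else 0,
        bite_node=mesh.nearest_node(bite_point) if bite_point is not None else 1,
    )
    return mesh, case


# ---------------------------------------------------------------------------
# ASCII mesh I/O (documented format: '# nodes' id,x,y then '# elements'
# id,n1,n2,n3,material)


def write_mesh(mesh: PlaneMesh, path_or_buf) -> None:
    buf = io.StringIO()
    buf.write("# nodes: id,x,y\n")
    for i, (x, y) in enumerate(mesh.nodes):
        buf.write(f"{i},{float(x)!r},{float(y)!r}\n")
    buf.write("# elements: id,n1,n2,n3,material\n")
    for e, tri in enumerate(mesh.triangles):
        buf.write(f"{e},{tri[0]},{tri[1]},{tri[2]},{mesh.materials[e]}\n")
    text = buf.getvalue()
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(text)


def read_gmsh(path_or_buf, material_map: dict[int, str] | None = None) -> PlaneMesh:
    """Import triangles from a Gmsh ASCII v2 file.

    Only 3-node triangle elements (type 2) are kept; the physical tag selects
    the material id through ``material_map`` (default: tag 1 -> bone,
    tag 2 -> rhamphotheca).
    """
    if hasattr(path_or_buf, "read"):
        lines = path_or_buf.read().splitlines()
    else:
        with open(path_or_buf) as fh:
            lines = fh.read().splitlines()
    material_map = material_map or {1: "bone", 2: "rhamphotheca"}
    it = iter(lines)
    node_xy: dict[int, tuple[float, float]] = {}
    tris, mats = [], []
    for line in it:
        tag = line.strip()
        if tag == "$Nodes":
            count = int(next(it))
            for _ in range(count):
                parts = next(it).split()
                node_xy[int(parts[0])] = (float(parts[1]), float(parts[2]))
        elif tag == "$Elements":
            count = int(next(it))
            for _ in range(count):
                parts = [int(p) for p in next(it).split()]
                etype, ntags = parts[1], parts[2]
                if etype != 2:
                    continue
                phys = parts[3] if ntags >= 1 else 1
                tris.append(tuple(parts[3 + ntags:3 + ntags + 3]))
                mats.append(material_map.get(phys, "bone"))
    if not tris:
        raise MeshError("no triangle elements found in Gmsh file")
    ids = sorted(node_xy)
    remap = {nid: k for k, nid in enumerate(ids)}
    nodes = np.array([node_xy[nid] for nid in ids])
    elems = np.array([[remap[a], remap[b], remap[c]] for a, b, c in tris])
    # enforce counter-clockwise orientation
    p = nodes[elems]
    areas = 0.5 * ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                   - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))
    elems[areas < 0] = elems[areas < 0][:, [0, 2, 1]]
    return PlaneMesh(nodes, elems, mats)


def plot_contours(mesh: PlaneMesh, result: FEResult, path, title: str = "",
                  cmap: str = "viridis") -> None:
    """Export a per-element principal-strain contour plot (PNG or SVG)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.collections import PolyCollection

    fig, ax = plt.subplots(figsize=(8, 4))
    polys = [mesh.nodes[tri] for tri in mesh.triangles]
    coll = PolyCollection(polys, array=result.principal_microstrain,
                          cmap=cmap, edgecolors="none")
    ax.add_collection(coll)
    ax.autoscale()
    ax.set_aspect("equal")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    if title:
        ax.set_title(title)
    fig.colorbar(coll, ax=ax, label="max in-plane principal strain (microstrain)")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


def read_mesh(path_or_buf) -> PlaneMesh:
    if hasattr(path_or_buf, "read"):
        lines = path_or_buf.read().splitlines()
    else:
        with open(path_or_buf) as fh:
            lines = fh.read().splitlines()
    nodes, tris, mats = [], [], []
    section = None
    for line in lines:
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            section = "nodes" if "nodes" in line else "elements"
            continue
        parts = line.split(",")
        if section == "nodes":
            nodes.append((float(parts[1]), float(parts[2])))
        elif section == "elements":
            tris.append((int(parts[1]), int(parts[2]), int(parts[3])))
            mats.append(parts[4])
        else:
            raise MeshError("mesh file must start with a '# nodes' header")
    return PlaneMesh(np.asarray(nodes), np.asarray(tris), mats)
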