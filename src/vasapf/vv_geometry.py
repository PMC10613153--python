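"""Annulus mesh generation and the stochastic vasa-vasorum tree fractal.

The artery cross-section is meshed with a structured, polar-graded quad4
grid (hex8 after axial extrusion).  The VV network is a binary tree fractal
rooted on the outer wall and growing radially inward: a trunk of length L0
plus three branching levels whose branch angles carry a seeded uniform
jitter.  An occlusion splits the trunk at a given arclength; everything
distal of the split is flagged occluded and stops supplying nutrient.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .params import GeometryParams, VVTreeParams, ConfigError


class GeometryError(ValueError):
    """Raised for inconsistent geometric input (e.g. root off the wall)."""


class MeshError(ValueError):
    """Raised when a valid mesh cannot be produced."""


# ---------------------------------------------------------------------------
# VV tree
# ---------------------------------------------------------------------------

@dataclass
class VVTree:
    """Directed segment list; the root segment is the trunk (parent -1)."""

    start: np.ndarray        # (ns, 2) um
    end: np.ndarray          # (ns, 2) um
    level: np.ndarray        # (ns,) int, trunk = 1
    parent: np.ndarray       # (ns,) int, -1 for trunk
    occluded: np.ndarray     # (ns,) bool

    @property
    def n_segments(self) -> int:
        return len(self.level)

    def lengths(self) -> np.ndarray:
        return np.linalg.norm(self.end - self.start, axis=1)

    def children(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.parent == i)

    def descendants(self, i: int) -> list:
        out, stack = [], list(self.children(i))
        while stack:
            j = stack.pop()
            out.append(j)
            stack.extend(self.children(j))
        return out

    def copy(self) -> "VVTree":
        return VVTree(self.start.copy(), self.end.copy(), self.level.copy(),
                      self.parent.copy(), self.occluded.copy())


def _rot(vec: np.ndarray, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([c * vec[0] - s * vec[1], s * vec[0] + c * vec[1]])


def _clip_to_annulus(p0: np.ndarray, p1: np.ndarray, r_min: float,
                     center: np.ndarray) -> np.ndarray:
    """Shorten segment p0->p1 so it does not cross the circle r = r_min.

    The tree grows inward from the outer wall; r_min is the mid-wall radius
    past which segments are clipped.
    """
    d0 = np.linalg.norm(p0 - center)
    if d0 <= r_min:                       # already at the clip circle
        return p0.copy()
    e = p1 - p0
    a = float(e @ e)
    if a == 0.0:
        return p1.copy()
    b = 2.0 * float((p0 - center) @ e)
    c = float((p0 - center) @ (p0 - center)) - r_min * r_min
    disc = b * b - 4 * a * c
    if disc < 0:
        return p1.copy()
    t = (-b - math.sqrt(disc)) / (2 * a)
    if 0.0 <= t <= 1.0:
        return p0 + t * e
    return p1.copy()


def generate_vv_tree(params: VVTreeParams, root: np.ndarray,
                     direction: np.ndarray,
                     outer_radius: Optional[float] = None,
                     clip_radius: Optional[float] = None,
                     center=(0.0, 0.0)) -> VVTree:
    """Grow the seeded binary tree fractal from ``root`` along ``direction``.

    Level 1 is the trunk of length L0; at levels 2..4 each tip spawns two
    children of length lambda_k x parent length whose directions sit at
    +/- gamma_k/2 about the parent axis, each perturbed by a uniform angle
    in [-jitter, +jitter].  If ``outer_radius`` is given the root must lie
    on that circle; if ``clip_radius`` is given segments are clipped so the
    tree reaches at most that radius (mid-wall depth).
    """
    center = np.asarray(center, dtype=float)
    root = np.asarray(root, dtype=float)
    direction = np.asarray(direction, dtype=float)
    nrm = np.linalg.norm(direction)
    if nrm == 0:
        raise GeometryError("tree direction must be non-zero")
    direction = direction / nrm
    if outer_radius is not None:
        if abs(np.linalg.norm(root - center) - outer_radius) > 1e-6 * outer_radius:
            raise GeometryError("VV root does not lie on the outer wall")
        if (root - center) @ direction >= 0:
            raise GeometryError("VV trunk direction must point inward")

    rng = np.random.default_rng(params.seed)
    starts, ends, levels, parents = [], [], [], []

    def add(p0, p1, lev, par):
        starts.append(np.asarray(p0, float))
        ends.append(np.asarray(p1, float))
        levels.append(lev)
        parents.append(par)
        return len(starts) - 1

    tip0 = root + params.trunk_length * direction
    if clip_radius is not None:
        tip0 = _clip_to_annulus(root, tip0, clip_radius, center)
    trunk = add(root, tip0, 1, -1)

    frontier = [(trunk, direction, params.trunk_length)]
    for k, (lam, gamma) in enumerate(zip(params.length_ratios,
                                         params.branch_angles), start=2):
        new_frontier = []
        for idx, pdir, plen in frontier:
            tip = ends[idx]
            clen = lam * plen
            for sign in (+1.0, -1.0):
                ang = sign * gamma / 2.0
                if params.angle_jitter > 0:
                    ang += rng.uniform(-params.angle_jitter,
                                       params.angle_jitter)
                cdir = _rot(pdir, ang)
                p1 = tip + clen * cdir
                if clip_radius is not None:
                    p1 = _clip_to_annulus(tip, p1, clip_radius, center)
                child = add(tip, p1, k, idx)
                new_frontier.append((child, cdir, clen))
        frontier = new_frontier

    ns = len(starts)
    return VVTree(np.array(starts), np.array(ends),
                  np.array(levels, dtype=int), np.array(parents, dtype=int),
                  np.zeros(ns, dtype=bool))


def apply_occlusion(tree: VVTree, arclength: float) -> VVTree:
    """Split the trunk at ``arclength`` from its root; flag the distal part
    and every descendant as occluded.  S=0 occludes the whole tree; S equal
    to the trunk length occludes all descendants but not the trunk."""
    trunk = int(np.flatnonzero(tree.parent == -1)[0])
    L = float(np.linalg.norm(tree.end[trunk] - tree.start[trunk]))
    if arclength < -1e-12 or arclength > L + 1e-9:
        raise ConfigError("occlusion arclength outside the trunk")

    out = tree.copy()
    if arclength <= 1e-12:
        out.occluded[:] = True
        return out
    if arclength >= L - 1e-12:
        for j in out.descendants(trunk):
            out.occluded[j] = True
        return out

    u = (tree.end[trunk] - tree.start[trunk]) / L
    split = tree.start[trunk] + arclength * u
    # rebuild with the distal trunk piece inserted right after the trunk
    ns = tree.n_segments
    start = np.insert(tree.start, trunk + 1, split, axis=0)
    end = np.insert(tree.end, trunk + 1, tree.end[trunk], axis=0)
    end[trunk] = split
    level = np.insert(tree.level, trunk + 1, tree.level[trunk])
    shift = np.where(np.arange(ns) > trunk, 1, 0)
    parent_old = tree.parent.copy()
    parent = np.empty(ns + 1, dtype=int)
    distal = trunk + 1
    for i_old in range(ns):
        i_new = i_old + (1 if i_old > trunk else 0)
        p = parent_old[i_old]
        if i_old != trunk and p == trunk:
            parent[i_new] = distal          # reattach to distal piece
        elif p == -1:
            parent[i_new] = -1
        else:
            parent[i_new] = p + (1 if p > trunk else 0)
    parent[distal] = trunk
    occluded = np.zeros(ns + 1, dtype=bool)
    new = VVTree(start, end, level, parent, occluded)
    new.occluded[distal] = True
    for j in new.descendants(distal):
        new.occluded[j] = True
    return new


def occlusion_point(params: VVTreeParams, root, direction) -> np.ndarray:
    """Location of the occlusion on the trunk (nucleation site in the
    dissection scenario)."""
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    return np.asarray(root, float) + params.occlusion_arclength * d


def point_segment_distance(points: np.ndarray, p0: np.ndarray,
                           p1: np.ndarray) -> np.ndarray:
    """Distances from each point to the segment p0-p1 (vectorized)."""
    e = p1 - p0
    ee = float(e @ e)
    if ee == 0.0:
        return np.linalg.norm(points - p0, axis=1)
    t = np.clip((points - p0) @ e / ee, 0.0, 1.0)
    proj = p0 + t[:, None] * e
    return np.linalg.norm(points - proj, axis=1)


# ---------------------------------------------------------------------------
# Mesh
# ---------------------------------------------------------------------------

@dataclass
class Mesh:
    """Unstructured-grid container (quad4 in 2D, hex8 in 3D)."""

    coords: np.ndarray                 # (n_nodes, dim) um
    elems: np.ndarray                  # (n_elems, 4 or 8) int
    node_sets: dict = field(default_factory=dict)
    lumen_facets: np.ndarray = None    # (nf, 2) 2D / (nf, 4) 3D, oriented
    geom: Optional[GeometryParams] = None

    @property
    def dim(self) -> int:
        return self.coords.shape[1]

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    @property
    def n_elems(self) -> int:
        return self.elems.shape[0]


def _graded_arcs(total: float, fine_extent: float, h_fine: float,
                 h_coarse: float, growth: float = 1.3) -> np.ndarray:
    """1D grid from 0 to ``total``: spacing h_fine on [0, fine_extent],
    geometric transition to h_coarse beyond.  Returns node positions."""
    pts = [0.0]
    h = h_fine
    while pts[-1] + h < fine_extent - 1e-12:
        pts.append(pts[-1] + h)
    # transition + coarse region
    while pts[-1] < total - 1e-12:
        h = min(h * growth, h_coarse)
        pts.append(pts[-1] + h)
    pts = np.array(pts)
    if len(pts) < 2:
        pts = np.array([0.0, total])
    # rescale the part beyond the fine region so the grid ends exactly at total
    if pts[-1] != total:
        n_fine = int(np.searchsorted(pts, fine_extent - 1e-12))
        n_fine = min(n_fine, len(pts) - 2)
        anchor = pts[n_fine]
        scale = (total - anchor) / (pts[-1] - anchor)
        pts[n_fine + 1:] = anchor + (pts[n_fine + 1:] - anchor) * scale
    return pts


def build_annulus_mesh(geom: GeometryParams, dim: int = 2) -> Mesh:
    """Structured polar quad mesh of the annular sector.

    Radial spacing uses the fine target size (the lesion spans the wall
    thickness); the angular spacing is h_fine inside the refinement sector
    around theta = 0 and grades geometrically to h_coarse outside.  For
    ``dim == 3`` the quad mesh is extruded along z.
    """
    if geom.h_fine > geom.wall_thickness:
        raise MeshError("h_fine exceeds the wall thickness")
    r_in, r_out = geom.inner_radius, geom.outer_radius
    r_mid = 0.5 * (r_in + r_out)
    refined = geom.h_fine < geom.h_coarse

    h_r = geom.h_fine if refined else geom.h_coarse
    n_r = max(1, round(geom.wall_thickness / h_r))
    radii = np.linspace(r_in, r_out, n_r + 1)

    theta_max = geom.sector_half_angle
    full = abs(theta_max - math.pi) < 1e-12
    arc_total = theta_max * r_mid
    arc_fine = (geom.refine_center_angle * r_mid + geom.refine_arc_margin
                if refined else 0.0)
    arc_fine = min(arc_fine, arc_total)
    arcs = _graded_arcs(arc_total, arc_fine, geom.h_fine, geom.h_coarse)
    thetas_half = arcs / r_mid
    thetas = np.concatenate([-thetas_half[::-1], thetas_half[1:]])
    if full:
        thetas = thetas[:-1]            # wrap: last column == first

    n_t = len(thetas)
    n_cols = n_t if full else n_t - 1

    rr, tt = np.meshgrid(radii, thetas, indexing="ij")
    coords = np.column_stack([(rr * np.cos(tt)).ravel(),
                              (rr * np.sin(tt)).ravel()])

    def nid(i, j):
        return i * n_t + (j % n_t if full else j)

    elems = np.empty((n_r * n_cols, 4), dtype=int)
    k = 0
    for i in range(n_r):
        for j in range(n_cols):
            elems[k] = (nid(i, j), nid(i + 1, j),
                        nid(i + 1, j + 1), nid(i, j + 1))
            k += 1

    lumen = np.array([nid(0, j) for j in range(n_t)], dtype=int)
    outer = np.array([nid(n_r, j) for j in range(n_t)], dtype=int)
    if full:
        symmetry = np.array([], dtype=int)
    else:
        symmetry = np.array([nid(i, j) for i in range(n_r + 1)
                             for j in (0, n_t - 1)], dtype=int)
    facets = np.array([[nid(0, j), nid(0, j + 1)] for j in range(n_cols)],
                      dtype=int)

    mesh = Mesh(coords, elems,
                {"lumen": lumen, "outer": outer, "symmetry": symmetry,
                 "vv_supply": np.array([], dtype=int)},
                facets, geom)
    if dim == 3:
        mesh = extrude_mesh(mesh, geom.axial_length,
                            max(1, round(geom.axial_length / geom.h_coarse)))
    if np.min(element_jacobians(mesh)) <= 0:
        raise MeshError("non-positive element Jacobian")
    return mesh


def build_rect_mesh(nx: int, ny: int, lx: float, ly: float,
                    distort: float = 0.0, seed: int = 0) -> Mesh:
    """Axis-aligned quad mesh of [0,lx]x[0,ly]; optional interior-node
    distortion (fraction of the cell size) for patch tests."""
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    coords = np.column_stack([xx.ravel(), yy.ravel()])
    if distort > 0:
        rng = np.random.default_rng(seed)
        interior = ((coords[:, 0] > 1e-12) & (coords[:, 0] < lx - 1e-12) &
                    (coords[:, 1] > 1e-12) & (coords[:, 1] < ly - 1e-12))
        h = min(lx / nx, ly / ny)
        coords[interior] += rng.uniform(-distort, distort,
                                        (interior.sum(), 2)) * h

    def nid(i, j):
        return i * (ny + 1) + j

    elems = np.array([[nid(i, j), nid(i + 1, j), nid(i + 1, j + 1),
                       nid(i, j + 1)]
                      for i in range(nx) for j in range(ny)], dtype=int)
    left = np.array([nid(0, j) for j in range(ny + 1)])
    right = np.array([nid(nx, j) for j in range(ny + 1)])
    bottom = np.array([nid(i, 0) for i in range(nx + 1)])
    top = np.array([nid(i, ny) for i in range(nx + 1)])
    facets = np.array([[nid(0, j + 1), nid(0, j)] for j in range(ny)])
    return Mesh(coords, elems,
                {"lumen": left, "outer": right, "symmetry": np.array([], int),
                 "vv_supply": np.array([], int),
                 "bottom": bottom, "top": top},
                facets, None)


def extrude_mesh(mesh2d: Mesh, length: float, n_layers: int) -> Mesh:
    """Extrude a quad4 mesh along z into hex8 elements."""
    n2 = mesh2d.n_nodes
    zs = np.linspace(0.0, length, n_layers + 1)
    coords = np.vstack([np.column_stack([mesh2d.coords,
                                         np.full(n2, z)]) for z in zs])
    elems = []
    for layer in range(n_layers):
        lo, hi = layer * n2, (layer + 1) * n2
        for quad in mesh2d.elems:
            elems.append(np.concatenate([quad + lo, quad + hi]))
    elems = np.array(elems, dtype=int)
    sets = {}
    for name, nodes in mesh2d.node_sets.items():
        sets[name] = np.concatenate([nodes + layer * n2
                                     for layer in range(n_layers + 1)])
    facets = []
    for layer in range(n_layers):
        lo, hi = layer * n2, (layer + 1) * n2
        for (a, b) in mesh2d.lumen_facets:
            facets.append([a + lo, b + lo, b + hi, a + hi])
    return Mesh(coords, elems, sets, np.array(facets, dtype=int),
                mesh2d.geom)


def element_jacobians(mesh: Mesh) -> np.ndarray:
    """Determinant of the isoparametric Jacobian at every Gauss point."""
    from .weak_forms import shape_quadrature
    et = "quad4" if mesh.elems.shape[1] == 4 else "hex8"
    _, w, _, dN = shape_quadrature(et)
    X = mesh.coords[mesh.elems]                      # (ne, nen, dim)
    J0 = np.einsum("gnj,eni->egij", dN, X)
    return np.linalg.det(J0)


def mark_vv_supply_nodes(mesh: Mesh, tree: VVTree, tol: float) -> np.ndarray:
    """Nodes within ``tol`` of any non-occluded VV segment; stored on the
    mesh as set ``vv_supply``.  The supply set is how the (1D) VV network
    couples to the continuum: those nodes receive the maximum nutrient
    concentration as a Dirichlet condition."""
    pts = mesh.coords[:, :2]
    near = np.zeros(mesh.n_nodes, dtype=bool)
    for s in range(tree.n_segments):
        if tree.occluded[s]:
            continue
        d = point_segment_distance(pts, tree.start[s], tree.end[s])
        near |= d <= tol + 1e-12
    nodes = np.flatnonzero(near)
    mesh.node_sets["vv_supply"] = nodes
    return nodes


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

FIXTURE_GEOMS = {
    # desk-scale variants of the reference geometry; only the mesh sizes
    # differ from the full-resolution defaults
    "tiny": dict(h_coarse=100.0, h_fine=50.0, refine_arc_margin=40.0),
    "small": dict(h_coarse=60.0, h_fine=20.0, refine_arc_margin=40.0),
}


def make_fixture(level: str, seed: int = 0):
    """Deterministic miniature (mesh, tree) instances for tests.

    ``unit``: one quad element.  ``tiny``: ~2x10^2 elements.  ``small``:
    ~10^3 elements.  The tiny/small fixtures carry the reference geometry
    with coarser mesh sizes, the seeded VV tree and the trunk occlusion.
    """
    if level == "unit":
        mesh = build_rect_mesh(1, 1, 1.0, 1.0)
        tree = generate_vv_tree(
            VVTreeParams(trunk_length=0.25, occlusion_arclength=0.1,
                         angle_jitter=0.0, seed=seed),
            root=np.array([0.5, 1.0]), direction=np.array([0.0, -1.0]))
        tree = apply_occlusion(tree, 0.1)
        return mesh, tree
    if level not in FIXTURE_GEOMS:
        raise ConfigError(f"unknown fixture level {level!r}")
    geom = GeometryParams(**FIXTURE_GEOMS[level])
    # damage length scale tracks the mesh (l = 2 h_fine)
    mesh = build_annulus_mesh(geom, dim=2)
    vv = VVTreeParams(seed=seed)
    root = np.array([geom.outer_radius, 0.0])
    tree = generate_vv_tree(vv, root, np.array([-1.0, 0.0]),
                            outer_radius=geom.outer_radius,
                            clip_radius=geom.outer_radius
                            - 0.5 * geom.wall_thickness)
    tree = apply_occlusion(tree, vv.occlusion_arclength)
    mark_vv_supply_nodes(mesh, tree, tol=geom.h_fine)
    return mesh, tree


# ---------------------------------------------------------------------------
# Plain-text serialization
# ---------------------------------------------------------------------------

def write_tree_text(tree: VVTree, path) -> None:
    with open(path, "w") as fh:
        fh.write("# x1 y1 x2 y2 level parent occluded\n")
        for i in range(tree.n_segments):
            fh.write("%.17g %.17g %.17g %.17g %d %d %d\n" % (
                tree.start[i, 0], tree.start[i, 1],
                tree.end[i, 0], tree.end[i, 1],
                tree.level[i], tree.parent[i], int(tree.occluded[i])))


def read_tree_text(path) -> VVTree:
    rows = np.loadtxt(path, comments="#", ndmin=2)
    return VVTree(rows[:, 0:2].copy(), rows[:, 2:4].copy(),
                  rows[:, 4].astype(int), rows[:, 5].astype(int),
                  rows[:, 6].astype(bool))


def write_mesh_text(mesh: Mesh, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"dim {mesh.dim}\n")
        fh.write(f"nodes {mesh.n_nodes}\n")
        for row in mesh.coords:
            fh.write(" ".join("%.17g" % v for v in row) + "\n")
        fh.write(f"elements {mesh.n_elems} {mesh.elems.shape[1]}\n")
        for row in mesh.elems:
            fh.write(" ".join(str(v) for v in row) + "\n")
        for name, nodes in mesh.node_sets.items():
            fh.write(f"set {name} {len(nodes)}\n")
            fh.write(" ".join(str(v) for v in nodes) + "\n")
        nf = 0 if mesh.lumen_facets is None else len(mesh.lumen_facets)
        fh.write(f"facets lumen {nf}\n")
        if nf:
            for row in mesh.lumen_facets:
                fh.write(" ".join(str(v) for v in row) + "\n")


def read_mesh_text(path) -> Mesh:
    with open(path) as fh:
        tokens = fh.read().split("\n")
    it = iter(tokens)

    def next_line():
        line = next(it)
        while not line.strip():
            line = next(it)
        return line.split()

    hdr = next_line()
    assert hdr[0] == "dim"
    dim = int(hdr[1])
    n = int(next_line()[1])
    coords = np.array([[float(v) for v in next_line()] for _ in range(n)])
    hdr = next_line()
    ne, nen = int(hdr[1]), int(hdr[2])
    elems = np.array([[int(v) for v in next_line()] for _ in range(ne)])
    sets, facets = {}, None
    while True:
        try:
            hdr = next_line()
        except StopIteration:
            break
        if hdr[0] == "set":
            cnt = int(hdr[2])
            vals = next_line() if cnt else []
            sets[hdr[1]] = np.array([int(v) for v in vals], dtype=int)
        elif hdr[0] == "facets":
            cnt = int(hdr[2])
            facets = np.array([[int(v) for v in next_line()]
                               for _ in range(cnt)], dtype=int)
    assert coords.shape[1] == dim
    return Mesh(coords, elems, sets, facets, None)
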