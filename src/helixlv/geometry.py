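"""Idealized left-ventricular geometries and quadratic tetrahedral meshes.

The LV wall is modelled as the region between two confocal-offset half
ellipsoids: the endocardial surface with semi-axes (length, width/2, depth/2)
and the epicardial surface obtained by adding the wall thickness to every
semi-axis.  The base is the flat plane z = 0; the apex points toward
negative z; the apex-to-base (longitudinal) direction is +z.

Meshing is structured: a (circumferential x longitudinal x transmural) grid
of cells mapped onto the wall, each cell split into six tetrahedra by the
Freudenthal/Kuhn subdivision (globally conforming), degenerate apex cells
collapsed.  Midside nodes are generated in parameter space and mapped through
the exact surface parameterisation, so boundary faces are curved and cavity
volumes converge fast.

Printed fetal/adult dimensions (mm):

========== ============ ============ =====
shape      cavity len   basal width  wall
========== ============ ============ =====
symmetric       16.00        13.40    3.0
regular         18.75        15.40    3.0
hypertrophic    16.00        13.40    6.0
long            24.00        solved   3.0
hemisphere      solved       solved   3.0
wide             6.70   16.00/13.40   3.0
adult_regular   85.00        45.00    9.0
========== ============ ============ =====

"Long", "hemisphere" and "wide" are volume-matched to the symmetric
reference cavity (within 2%): the long shape keeps the 1.5x length and
solves its equatorial radius; the hemisphere solves its radius from
V = (2/3) pi r^3; the wide shape is the symmetric prolate ellipsoid cut
along an equatorial axis (so its cavity volume is identical by symmetry).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._tet import (
    TET10_EDGES,
    TET_FACES,
    map_gradients,
    tet4_signed_volume,
    tet10_shape,
    tet_quadrature,
    tri6_shape,
    tri_quadrature,
)

SYMMETRIC_CAVITY_LENGTH = 16.00  # mm
SYMMETRIC_BASAL_WIDTH = 13.40  # mm
FETAL_WALL_THICKNESS = 3.0  # mm

_SHAPES = (
    "regular",
    "symmetric",
    "hypertrophic",
    "long",
    "hemisphere",
    "wide",
    "adult_regular",
)


class GeometryError(ValueError):
    """Raised for infeasible or inconsistent geometry specifications."""


@dataclass(frozen=True)
class IdealizedGeometrySpec:
    """Dimensions of an idealized half-ellipsoidal LV.

    ``basal_cavity_width`` and ``basal_cavity_depth`` are the two equatorial
    cavity diameters at the base plane (equal for axisymmetric shapes).
    ``septal_lean_amplitude`` shears the apex sideways to emulate the
    straight-septum asymmetry of real fetal LVs; 0 gives a symmetric shape.
    """

    shape: str
    wall_thickness: float  # mm
    cavity_length: float  # mm
    basal_cavity_width: float  # mm
    basal_cavity_depth: float | None = None  # mm, defaults to width
    target_cavity_volume: float | None = None  # ml
    septal_lean_amplitude: float = 0.0  # mm

    def __post_init__(self):
        if self.shape not in _SHAPES:
            raise GeometryError(f"unknown shape {self.shape!r}; one of {_SHAPES}")
        for name in ("wall_thickness", "cavity_length", "basal_cavity_width"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        if self.basal_cavity_depth is not None and self.basal_cavity_depth <= 0:
            raise GeometryError("basal_cavity_depth must be positive")
        if self.wall_thickness >= self.basal_cavity_width / 2.0:
            raise GeometryError(
                "wall_thickness must be smaller than half the basal cavity width"
            )
        if self.shape == "hemisphere":
            r = self.basal_cavity_width / 2.0
            if abs(self.cavity_length - r) > 1e-9 * max(1.0, r):
                raise GeometryError(
                    "hemisphere requires cavity_length == basal_cavity_width/2"
                )

    @property
    def semi_axes(self) -> tuple[float, float, float]:
        """Endocardial semi-axes (a_z length, b_x, c_y) in mm."""
        depth = self.basal_cavity_depth or self.basal_cavity_width
        return (self.cavity_length, self.basal_cavity_width / 2.0, depth / 2.0)

    @property
    def cavity_volume(self) -> float:
        """Closed-form cavity volume of the half ellipsoid, in ml."""
        a, b, c = self.semi_axes
        return (2.0 / 3.0) * np.pi * a * b * c / 1000.0


def _symmetric_reference_volume() -> float:
    a = SYMMETRIC_CAVITY_LENGTH
    b = SYMMETRIC_BASAL_WIDTH / 2.0
    return (2.0 / 3.0) * np.pi * a * b * b / 1000.0  # ml


def fetal_geometry_spec(shape: str, septal_lean: float = 1.5) -> IdealizedGeometrySpec:
    """Build the printed-dimension spec for one of the idealized LV shapes.

    ``septal_lean`` (mm) only applies to the asymmetric ``regular`` shape;
    the quantitative lean of a real fetal LV is not standardized, so it is a
    caller-set parameter with a mild default.
    """
    v_ref = _symmetric_reference_volume()
    if shape == "symmetric":
        return IdealizedGeometrySpec(
            "symmetric", FETAL_WALL_THICKNESS, SYMMETRIC_CAVITY_LENGTH,
            SYMMETRIC_BASAL_WIDTH,
        )
    if shape == "regular":
        return IdealizedGeometrySpec(
            "regular", FETAL_WALL_THICKNESS, 18.75, 15.40,
            septal_lean_amplitude=septal_lean,
        )
    if shape == "hypertrophic":
        # doubled wall thickness, same cavity -> volume matched trivially
        return IdealizedGeometrySpec(
            "hypertrophic", 2 * FETAL_WALL_THICKNESS, SYMMETRIC_CAVITY_LENGTH,
            SYMMETRIC_BASAL_WIDTH, target_cavity_volume=v_ref,
        )
    if shape == "long":
        a = 1.5 * SYMMETRIC_CAVITY_LENGTH
        b = np.sqrt(3000.0 * v_ref / (2.0 * np.pi * a))
        if 2 * b <= 2 * FETAL_WALL_THICKNESS:
            raise GeometryError(
                "long shape cannot match the reference volume: solved basal "
                "width is below twice the wall thickness"
            )
        return IdealizedGeometrySpec(
            "long", FETAL_WALL_THICKNESS, a, 2 * b, target_cavity_volume=v_ref,
        )
    if shape == "hemisphere":
        r = (1.5 * 1000.0 * v_ref / np.pi) ** (1.0 / 3.0)
        return IdealizedGeometrySpec(
            "hemisphere", FETAL_WALL_THICKNESS, r, 2 * r, target_cavity_volume=v_ref,
        )
    if shape == "wide":
        # the symmetric prolate cut along an equatorial axis: cavity length
        # equals the small semi-axis, one basal diameter equals twice the
        # long semi-axis -> identical cavity volume by symmetry
        return IdealizedGeometrySpec(
            "wide", FETAL_WALL_THICKNESS, SYMMETRIC_BASAL_WIDTH / 2.0,
            2 * SYMMETRIC_CAVITY_LENGTH, basal_cavity_depth=SYMMETRIC_BASAL_WIDTH,
            target_cavity_volume=v_ref,
        )
    if shape == "adult_regular":
        return IdealizedGeometrySpec("adult_regular", 9.0, 85.0, 45.0)
    raise GeometryError(f"unknown shape {shape!r}")


VOLUME_MATCHED_FAMILY = ("symmetric", "hypertrophic", "long", "hemisphere", "wide")


@dataclass
class LVMesh:
    """Quadratic tetrahedral LV wall mesh with labelled boundary surfaces.

    Attributes
    ----------
    points : (n, 3) node coordinates in mm.
    cells : (m, 10) tet10 connectivity (Gmsh node ordering).
    facets : mapping label -> (k, 6) tri6 boundary faces; labels are
        "endo", "epi", "base".
    long_axis : apex-to-base unit vector (+z by construction).
    spec : the generating spec, if any.
    """

    points: np.ndarray
    cells: np.ndarray
    facets: dict[str, np.ndarray]
    long_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    spec: IdealizedGeometrySpec | None = None

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def n_cells(self) -> int:
        return self.cells.shape[0]

    @property
    def vertex_ids(self) -> np.ndarray:
        """Sorted unique ids of corner (vertex) nodes."""
        return np.unique(self.cells[:, :4])

    def copy(self) -> "LVMesh":
        return LVMesh(
            self.points.copy(),
            self.cells.copy(),
            {k: v.copy() for k, v in self.facets.items()},
            self.long_axis.copy(),
            self.spec,
        )

    def corner_coords(self) -> np.ndarray:
        return self.points[self.cells[:, :4]]

    def min_jacobian(self) -> float:
        """Minimum isoparametric Jacobian over quadrature points (mm^3)."""
        pts, _ = tet_quadrature(2)
        _, dN = tet10_shape(pts)
        _, detJ = map_gradients(self.points[self.cells], dN)
        return float(detJ.min())

    def wall_volume(self) -> float:
        """Myocardial wall volume in ml (quadrature over all elements)."""
        pts, w = tet_quadrature(3)
        _, dN = tet10_shape(pts)
        _, detJ = map_gradients(self.points[self.cells], dN)
        return float(np.einsum("eq,q->", detJ, w)) / 1000.0


def _ellipsoid_point(theta, v, e, endo_axes, wall):
    """Map parametric (theta, v, e) to cartesian mm; e=0 epi, e=1 endo."""
    a0, b0, c0 = endo_axes
    t = wall * (1.0 - e)
    a, b, c = a0 + t, b0 + t, c0 + t
    phi = v * (np.pi / 2.0)
    x = b * np.cos(theta) * np.cos(phi)
    y = c * np.sin(theta) * np.cos(phi)
    z = -a * np.sin(phi)
    return np.stack([x, y, z], axis=-1)


# Freudenthal/Kuhn subdivision of the unit cell: six tets sharing the main
# diagonal, one per coordinate ordering; globally conforming on a grid.
_KUHN_PERMS = (
    (0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0),
)


def _kuhn_tets():
    tets = []
    for perm in _KUHN_PERMS:
        verts = [np.zeros(3, dtype=int)]
        v = np.zeros(3, dtype=int)
        for axis in perm:
            v = v.copy()
            v[axis] = 1
            verts.append(v)
        tets.append(np.array(verts))
    return tets


_KUHN = _kuhn_tets()


def generate_idealized_lv(
    spec: IdealizedGeometrySpec,
    resolution: float | None = None,
    *,
    n_circ: int | None = None,
    n_long: int | None = None,
    n_trans: int | None = None,
    min_elements: int = 2500,
    enforce_min_elements: bool = True,
) -> LVMesh:
    """Generate a tet10 mesh of the idealized LV wall.

    ``resolution`` is a target element edge length in mm; the structured
    grid divisions are derived from it unless given explicitly.  The default
    sizing honours a minimum of 2500 quadratic tetrahedra; pass
    ``enforce_min_elements=False`` for deliberately coarse test meshes.
    """
    axes = spec.semi_axes
    wall = spec.wall_thickness

    if n_circ is None or n_long is None or n_trans is None:
        if resolution is None:
            resolution = _default_resolution(spec, min_elements)
        circum = np.pi * (axes[1] + axes[2] + wall)  # rough mid-wall girth
        arc = 0.5 * np.pi * (axes[0] + 0.5 * (axes[1] + axes[2]))
        n_circ = n_circ or max(8, int(np.ceil(circum / resolution)))
        n_long = n_long or max(3, int(np.ceil(arc / resolution)))
        n_trans = n_trans or max(1, int(np.ceil(wall / resolution)))

    mesh = _structured_half_ellipsoid(axes, wall, n_circ, n_long, n_trans)
    if enforce_min_elements and mesh.n_cells < min_elements:
        raise GeometryError(
            f"mesh has {mesh.n_cells} elements (< {min_elements}); refine the "
            "resolution or pass enforce_min_elements=False"
        )
    mesh.spec = spec

    if spec.septal_lean_amplitude:
        mesh = apply_septal_lean(mesh, spec.septal_lean_amplitude)
        mesh.spec = spec

    vol = compute_cavity_volume(mesh)
    # discretization check only guards production meshes; deliberately
    # coarse meshes (enforce_min_elements=False) may under-resolve the wall
    if enforce_min_elements and abs(vol - spec.cavity_volume) > (
        0.02 * spec.cavity_volume
    ):
        raise GeometryError(
            f"discretized cavity volume {vol:.4f} ml deviates from the "
            f"specified {spec.cavity_volume:.4f} ml by more than 2%"
        )
    if enforce_min_elements and spec.target_cavity_volume is not None:
        if abs(vol - spec.target_cavity_volume) > 0.02 * spec.target_cavity_volume:
            raise GeometryError(
                f"shape {spec.shape!r}: cavity volume {vol:.4f} ml misses the "
                f"matching target {spec.target_cavity_volume:.4f} ml by > 2%"
            )
    if mesh.min_jacobian() <= 0:
        raise GeometryError("mesh contains non-positive Jacobians")
    return mesh


def _default_resolution(spec: IdealizedGeometrySpec, min_elements: int) -> float:
    # ~36 tets per (res^3) cell block; solve for res from the wall volume
    a, b, c = spec.semi_axes
    t = spec.wall_thickness
    outer = (2.0 / 3.0) * np.pi * (a + t) * (b + t) * (c + t)
    wall_vol = outer - 1000.0 * spec.cavity_volume
    res = (6.0 * wall_vol / min_elements) ** (1.0 / 3.0)
    return min(res, t)


def _structured_half_ellipsoid(endo_axes, wall, n_circ, n_long, n_trans) -> LVMesh:
    NC, NL, NT = 2 * n_circ, 2 * n_long, 2 * n_trans  # doubled-index grid

    node_ids: dict[tuple[int, int, int], int] = {}
    node_keys: list[tuple[int, int, int]] = []

    def node(i: int, j: int, k: int) -> int:
        key = (0, j, k) if j == NL else (i % NC, j, k)
        idx = node_ids.get(key)
        if idx is None:
            idx = len(node_keys)
            node_ids[key] = idx
            node_keys.append(key)
        return idx

    cells = []
    for jc in range(n_long):
        for ic in range(n_circ):
            for kc in range(n_trans):
                base = np.array([2 * ic, 2 * jc, 2 * kc])
                for tet in _KUHN:
                    corners = base + 2 * tet  # (4, 3) doubled indices
                    vids = [node(*c) for c in corners]
                    if len(set(vids)) < 4:
                        continue  # degenerate apex tet
                    conn = list(vids)
                    for a, b in TET10_EDGES:
                        mid = (corners[a] + corners[b]) // 2
                        conn.append(node(*mid))
                    cells.append(conn)

    keys = np.array(node_keys, dtype=float)
    theta = keys[:, 0] * (np.pi / n_circ)
    v = keys[:, 1] / NL
    e = 1.0 - keys[:, 2] / NT  # k=0 at endo? choose k axis: k=0 -> endo
    # Convention: grid k runs endo (k=0) to epi (k=NT): e = 1 - k/NT
    points = _ellipsoid_point(theta, v, e, endo_axes, wall)
    cells = np.array(cells, dtype=np.int64)

    # fix orientation on corner vertices, then re-derive midside ordering
    p = points
    vol = tet4_signed_volume(
        p[cells[:, 0]], p[cells[:, 1]], p[cells[:, 2]], p[cells[:, 3]]
    )
    flip = vol < 0
    if np.any(flip):
        c = cells[flip]
        # swap vertices 1<->2 and the affected midside nodes:
        # edges (0,1)<->(2,0), (1,2) fixed endpoints swapped (same set),
        # (0,3) stays, (2,3)<->(1,3)
        c = c[:, [0, 2, 1, 3, 6, 5, 4, 7, 9, 8]]
        cells[flip] = c

    facets = _extract_facets(cells, keys, NL, NT)
    return LVMesh(points=points, cells=cells, facets=facets)


def _extract_facets(cells, keys, NL, NT):
    """Boundary tri6 faces classified by the parametric grid coordinates."""
    from collections import defaultdict

    face_count: dict[tuple, list] = defaultdict(list)
    for ei, conn in enumerate(cells):
        for fi, (a, b, c, _) in enumerate(TET_FACES):
            tri = (conn[a], conn[b], conn[c])
            face_count[tuple(sorted(tri))].append((ei, fi))

    edge_lookup = {frozenset(e): 4 + m for m, e in enumerate(TET10_EDGES)}
    facets = {"endo": [], "epi": [], "base": []}
    for key, owners in face_count.items():
        if len(owners) != 1:
            continue
        ei, fi = owners[0]
        conn = cells[ei]
        a, b, c, _ = TET_FACES[fi]
        verts = [conn[a], conn[b], conn[c]]
        mids = [
            conn[edge_lookup[frozenset((x, y))]]
            for x, y in ((a, b), (b, c), (c, a))
        ]
        tri6 = verts + mids
        k = keys[np.array(tri6)]
        if np.all(k[:, 2] == 0):
            facets["endo"].append(tri6)
        elif np.all(k[:, 2] == NT):
            facets["epi"].append(tri6)
        elif np.all(k[:, 1] == 0):
            facets["base"].append(tri6)
        else:  # pragma: no cover - structured mesh should never hit this
            raise GeometryError("unclassifiable boundary face")
    return {k: np.array(v, dtype=np.int64) for k, v in facets.items()}


def apply_septal_lean(mesh: LVMesh, lean: float) -> LVMesh:
    """Shear the apex sideways by ``lean`` mm (volume-preserving).

    The displacement is x += lean * (z / z_apex)^2, a pure shear in x as a
    function of z only, so det(grad) = 1 exactly and labels are untouched.
    """
    out = mesh.copy()
    z = out.points[:, 2]
    z_apex = z.min()
    if z_apex >= 0:
        raise GeometryError("mesh has no apexward extent below the base plane")
    out.points[:, 0] += lean * (z / z_apex) ** 2
    if lean != 0.0 and out.min_jacobian() <= 0:
        raise GeometryError("septal lean inverted elements; reduce the amplitude")
    return out


def compute_cavity_volume(mesh: LVMesh, displacement: np.ndarray | None = None) -> float:
    """Cavity volume in ml via the divergence theorem.

    Integrates x.n/3 over the (possibly displaced) endocardial surface plus
    the flat basal cap; the cap lies in z = 0 where x.n vanishes, so only
    the endocardial faces contribute.  Faces are oriented out of the wall
    (into the cavity), hence the sign flip.
    """
    if "endo" not in mesh.facets or len(mesh.facets["endo"]) == 0:
        raise GeometryError("mesh lacks an endocardial surface")
    x = mesh.points if displacement is None else mesh.points + displacement
    faces = mesh.facets["endo"]

    ring = _endo_ring_max_abs_z(mesh, x)
    if ring > 1e-6 * np.ptp(x[:, 2]):
        raise GeometryError(
            "endocardial surface is not closed against the base plane "
            f"(free boundary reaches |z| = {ring:.3g} mm)"
        )

    qp, qw = tri_quadrature(4)
    N, dN = tri6_shape(qp)
    coords = x[faces]  # (f, 6, 3)
    xq = np.einsum("qn,fnd->fqd", N, coords)
    t1 = np.einsum("qn,fnd->fqd", dN[:, :, 0], coords)
    t2 = np.einsum("qn,fnd->fqd", dN[:, :, 1], coords)
    n = np.cross(t1, t2)  # right-hand normal of tri ordering (out of wall)
    integrand = np.einsum("fqd,fqd->fq", xq, n)
    vol = -np.einsum("fq,q->", integrand, qw) / 3.0  # flip: cavity outward
    if vol <= 0:
        raise GeometryError(f"non-positive cavity volume ({vol:.3g} mm^3)")
    return float(vol) / 1000.0


def _endo_ring_max_abs_z(mesh: LVMesh, x: np.ndarray) -> float:
    """Max |z| over the free boundary edges of the endocardial surface."""
    from collections import Counter

    edges = Counter()
    for f in mesh.facets["endo"]:
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            edges[frozenset((int(a), int(b)))] += 1
    ring_nodes = set()
    for e, cnt in edges.items():
        if cnt == 1:
            ring_nodes.update(e)
    if not ring_nodes:
        return np.inf  # closed surface with no basal ring: unexpected
    return float(np.abs(x[list(ring_nodes), 2]).max())


def generate_volume_matched_family(
    resolution: float | None = None, **mesh_kwargs
) -> dict[str, LVMesh]:
    """Generate the five volume-matched fetal shapes; assert <= 2% spread."""
    meshes = {
        s: generate_idealized_lv(fetal_geometry_spec(s), resolution, **mesh_kwargs)
        for s in VOLUME_MATCHED_FAMILY
    }
    vols = np.array([compute_cavity_volume(m) for m in meshes.values()])
    spread = cavity_volume_spread(vols)
    if spread > 2.0:
        raise GeometryError(
            f"volume-matched family spread {spread:.2f}% exceeds 2%"
        )
    return meshes


def cavity_volume_spread(volumes) -> float:
    """Maximum pairwise relative difference in percent."""
    v = np.asarray(list(volumes), dtype=float)
    return float((v.max() - v.min()) / v.min() * 100.0)
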