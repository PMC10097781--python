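"""Transmural coordinate, local wall frames, and helix-angle fiber fields.

The transmural coordinate e is the harmonic (Laplace) field with e = 0 on
the epicardium and e = 1 on the endocardium — the standard rule-based
(Laplace–Dirichlet) construction for ventricular fiber architecture.  The
helix angle varies linearly across the wall:

    alpha(e) = tau_bar + (e - 1/2) * tau_diff

so the epicardial (e=0) and endocardial (e=1) angles are
tau_bar -/+ tau_diff/2.  Fibers lie in the local wall-tangent plane
(circumferential, longitudinal); the transverse angle is fixed at zero.
Positive helix angles rotate from circumferential toward the apex-to-base
direction, giving right-handed endocardial fibers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ._tet import map_gradients, tet10_shape, tet_quadrature
from .geometry import LVMesh

HELIX_SWEEP_RANGE = (-90.0, 180.0)  # degrees, the studied configuration range


@dataclass(frozen=True)
class HelixConfig:
    """A (tau_bar, tau_diff) helix-angle configuration in degrees."""

    tau_bar: float
    tau_diff: float

    def __post_init__(self):
        if not (np.isfinite(self.tau_bar) and np.isfinite(self.tau_diff)):
            raise ValueError("helix angles must be finite")
        lo, hi = HELIX_SWEEP_RANGE
        for name, v in (("tau_bar", self.tau_bar), ("tau_diff", self.tau_diff)):
            if not lo <= v <= hi:
                warnings.warn(
                    f"{name} = {v:g} deg lies outside the swept range "
                    f"[{lo:g}, {hi:g}] deg",
                    stacklevel=3,
                )

    @property
    def endo_angle(self) -> float:
        return self.tau_bar + 0.5 * self.tau_diff

    @property
    def epi_angle(self) -> float:
        return self.tau_bar - 0.5 * self.tau_diff

    def angle_at(self, e) -> np.ndarray:
        """Helix angle (deg) at transmural coordinate e (0 epi, 1 endo)."""
        return self.tau_bar + (np.asarray(e) - 0.5) * self.tau_diff

    def inverted(self) -> "HelixConfig":
        """Endocardial-to-epicardial inversion of the transmural profile."""
        return HelixConfig(self.tau_bar, -self.tau_diff)


@dataclass
class LocalFrame:
    """Orthonormal (c, l, t) triads at element quadrature points.

    c circumferential, l longitudinal (apex-to-base), t transmural
    (endo-to-epi outward); arrays of shape (n_el, n_qp, 3), with c = l x t.
    """

    c: np.ndarray
    l: np.ndarray
    t: np.ndarray


@dataclass
class FiberField:
    """Fiber (f), sheet (s) and sheet-normal (n) unit vectors per point.

    ``alpha_deg`` is the local helix angle and ``e`` the transmural
    coordinate at the same (n_el, n_qp) points.
    """

    f: np.ndarray
    s: np.ndarray
    n: np.ndarray
    alpha_deg: np.ndarray
    e: np.ndarray
    config: HelixConfig | None = None
    frames: "LocalFrame | None" = None


def _p2_stiffness(mesh: LVMesh, qdeg: int = 2) -> sp.csr_matrix:
    pts, w = tet_quadrature(qdeg)
    _, dN = tet10_shape(pts)
    coords = mesh.points[mesh.cells]
    dNx, detJ = map_gradients(coords, dN)
    ke = np.einsum("eqad,eqbd,eq,q->eab", dNx, dNx, detJ, w)
    n = 10
    rows = np.repeat(mesh.cells, n, axis=1).ravel()
    cols = np.tile(mesh.cells, (1, n)).ravel()
    return sp.csr_matrix(
        (ke.ravel(), (rows, cols)), shape=(mesh.n_points, mesh.n_points)
    )


def solve_laplace(mesh: LVMesh, boundary_values: dict[str, float]) -> np.ndarray:
    """Solve Laplace's equation with Dirichlet data on labelled surfaces."""
    for label in boundary_values:
        if label not in mesh.facets or len(mesh.facets[label]) == 0:
            raise ValueError(f"mesh lacks boundary surface {label!r}")
    K = _p2_stiffness(mesh)
    u = np.zeros(mesh.n_points)
    fixed = np.zeros(mesh.n_points, dtype=bool)
    for label, value in boundary_values.items():
        ids = np.unique(mesh.facets[label])
        u[ids] = value
        fixed[ids] = True
    free = ~fixed
    rhs = -K[free][:, fixed] @ u[fixed]
    u[free] = spla.spsolve(K[free][:, free].tocsc(), rhs)
    return u


def solve_transmural_coordinate(mesh: LVMesh) -> np.ndarray:
    """Nodal transmural coordinate: harmonic, 0 on epi, 1 on endo."""
    e = solve_laplace(mesh, {"epi": 0.0, "endo": 1.0})
    # the discrete maximum principle can be violated by ~1e-3 on coarse
    # quadratic meshes; clip hard outliers but fail on gross violations
    if e.min() < -0.05 or e.max() > 1.05:
        raise RuntimeError(
            f"transmural field badly violates [0,1]: [{e.min():.3f}, {e.max():.3f}]"
        )
    return np.clip(e, 0.0, 1.0)


def interpolate_at_qp(mesh: LVMesh, nodal: np.ndarray, qdeg: int = 2):
    """Values and physical gradients of a nodal field at quadrature points."""
    pts, _ = tet_quadrature(qdeg)
    N, dN = tet10_shape(pts)
    en = nodal[mesh.cells]  # (e, 10)
    vals = np.einsum("qn,en->eq", N, en)
    dNx, _ = map_gradients(mesh.points[mesh.cells], dN)
    grads = np.einsum("en,eqnd->eqd", en, dNx)
    return vals, grads


def quadrature_point_coords(mesh: LVMesh, qdeg: int = 2) -> np.ndarray:
    pts, _ = tet_quadrature(qdeg)
    N, _ = tet10_shape(pts)
    return np.einsum("qn,end->eqd", N, mesh.points[mesh.cells])


def build_local_frames(
    mesh: LVMesh,
    e_nodal: np.ndarray,
    qdeg: int = 2,
    apex_cap_fraction: float = 0.02,
    orthotol: float = 1e-8,
) -> LocalFrame:
    """Construct (c, l, t) triads from the transmural field gradient.

    t is the normalized transmural-gradient direction flipped endo-to-epi;
    l is the projection of the apex-to-base axis onto the plane orthogonal
    to t; c = l x t.  Quadrature points where the projection degenerates
    (the apex cap) inherit the triad of the nearest regular point.
    """
    _, grads = interpolate_at_qp(mesh, e_nodal, qdeg)
    gnorm = np.linalg.norm(grads, axis=-1)
    xq = quadrature_point_coords(mesh, qdeg)

    z = mesh.long_axis / np.linalg.norm(mesh.long_axis)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = -grads / gnorm[..., None]  # e grows epi->endo; flip to endo->epi
    lproj = z[None, None, :] - t * np.einsum("eqd,d->eq", t, z)[..., None]
    lnorm = np.linalg.norm(lproj, axis=-1)

    cavity_length = float(np.ptp(mesh.points[:, 2]))
    apex = mesh.points[np.argmin(mesh.points @ z)]
    dist_apex = np.linalg.norm(xq - apex, axis=-1)
    cap = apex_cap_fraction * cavity_length

    regular = (gnorm > 1e-10) & (lnorm > 1e-6)
    degenerate = ~regular | (dist_apex < cap)
    if not np.any(~degenerate):
        raise RuntimeError("no regular quadrature points outside the apex cap")
    n_bad_outside = np.count_nonzero(~regular & (dist_apex >= cap))
    if n_bad_outside > 0.01 * regular.size:
        raise RuntimeError(
            f"{n_bad_outside} degenerate frame points outside the declared "
            "apex cap — transmural field gradient vanishes over a region"
        )

    with np.errstate(invalid="ignore", divide="ignore"):
        l = lproj / lnorm[..., None]
    c = np.cross(l, t)

    if np.any(degenerate):
        from scipy.spatial import cKDTree

        good = ~degenerate
        tree = cKDTree(xq[good])
        _, idx = tree.query(xq[degenerate])
        for arr in (c, l, t):
            arr[degenerate] = arr[good][idx]

    frame = LocalFrame(c=c, l=l, t=t)
    _check_orthonormal(frame, orthotol)
    return frame


def _check_orthonormal(frame: LocalFrame, tol: float):
    for v in (frame.c, frame.l, frame.t):
        err = np.abs(np.linalg.norm(v, axis=-1) - 1.0).max()
        if err > tol:
            raise RuntimeError(f"frame vectors not unit to {tol:g} (err {err:.2e})")
    for a, b in ((frame.c, frame.l), (frame.c, frame.t), (frame.l, frame.t)):
        err = np.abs(np.einsum("...d,...d->...", a, b)).max()
        if err > tol:
            raise RuntimeError(f"frame vectors not orthogonal to {tol:g}")


def assign_helix_field(
    mesh: LVMesh,
    frames: LocalFrame,
    e_qp: np.ndarray,
    config: HelixConfig,
) -> FiberField:
    """Assign the linear transmural helix fiber field at quadrature points.

    f = cos(alpha) c + sin(alpha) l lies in the wall-tangent plane;
    the sheet direction s is transmural and n = f x s completes the triad.
    """
    alpha = config.angle_at(e_qp)
    ar = np.deg2rad(alpha)
    f = np.cos(ar)[..., None] * frames.c + np.sin(ar)[..., None] * frames.l
    s = frames.t.copy()
    n = np.cross(f, s)
    return FiberField(f=f, s=s, n=n, alpha_deg=alpha, e=e_qp.copy(), config=config)


def make_fiber_field(
    mesh: LVMesh, config: HelixConfig, qdeg: int = 2
) -> tuple[FiberField, LocalFrame, np.ndarray]:
    """Convenience pipeline: transmural solve -> frames -> helix field."""
    e_nodal = solve_transmural_coordinate(mesh)
    frames = build_local_frames(mesh, e_nodal, qdeg)
    e_qp, _ = interpolate_at_qp(mesh, e_nodal, qdeg)
    e_qp = np.clip(e_qp, 0.0, 1.0)
    field = assign_helix_field(mesh, frames, e_qp, config)
    field.frames = frames
    return field, frames, e_nodal
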