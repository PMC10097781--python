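"""Quadratic tetrahedral (tet10) and quadratic triangular (tri6) element kernels.

Node ordering follows the Gmsh convention:

* tet10 — vertices 0..3 then mid-edge nodes on edges
  (0,1), (1,2), (2,0), (0,3), (2,3), (1,3);
* tri6  — vertices 0..2 then mid-edge nodes on edges (0,1), (1,2), (2,0).

Shape functions are expressed in barycentric coordinates; all routines are
vectorised over (element, quadrature point) axes.
"""

from __future__ import annotations

import numpy as np

# Mid-edge node -> (vertex, vertex), Gmsh ordering.
TET10_EDGES = ((0, 1), (1, 2), (2, 0), (0, 3), (2, 3), (1, 3))
TRI6_EDGES = ((0, 1), (1, 2), (2, 0))

# The four faces of a tetrahedron as (v0, v1, v2, opposite vertex),
# ordered so the right-hand normal points OUT of a positively oriented tet.
TET_FACES = ((0, 2, 1, 3), (0, 1, 3, 2), (1, 2, 3, 0), (0, 3, 2, 1))


def tet10_shape(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Shape functions and reference gradients at reference points.

    Parameters
    ----------
    points : (q, 3) array of (xi, eta, zeta) reference coordinates.

    Returns
    -------
    N : (q, 10) shape function values.
    dN : (q, 10, 3) gradients with respect to (xi, eta, zeta).
    """
    pts = np.asarray(points, dtype=float)
    xi, eta, zeta = pts[:, 0], pts[:, 1], pts[:, 2]
    lam = np.stack([1.0 - xi - eta - zeta, xi, eta, zeta], axis=-1)  # (q, 4)
    dlam = np.array(
        [[-1.0, -1.0, -1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )  # (4, 3)

    q = pts.shape[0]
    N = np.empty((q, 10))
    dN = np.empty((q, 10, 3))
    for a in range(4):
        N[:, a] = lam[:, a] * (2.0 * lam[:, a] - 1.0)
        dN[:, a, :] = (4.0 * lam[:, a, None] - 1.0) * dlam[a]
    for m, (a, b) in enumerate(TET10_EDGES):
        N[:, 4 + m] = 4.0 * lam[:, a] * lam[:, b]
        dN[:, 4 + m, :] = 4.0 * (lam[:, a, None] * dlam[b] + lam[:, b, None] * dlam[a])
    return N, dN


def tri6_shape(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """tri6 shape functions/gradients at reference (xi, eta) points."""
    pts = np.asarray(points, dtype=float)
    xi, eta = pts[:, 0], pts[:, 1]
    lam = np.stack([1.0 - xi - eta, xi, eta], axis=-1)
    dlam = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])

    q = pts.shape[0]
    N = np.empty((q, 6))
    dN = np.empty((q, 6, 2))
    for a in range(3):
        N[:, a] = lam[:, a] * (2.0 * lam[:, a] - 1.0)
        dN[:, a, :] = (4.0 * lam[:, a, None] - 1.0) * dlam[a]
    for m, (a, b) in enumerate(TRI6_EDGES):
        N[:, 3 + m] = 4.0 * lam[:, a] * lam[:, b]
        dN[:, 3 + m, :] = 4.0 * (lam[:, a, None] * dlam[b] + lam[:, b, None] * dlam[a])
    return N, dN


def tet_quadrature(degree: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric Gauss rules on the reference tetrahedron (volume 1/6).

    degree 2 -> 4 points (positive weights), degree 3 -> 5 points,
    degree 5 -> 14 points (positive weights).
    """
    if degree <= 2:
        a, b = 0.5854101966249685, 0.1381966011250105
        pts = np.array(
            [[b, b, b], [a, b, b], [b, a, b], [b, b, a]]
        )
        w = np.full(4, 1.0 / 24.0)
    elif degree == 3:
        pts = np.array(
            [
                [0.25, 0.25, 0.25],
                [0.5, 1 / 6, 1 / 6],
                [1 / 6, 0.5, 1 / 6],
                [1 / 6, 1 / 6, 0.5],
                [1 / 6, 1 / 6, 1 / 6],
            ]
        )
        w = np.array([-2.0 / 15.0, 3.0 / 40.0, 3.0 / 40.0, 3.0 / 40.0, 3.0 / 40.0])
    else:
        # 14-point degree-5 rule (Grundmann–Möller family, positive weights).
        a1, w1 = 0.0673422422100983, 0.1126879257180162 / 6.0
        a2, w2 = 0.4544962958743503, 0.0425460207770812 / 6.0
        a3, w3 = 0.3108859192633005, 0.0734930431163619 / 6.0
        pts, w = [], []
        b1 = (1.0 - a1) / 3.0
        for i in range(4):
            p = [b1] * 4
            p[i] = a1
            pts.append(p[1:])
            w.append(w1)
        b3 = (1.0 - a3) / 3.0
        for i in range(4):
            p = [b3] * 4
            p[i] = a3
            pts.append(p[1:])
            w.append(w3)
        # six edge-midpoint-type points: two coordinates a2, two (0.5-a2)
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for i, j in pairs:
            p = [0.5 - a2] * 4
            p[i] = a2
            p[j] = a2
            pts.append(p[1:])
            w.append(w2)
        pts = np.array(pts)
        w = np.array(w)
        # note: barycentric l0 is implied; pts stores (l1, l2, l3)
        return pts, w
    return pts, w


def tri_quadrature(degree: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Dunavant rules on the reference triangle (area 1/2)."""
    if degree <= 2:
        pts = np.array([[1 / 6, 1 / 6], [2 / 3, 1 / 6], [1 / 6, 2 / 3]])
        w = np.full(3, 1.0 / 6.0)
    else:
        a = 0.445948490915965
        b = 0.091576213509771
        wa = 0.223381589678011 / 2.0
        wb = 0.109951743655322 / 2.0
        pts = np.array(
            [
                [a, a],
                [1 - 2 * a, a],
                [a, 1 - 2 * a],
                [b, b],
                [1 - 2 * b, b],
                [b, 1 - 2 * b],
            ]
        )
        w = np.array([wa, wa, wa, wb, wb, wb])
    return pts, w


def map_gradients(
    coords: np.ndarray, dN: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Isoparametric mapping of reference gradients to physical gradients.

    Parameters
    ----------
    coords : (n_el, 10, 3) nodal coordinates per element.
    dN : (q, 10, 3) reference gradients.

    Returns
    -------
    dN_phys : (n_el, q, 10, 3) physical gradients.
    detJ : (n_el, q) Jacobian determinants.
    """
    # J[e, q, i, j] = d x_i / d xi_j
    J = np.einsum("enk,qnj->eqkj", coords, dN)
    detJ = np.linalg.det(J)
    Jinv = np.linalg.inv(J)
    dN_phys = np.einsum("qnj,eqjk->eqnk", dN, Jinv)
    return dN_phys, detJ


def tet4_signed_volume(p0, p1, p2, p3) -> np.ndarray:
    """Signed volume of the linear tetrahedra spanned by vertex arrays."""
    return np.einsum(
        "...i,...i->...", np.cross(p1 - p0, p2 - p0), p3 - p0
    ) / 6.0
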