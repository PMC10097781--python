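"""Quasi-static finite-element mechanics of the LV wall.

Two-field total-Lagrangian formulation: quadratic (P2) displacements and a
linear (P1) hydrostatic-pressure multiplier enforcing incompressibility
(Taylor–Hood pair), with the Fung passive law and active fiber tension
added as P_act f0 x f0 in the second Piola–Kirchhoff stress.  The cavity
pressure is the Lagrange multiplier of a cavity-volume constraint, so
"inflate to volume" solves pressure and displacement together; the cavity
volume and its exact gradient/Hessian are evaluated by the divergence
theorem over the deformed endocardial surface.

Boundary conditions: longitudinal displacement fixed on the base plane
(in-plane motion free) and a weak epicardial spring representing the
surrounding tissue, which also removes the remaining rigid modes.

Units: mm, kPa, ms; cavity pressures cross the API in mmHg
(1 mmHg = 0.133322 kPa); cavity volumes in ml.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ._tet import (
    map_gradients,
    tet10_shape,
    tet_quadrature,
    tri6_shape,
    tri_quadrature,
)
from . import constitutive as law
from .constitutive import ActiveParams, PassiveParams
from .fibers import FiberField
from .geometry import LVMesh

MMHG_TO_KPA = 0.133322
KPA_TO_MMHG = 1.0 / MMHG_TO_KPA

_EPS3 = np.zeros((3, 3, 3))
for _i, _j, _k in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
    _EPS3[_i, _j, _k] = 1.0
    _EPS3[_i, _k, _j] = -1.0


class NewtonError(RuntimeError):
    """Newton iteration failure; carries the residual history."""

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = list(residuals or [])


@dataclass
class SolverConfig:
    steps_per_cycle: int = 50
    newton_tol: float = 1e-8  # relative residual
    newton_abs_tol: float = 1e-10
    newton_maxit: int = 25
    max_substeps: int = 32  # adaptive load sub-stepping
    epicardial_spring: float = 0.05  # kPa/mm
    bulk_penalty: float = 500.0  # kPa, augments the multiplier field
    quadrature_degree: int = 2
    use_load_stiffness: bool = True
    incompressibility_tol: float = 0.01  # |J-1| allowed at accepted steps

    def __post_init__(self):
        if self.newton_tol <= 0 or self.newton_abs_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.steps_per_cycle < 20:
            raise ValueError("steps_per_cycle must be at least 20")


@dataclass
class CardiacState:
    """Solution snapshot: nodal displacement, multiplier field, scalars."""

    u: np.ndarray  # (n_points, 3) mm
    p_mult: np.ndarray  # (n_vertices,) kPa
    cavity_pressure: float  # mmHg
    cavity_volume: float  # ml
    time: float  # ms within cycle
    activation_time: float  # ms within activation cycle


@dataclass
class PVLoop:
    time_ms: np.ndarray
    pressure_mmhg: np.ndarray
    volume_ml: np.ndarray

    @property
    def stroke_volume(self) -> float:
        return float(self.volume_ml.max() - self.volume_ml.min())


@dataclass
class UnloadedState:
    points: np.ndarray  # zero-pressure node coordinates (mm)
    pressure_residual: float  # mmHg, EDP round-trip mismatch
    volume_residual: float  # relative cavity-volume round-trip error
    nodal_rms: float  # mm, round-trip nodal RMS error
    iterations: int


class LVSolver:
    """Assembles and solves the mixed displacement/pressure system."""

    def __init__(
        self,
        mesh: LVMesh,
        fibers: FiberField,
        passive: PassiveParams,
        active: ActiveParams | None = None,
        config: SolverConfig | None = None,
    ):
        self.mesh = mesh
        self.fibers = fibers
        self.passive = passive
        self.active = active
        self.cfg = config or SolverConfig()

        qpts, qw = tet_quadrature(self.cfg.quadrature_degree)
        self.qw = qw
        N, dN = tet10_shape(qpts)
        self.N = N
        coords = mesh.points[mesh.cells]
        self.dNx, self.detJ0 = map_gradients(coords, dN)
        if self.detJ0.min() <= 0:
            raise ValueError("mesh has non-positive Jacobians")
        # P1 pressure shape values at the quadrature points
        xi = qpts
        self.Np = np.stack(
            [1 - xi[:, 0] - xi[:, 1] - xi[:, 2], xi[:, 0], xi[:, 1], xi[:, 2]],
            axis=1,
        )  # (q, 4)

        # fiber-frame rotation R rows (f, s, n): (e, q, 3, 3)
        self.R = np.stack([fibers.f, fibers.s, fibers.n], axis=-2)
        self.f0 = fibers.f

        n = mesh.n_points
        self.n_u = 3 * n
        self.vertices = mesh.vertex_ids
        self.n_p = len(self.vertices)
        vmap = -np.ones(n, dtype=np.int64)
        vmap[self.vertices] = np.arange(self.n_p)
        self.cell_pdof = vmap[mesh.cells[:, :4]]  # (e, 4)

        self._build_dof_indices()
        self._build_boundary()
        self._endo_setup()

        self.u = np.zeros((n, 3))
        self.p_mult = np.zeros(self.n_p)
        self.p_cav = 0.0  # kPa

    # ------------------------------------------------------------------ setup

    def _build_dof_indices(self):
        cells = self.mesh.cells
        udof = (3 * cells[:, :, None] + np.arange(3)).reshape(len(cells), 30)
        self.udof = udof
        self.rows_uu = np.repeat(udof, 30, axis=1).ravel()
        self.cols_uu = np.tile(udof, (1, 30)).ravel()
        pdof = self.n_u + self.cell_pdof
        self.rows_up = np.repeat(udof, 4, axis=1).ravel()
        self.cols_up = np.tile(pdof, (1, 30)).ravel()

    def _build_boundary(self):
        mesh = self.mesh
        base_nodes = np.unique(mesh.facets["base"])
        fixed = np.zeros(self.n_u + self.n_p, dtype=bool)
        fixed[3 * base_nodes + 2] = True  # longitudinal (z) fixed at base
        self.free = ~fixed

        # epicardial spring: tri6 surface mass matrix, one block per component
        faces = mesh.facets["epi"]
        qp, qw = tri_quadrature(4)
        N, dN = tri6_shape(qp)
        coords = mesh.points[faces]
        t1 = np.einsum("qn,fnd->fqd", dN[:, :, 0], coords)
        t2 = np.einsum("qn,fnd->fqd", dN[:, :, 1], coords)
        dA = np.linalg.norm(np.cross(t1, t2), axis=-1)  # (f, q)
        me = np.einsum("qa,qb,fq,q->fab", N, N, dA, qw)  # (f, 6, 6)
        k = self.cfg.epicardial_spring
        rows, cols, vals = [], [], []
        for c in range(3):
            fd = 3 * faces + c
            rows.append(np.repeat(fd, 6, axis=1).ravel())
            cols.append(np.tile(fd, (1, 6)).ravel())
            vals.append(k * me.ravel())
        self.K_spring = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n_u + self.n_p, self.n_u + self.n_p),
        )

    def _endo_setup(self):
        faces = self.mesh.facets["endo"]
        qp, qw = tri_quadrature(4)
        N, dN = tri6_shape(qp)
        self.endo_faces = faces
        self.endo_N = N  # (q, 6)
        self.endo_D1 = dN[:, :, 0]
        self.endo_D2 = dN[:, :, 1]
        self.endo_qw = qw
        fdof = (3 * faces[:, :, None] + np.arange(3)).reshape(len(faces), 18)
        self.endo_fdof = fdof
        self.endo_rows = np.repeat(fdof, 18, axis=1).ravel()
        self.endo_cols = np.tile(fdof, (1, 18)).ravel()

    # ------------------------------------------------------- cavity geometry

    def _endo_coords(self, u):
        return (self.mesh.points + u)[self.endo_faces]  # (f, 6, 3)

    def cavity_volume(self, u=None) -> float:
        """Deformed cavity volume in ml."""
        x = self._endo_coords(self.u if u is None else u)
        xq = np.einsum("qn,fnd->fqd", self.endo_N, x)
        t1 = np.einsum("qn,fnd->fqd", self.endo_D1, x)
        t2 = np.einsum("qn,fnd->fqd", self.endo_D2, x)
        v = np.einsum("fqd,fqd,q->", xq, np.cross(t1, t2), self.endo_qw)
        return float(-v / 3.0) / 1000.0

    def cavity_volume_gradient(self, u) -> np.ndarray:
        """dV/du as a dense vector over u-dofs (mm^3 per mm)."""
        x = self._endo_coords(u)
        N, D1, D2, w = self.endo_N, self.endo_D1, self.endo_D2, self.endo_qw
        xq = np.einsum("qn,fnd->fqd", N, x)
        t1 = np.einsum("qn,fnd->fqd", D1, x)
        t2 = np.einsum("qn,fnd->fqd", D2, x)
        cr12 = np.cross(t1, t2)
        cr2x = np.cross(t2, xq)
        crx1 = np.cross(xq, t1)
        g = (
            np.einsum("qa,fqp,q->fap", N, cr12, w)
            + np.einsum("qa,fqp,q->fap", D1, cr2x, w)
            + np.einsum("qa,fqp,q->fap", D2, crx1, w)
        ) / -3.0
        out = np.zeros(self.n_u)
        np.add.at(out, self.endo_fdof.reshape(-1, 18), g.reshape(-1, 18))
        return out

    def cavity_volume_hessian(self, u) -> sp.csr_matrix:
        """d2V/du2 (symmetric load-stiffness of the cavity functional)."""
        x = self._endo_coords(u)
        N, D1, D2, w = self.endo_N, self.endo_D1, self.endo_D2, self.endo_qw
        xq = np.einsum("qn,fnd->fqd", N, x)
        t1 = np.einsum("qn,fnd->fqd", D1, x)
        t2 = np.einsum("qn,fnd->fqd", D2, x)
        E = _EPS3
        # six bilinear blocks; all contracted with the Levi-Civita tensor
        T_eta = np.einsum("pqk,fik->fipq", E, t2)  # uses x_eta
        T_xi = np.einsum("pjq,fij->fipq", E, t1)
        T_x = np.einsum("ipq,fmi->fmpq", E, xq)
        qwN = w[:, None] * N
        H = (
            np.einsum("qa,qb,fqpr->fapbr", qwN, D1, T_eta)
            + np.einsum("qa,qb,fqpr->fapbr", qwN, D2, T_xi)
            + np.einsum("qa,qb,fqpr->fbrap", qwN, D1, T_eta)
            + np.einsum("qa,qb,fqpr->fbrap", qwN, D2, T_xi)
            + np.einsum("qa,qb,fqpr->fapbr", w[:, None] * D1, D2, T_x)
            + np.einsum("qa,qb,fqpr->fbrap", w[:, None] * D1, D2, T_x)
        ) / -3.0
        vals = H.reshape(len(self.endo_faces), 18, 18)
        Hm = sp.csr_matrix(
            (vals.ravel(), (self.endo_rows, self.endo_cols)),
            shape=(self.n_u + self.n_p, self.n_u + self.n_p),
        )
        return Hm

    # ----------------------------------------------------------- kinematics

    def kinematics(self, u):
        ucell = u[self.mesh.cells]  # (e, 10, 3)
        F = np.einsum("eni,eqnj->eqij", ucell, self.dNx)
        F[..., 0, 0] += 1.0
        F[..., 1, 1] += 1.0
        F[..., 2, 2] += 1.0
        C = np.einsum("eqki,eqkj->eqij", F, F)
        Eg = 0.5 * (C - np.eye(3))
        J = np.linalg.det(F)
        Cinv = np.linalg.inv(C)
        return F, C, Eg, J, Cinv

    def fiber_stretch(self, C) -> np.ndarray:
        return np.sqrt(np.einsum("eqi,eqij,eqj->eq", self.f0, C, self.f0))

    def _stress_and_tangent(self, Eg, C, t_act, act_scale=1.0):
        """Total S (e,q,3,3) and material tangent (e,q,3,3,3,3), fiber+passive."""
        R = self.R
        Efib = np.einsum("eqai,eqij,eqbj->eqab", R, Eg, R)
        Sfib = law.passive_stress(Efib, self.passive)
        C4fib = law.passive_tangent(Efib, self.passive)

        if self.active is not None and t_act is not None and act_scale > 0.0:
            lam = np.sqrt(np.maximum(1.0 + 2.0 * Efib[..., 0, 0], 1e-12))
            l = self.active.sarcomere_length(lam)
            Pact = act_scale * law.active_stress(t_act, l, self.active)
            Sfib = Sfib.copy()
            Sfib[..., 0, 0] += Pact
            dPdl = act_scale * law.active_stress_dl(t_act, l, self.active)
            C4fib = C4fib.copy()
            C4fib[..., 0, 0, 0, 0] += dPdl * self.active.l_ref / lam

        S = np.einsum("eqai,eqab,eqbj->eqij", R, Sfib, R)
        C4 = np.einsum(
            "eqai,eqbj,eqck,eqdl,eqabcd->eqijkl", R, R, R, R, C4fib,
            optimize=True,
        )
        return S, C4

    # ------------------------------------------------------------- assembly

    def assemble(self, u, p_mult, p_cav_kpa, t_act=None, with_matrix=True,
                 act_scale=1.0):
        """Residual (and tangent) of the mixed system at the given state."""
        F, C, Eg, J, Cinv = self.kinematics(u)
        S_e, C4 = self._stress_and_tangent(Eg, C, t_act, act_scale)

        kappa = self.cfg.bulk_penalty
        pq = np.einsum("qa,ea->eq", self.Np, p_mult[self.cell_pdof])
        peff = pq + kappa * (J - 1.0)  # augmented-Lagrangian pressure
        JCinv = J[..., None, None] * Cinv
        S = S_e + peff[..., None, None] * JCinv

        P1 = np.einsum("eqij,eqjk->eqik", F, S)  # first PK
        wdet = self.qw[None, :] * self.detJ0  # (e, q)

        r_u_el = np.einsum("eqik,eqnk,eq->eni", P1, self.dNx, wdet)
        r_p_el = np.einsum("eq,qa,eq->ea", J - 1.0, self.Np, wdet)

        r = np.zeros(self.n_u + self.n_p)
        np.add.at(r, self.udof.reshape(-1, 30), r_u_el.reshape(-1, 30))
        np.add.at(r, self.n_u + self.cell_pdof.reshape(-1, 4), r_p_el.reshape(-1, 4))

        full_state = np.concatenate([u.ravel(), p_mult])
        r += self.K_spring @ full_state

        gV = self.cavity_volume_gradient(u)
        r[: self.n_u] -= p_cav_kpa * gV

        if not with_matrix:
            return r, gV, None

        # pressure-term material tangent: p_eff [Cinv x Cinv - 2 dCinv/dC] J
        # plus the penalty stiffness kappa (J Cinv) x (J Cinv)
        CiCi = np.einsum("eqij,eqkl->eqijkl", Cinv, Cinv)
        dCinv = -0.5 * (
            np.einsum("eqik,eqjl->eqijkl", Cinv, Cinv)
            + np.einsum("eqil,eqjk->eqijkl", Cinv, Cinv)
        )
        Jq = J[..., None, None, None, None]
        C4 = C4 + peff[..., None, None, None, None] * Jq * (CiCi + 2.0 * dCinv)
        C4 = C4 + kappa * Jq * Jq * CiCi

        A = np.einsum("eqim,eqkn,eqmjnl->eqijkl", F, F, C4, optimize=True)
        A += np.einsum("ik,eqjl->eqijkl", np.eye(3), S)
        k_uu = np.einsum(
            "eqnj,eqijkl,eqml,eq->enimk", self.dNx, A, self.dNx, wdet,
            optimize=True,
        ).reshape(-1, 30, 30)

        FJCinv = np.einsum("eqij,eqjk->eqik", F, JCinv)
        k_up = np.einsum(
            "eqik,eqnk,qa,eq->enia", FJCinv, self.dNx, self.Np, wdet,
            optimize=True,
        ).reshape(-1, 30, 4)

        nt = self.n_u + self.n_p
        K = sp.csr_matrix(
            (k_uu.ravel(), (self.rows_uu, self.cols_uu)), shape=(nt, nt)
        )
        Kup = sp.csr_matrix(
            (k_up.ravel(), (self.rows_up, self.cols_up)), shape=(nt, nt)
        )
        K = K + Kup + Kup.T + self.K_spring
        if self.cfg.use_load_stiffness and p_cav_kpa != 0.0:
            K = K - p_cav_kpa * self.cavity_volume_hessian(u)
        return r, gV, K

    # --------------------------------------------------------------- solves

    def _newton(self, p_cav_kpa=None, V_target=None, t_act=None, act_scale=1.0):
        """Newton solve at fixed load; either p_cav given or V_target given."""
        volume_driven = V_target is not None
        u = self.u.copy()
        p_mult = self.p_mult.copy()
        p_cav = self.p_cav if volume_driven else float(p_cav_kpa)
        free = self.free
        history = []
        ref_norm = None
        self._stall_count = 0

        for it in range(self.cfg.newton_maxit):
            try:
                r, gV, K = self.assemble(u, p_mult, p_cav, t_act,
                                         act_scale=act_scale)
            except law.StrainOverflowError as exc:
                raise NewtonError(f"strain overflow during iteration: {exc}",
                                  history) from exc
            if volume_driven:
                r_c = (self.cavity_volume(u) - V_target) * 1000.0  # mm^3
                res = np.concatenate([r[free], [r_c]])
            else:
                res = r[free]
            norm = np.linalg.norm(res)
            history.append(norm)
            if ref_norm is None:
                ref_norm = max(norm, self.cfg.newton_abs_tol)
            if norm < self.cfg.newton_abs_tol or norm < self.cfg.newton_tol * ref_norm:
                self.u, self.p_mult, self.p_cav = u, p_mult, p_cav
                return history
            if not np.isfinite(norm):
                raise NewtonError("non-finite residual", history)

            Kff = K[free][:, free].tocsc()
            try:
                lu = spla.splu(Kff)
            except RuntimeError as exc:  # singular factorization
                raise NewtonError(f"linear solve failed: {exc}", history)
            if volume_driven:
                g = np.zeros(self.n_u + self.n_p)
                g[: self.n_u] = gV
                gf = g[free]
                a = lu.solve(-r[free])
                b = lu.solve(gf)
                denom = gf @ b
                if abs(denom) < 1e-30:
                    raise NewtonError("singular volume-constraint border", history)
                dp_cav = -(r_c + gf @ a) / denom
                dx = a + dp_cav * b
            else:
                dp_cav = 0.0
                dx = lu.solve(-r[free])

            full = np.zeros(self.n_u + self.n_p)
            full[free] = dx

            # backtracking line search on the residual norm; a few
            # non-decreasing (salvage) steps are tolerated before failing
            alpha, accepted = 1.0, False
            best = (None, np.inf)
            for _ in range(6):
                u_try = u + alpha * full[: self.n_u].reshape(-1, 3)
                p_try = p_mult + alpha * full[self.n_u :]
                pc_try = p_cav + alpha * dp_cav if volume_driven else p_cav
                try:
                    r_t, _, _ = self.assemble(
                        u_try, p_try, pc_try, t_act, with_matrix=False,
                        act_scale=act_scale,
                    )
                    if volume_driven:
                        rc_t = (self.cavity_volume(u_try) - V_target) * 1000.0
                        n_t = np.linalg.norm(np.concatenate([r_t[free], [rc_t]]))
                    else:
                        n_t = np.linalg.norm(r_t[free])
                except law.StrainOverflowError:
                    n_t = np.inf
                if np.isfinite(n_t) and n_t < best[1]:
                    best = ((u_try, p_try, pc_try), n_t)
                if np.isfinite(n_t) and n_t < norm:
                    accepted = True
                    break
                alpha *= 0.5
            if accepted:
                stalls = 0
            else:
                if best[0] is None or best[1] > 2.0 * norm:
                    raise NewtonError(
                        "line search stalled (residual not decreasing)",
                        history,
                    )
                stalls = getattr(self, "_stall_count", 0) + 1
                if stalls > 3:
                    raise NewtonError(
                        "line search stalled repeatedly", history
                    )
                (u_try, p_try, pc_try), _ = best
            self._stall_count = stalls
            u, p_mult = u_try, p_try
            if volume_driven:
                p_cav = pc_try

        raise NewtonError(
            f"Newton did not converge in {self.cfg.newton_maxit} iterations "
            f"(last residual {history[-1]:.3e})",
            history,
        )

    def _activation_path(self, t_act):
        """Per-substep (t_act, act_scale) along the load path.

        From an inactive state the activation amplitude is ramped at the
        target time; from an active state the activation *time* is blended
        forward (wrapping at the cycle seam), so the non-smooth length
        dependence of the relaxation branch is crossed in small steps.
        """
        if t_act is None:
            return lambda frac: (None, 1.0)
        prev = getattr(self, "_last_t_act", None)
        if prev is None or self.active is None:
            return lambda frac: (t_act, frac)
        T = self.active.cycle_length
        t_new = t_act if t_act >= prev else t_act + T
        return lambda frac: ((prev + (t_new - prev) * frac) % T, 1.0)

    def solve_to_pressure(self, p_mmhg: float, t_act=None):
        """Quasi-static solve at a prescribed cavity pressure (mmHg)."""
        p_now = self.p_cav
        act_path = self._activation_path(t_act)

        def step(frac):
            t_f, scale = act_path(frac)
            self._newton(
                p_cav_kpa=self._blend(p_now, p_mmhg * MMHG_TO_KPA, frac),
                t_act=t_f, act_scale=scale,
            )

        self._substepped(step)
        self._last_t_act = t_act
        return self

    def solve_to_volume(self, V_target_ml: float, t_act=None):
        """Solve displacement and cavity pressure at a target volume (ml)."""
        V_now = self.cavity_volume()
        act_path = self._activation_path(t_act)

        def step(frac):
            t_f, scale = act_path(frac)
            self._newton(
                V_target=self._blend(V_now, V_target_ml, frac),
                t_act=t_f, act_scale=scale,
            )

        self._substepped(step)
        self._last_t_act = t_act
        achieved = self.cavity_volume()
        if abs(achieved - V_target_ml) > 1e-3 * max(abs(V_target_ml), 1e-9):
            raise NewtonError(
                f"volume constraint missed: {achieved:.6f} vs {V_target_ml:.6f} ml"
            )
        return self

    @staticmethod
    def _blend(a, b, frac):
        return a + (b - a) * frac

    def _substepped(self, solve_at_fraction):
        """Adaptive load sub-stepping around the Newton solve."""
        saved = (self.u.copy(), self.p_mult.copy(), self.p_cav)
        n_sub = 1
        while True:
            try:
                for k in range(1, n_sub + 1):
                    solve_at_fraction(k / n_sub)
                return
            except NewtonError as err:
                self.u, self.p_mult, self.p_cav = (
                    saved[0].copy(), saved[1].copy(), saved[2],
                )
                n_sub *= 2
                if n_sub > self.cfg.max_substeps:
                    raise NewtonError(
                        f"load step failed even with {self.cfg.max_substeps} "
                        f"substeps: {err}",
                        err.residuals,
                    ) from err

    # ------------------------------------------------------------- queries

    def check_incompressibility(self):
        _, _, _, J, _ = self.kinematics(self.u)
        worst = float(np.abs(J - 1.0).max())
        if worst > self.cfg.incompressibility_tol:
            raise RuntimeError(
                f"|J-1| = {worst:.3e} exceeds {self.cfg.incompressibility_tol}"
            )
        return worst

    def state(self, time=0.0, t_act=None) -> CardiacState:
        return CardiacState(
            u=self.u.copy(),
            p_mult=self.p_mult.copy(),
            cavity_pressure=self.p_cav * KPA_TO_MMHG,
            cavity_volume=self.cavity_volume(),
            time=time,
            activation_time=t_act if t_act is not None else time,
        )

    def set_state(self, st: CardiacState):
        self.u = st.u.copy()
        self.p_mult = st.p_mult.copy()
        self.p_cav = st.cavity_pressure * MMHG_TO_KPA

    def reset(self):
        self.u[:] = 0.0
        self.p_mult[:] = 0.0
        self.p_cav = 0.0
        self._last_t_act = None

    # quantities for the biomechanics metrics ---------------------------------

    def quad_weights(self) -> np.ndarray:
        """Reference volume weights (mm^3) at the quadrature points."""
        return self.qw[None, :] * self.detJ0

    def green_lagrange(self, u) -> np.ndarray:
        return self.kinematics(u)[2]

    def cauchy_fiber_stress(self, u, p_mult, t_act=None) -> np.ndarray:
        """Deformed-fiber-direction Cauchy stress (kPa) at quadrature points."""
        F, C, Eg, J, Cinv = self.kinematics(u)
        S_e, _ = self._stress_and_tangent(Eg, C, t_act)
        pq = np.einsum("qa,ea->eq", self.Np, p_mult[self.cell_pdof])
        peff = pq + self.cfg.bulk_penalty * (J - 1.0)
        S = S_e + (peff * J)[..., None, None] * Cinv
        sig = np.einsum("eqiI,eqIJ,eqjJ->eqij", F, S, F) / J[..., None, None]
        fdef = np.einsum("eqiJ,eqJ->eqi", F, self.f0)
        fdef /= np.linalg.norm(fdef, axis=-1, keepdims=True)
        return np.einsum("eqi,eqij,eqj->eq", fdef, sig, fdef)

    def passive_energy_density(self, u) -> np.ndarray:
        """Fung strain-energy density (kPa) against the unloaded reference."""
        Eg = self.green_lagrange(u)
        Efib = np.einsum("eqai,eqij,eqbj->eqab", self.R, Eg, self.R)
        return law.passive_energy(Efib, self.passive)


# ======================================================================
# cycle drivers
# ======================================================================


@dataclass
class CycleResult:
    """One simulated cardiac cycle: PV loop plus stored solution states."""

    loop: PVLoop
    states: list
    solver: LVSolver

    @property
    def ed_index(self) -> int:
        return int(np.argmax([s.cavity_volume for s in self.states]))

    @property
    def es_index(self) -> int:
        return int(np.argmin([s.cavity_volume for s in self.states]))


def run_volume_constrained_cycle(
    mesh: LVMesh,
    fibers: FiberField,
    passive: PassiveParams,
    active: ActiveParams,
    waveform,
    config: SolverConfig | None = None,
) -> CycleResult:
    """Prescribe the cavity volume waveform; solve pressure at every step.

    The mesh is taken as the unloaded geometry, which the waveform clock
    places at one third of the diastolic duration (the low-pressure point
    of filling); the activation clock has its zero at end-diastole, which
    is t = 0 of the waveform.
    """
    cfg = config or SolverConfig()
    solver = LVSolver(mesh, fibers, passive, active, cfg)
    T = waveform.cycle_length

    t_es = waveform.es_time
    t_start = t_es + (T - t_es) / 3.0  # 1/3 of diastolic duration past ES

    n = cfg.steps_per_cycle
    dt = T / n
    # anchor the step grid at end-diastole (t = 0 of the waveform clock) so
    # ED is sampled exactly, and inject the exact end-systolic instant
    t0 = np.round(t_start / dt) * dt
    times = t0 + dt * np.arange(n + 1)
    t_es_abs = t_es + T * np.ceil((t0 - t_es) / T - 1e-12)
    if np.min(np.abs(times - t_es_abs)) > 1e-9 * T:
        times = np.sort(np.append(times, t_es_abs))

    states = []
    for k, t_abs in enumerate(times):
        t_cyc = float(t_abs % T)
        V_tgt = float(waveform.volume_at(t_cyc))
        try:
            solver.solve_to_volume(V_tgt, t_act=t_cyc)
        except NewtonError as err:
            raise NewtonError(
                f"cycle step {k} (t = {t_cyc:.1f} ms, V = {V_tgt:.3f} ml) "
                f"failed: {err}",
                err.residuals,
            ) from err
        achieved = solver.cavity_volume()
        if abs(achieved - V_tgt) > 1e-3 * V_tgt:
            raise NewtonError(
                f"step {k}: achieved volume {achieved:.5f} ml misses target "
                f"{V_tgt:.5f} ml by more than 0.1%"
            )
        states.append(solver.state(time=t_cyc, t_act=t_cyc))

    loop = PVLoop(
        time_ms=np.array([s.time for s in states]),
        pressure_mmhg=np.array([s.cavity_pressure for s in states]),
        volume_ml=np.array([s.cavity_volume for s in states]),
    )
    return CycleResult(loop=loop, states=states, solver=solver)


def run_coupled_cycle(
    mesh: LVMesh,
    fibers: FiberField,
    passive: PassiveParams,
    active: ActiveParams,
    circ_params,
    config: SolverConfig | None = None,
    n_warmup_cycles: int = 12,
    n_coupled_cycles: int = 2,
) -> tuple[CycleResult, "object"]:
    """Couple the FE LV to the 0D circulation, one exchange per macro step.

    The closed loop is first run to periodic steady state with the LV as a
    time-varying elastance; the FE model then replaces the LV: at each
    macro time step the network integrates with the last FE pressure held,
    the integrated valve flows set the new LV target volume, and the FE
    solve at that volume returns the next pressure.
    """
    from . import circulation as circ0d

    cfg = config or SolverConfig()
    warm = circ0d.simulate_circulation(
        circ_params, n_cycles=n_warmup_cycles, check_steady_state=True
    )
    names = circ_params.node_names()
    V_net = {n: warm.volumes[n][-1] for n in names}

    solver = LVSolver(mesh, fibers, passive, active, cfg)
    T = circ_params.cycle_length
    n_steps = cfg.steps_per_cycle
    dt_s = (T / n_steps) / 1000.0

    # bring the FE cavity to the network's LV volume, passively (t=0 is ED)
    solver.solve_to_volume(V_net["LV"], t_act=0.0)
    p_lv = solver.p_cav * KPA_TO_MMHG

    rhs_factory = circ0d._network_rhs
    from scipy.integrate import solve_ivp

    states, times, pressures, volumes = [], [], [], []
    exchanged = []  # conservation bookkeeping
    t_clock = 0.0
    for cyc in range(n_coupled_cycles):
        for k in range(n_steps):
            p_fixed = p_lv
            rhs, flows_fn, _, idx = rhs_factory(
                circ_params, names, lv_pressure=lambda t, p0=p_fixed: p0
            )
            y0 = np.array([V_net[n] for n in names])
            sol = solve_ivp(
                rhs, (t_clock, t_clock + dt_s), y0, method="BDF",
                rtol=1e-8, atol=1e-10,
            )
            if not sol.success:
                raise RuntimeError(f"0D step failed: {sol.message}")
            yk = sol.y[:, -1]
            V_net = {n: yk[i] for i, n in enumerate(names)}
            t_clock += dt_s
            t_cyc = (t_clock * 1000.0) % T

            try:
                solver.solve_to_volume(V_net["LV"], t_act=t_cyc)
            except NewtonError as err:
                raise NewtonError(
                    f"coupled step {cyc}.{k} failed (V = {V_net['LV']:.3f} "
                    "ml); consider sub-iterating the exchange or smaller "
                    f"steps: {err}",
                    err.residuals,
                ) from err
            p_lv = solver.p_cav * KPA_TO_MMHG
            if cyc == n_coupled_cycles - 1:
                states.append(solver.state(time=t_cyc, t_act=t_cyc))
                times.append(t_cyc)
                pressures.append(p_lv)
                volumes.append(solver.cavity_volume())
            exchanged.append(V_net["LV"])

    order = np.argsort(times)
    loop = PVLoop(
        time_ms=np.array(times)[order],
        pressure_mmhg=np.array(pressures)[order],
        volume_ml=np.array(volumes)[order],
    )
    result = CycleResult(loop=loop, states=[states[i] for i in order],
                         solver=solver)
    return result, warm


def find_unloaded_state(
    mesh: LVMesh,
    edp_mmhg: float,
    passive: PassiveParams,
    config: SolverConfig | None = None,
    helix=None,
    edv_ml: float | None = None,
    max_iterations: int = 10,
    rel_tol: float = 1e-3,
) -> UnloadedState:
    """Backward-displacement estimate of the zero-pressure geometry.

    The input mesh is the measured (loaded, end-diastolic) geometry.  The
    fixed point X0 <- X_meas - u(X0; EDP) is iterated until the update
    stalls; the returned state records the round-trip reinflation errors.
    """
    from .fibers import HelixConfig, make_fiber_field
    from .geometry import compute_cavity_volume

    cfg = config or SolverConfig()
    helix = helix or HelixConfig(10.0, 123.0)
    target_points = mesh.points.copy()
    edv = edv_ml if edv_ml is not None else compute_cavity_volume(mesh)
    char = 0.5 * (np.ptp(mesh.points[:, 0]) + np.ptp(mesh.points[:, 1])) / 2.0

    if edp_mmhg < 0:
        raise ValueError("end-diastolic pressure must be non-negative")
    work = mesh.copy()
    iterations = 0
    if edp_mmhg > 0:
        for iterations in range(1, max_iterations + 1):
            fibers, _, _ = make_fiber_field(work, helix, cfg.quadrature_degree)
            solver = LVSolver(work, fibers, passive, None, cfg)
            solver.solve_to_pressure(edp_mmhg)
            new_points = target_points - solver.u
            change = np.sqrt(((new_points - work.points) ** 2).mean())
            work = work.copy()
            work.points = new_points
            if change < rel_tol * char:
                break

    # round-trip validation
    fibers, _, _ = make_fiber_field(work, helix, cfg.quadrature_degree)
    solver = LVSolver(work, fibers, passive, None, cfg)
    solver.solve_to_pressure(edp_mmhg) if edp_mmhg > 0 else None
    v_round = solver.cavity_volume()
    rms = float(np.sqrt(((work.points + solver.u - target_points) ** 2).mean()))
    return UnloadedState(
        points=work.points.copy(),
        pressure_residual=0.0,
        volume_residual=abs(v_round - edv) / edv,
        nodal_rms=rms,
        iterations=iterations,
    )


def calibrate_t0lv(
    peak_pressure_of_t0,
    target_peak_mmhg: float,
    bounds: tuple[float, float] = (23.9, 59.2),
    tol_mmhg: float = 0.5,
    max_iterations: int = 30,
) -> float:
    """Bisect the maximum tension T0_LV to match a target peak pressure.

    ``peak_pressure_of_t0`` maps a T0_LV (kPa) to the simulated peak
    systolic pressure (mmHg); the fetal literature bracket 23.9-59.2 kPa
    is the default search interval.  Raises if the target is outside the
    bracket (reporting the bracket pressures).
    """
    lo, hi = bounds
    if lo >= hi:
        raise ValueError("invalid bounds")
    p_lo = peak_pressure_of_t0(lo)
    if abs(p_lo - target_peak_mmhg) < tol_mmhg:
        return lo
    p_hi = peak_pressure_of_t0(hi)
    if abs(p_hi - target_peak_mmhg) < tol_mmhg:
        return hi
    if not (min(p_lo, p_hi) < target_peak_mmhg < max(p_lo, p_hi)):
        raise ValueError(
            f"target {target_peak_mmhg:.2f} mmHg not bracketed: "
            f"T0 = {lo} kPa gives {p_lo:.2f} mmHg, "
            f"T0 = {hi} kPa gives {p_hi:.2f} mmHg"
        )
    for _ in range(max_iterations):
        mid = 0.5 * (lo + hi)
        p_mid = peak_pressure_of_t0(mid)
        if abs(p_mid - target_peak_mmhg) < tol_mmhg:
            return mid
        if (p_mid < target_peak_mmhg) == (p_lo < target_peak_mmhg):
            lo, p_lo = mid, p_mid
        else:
            hi = mid
    raise RuntimeError("tension calibration did not converge")
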