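"""Myocardial constitutive models.

Passive response: transversely isotropic Fung-type hyperelasticity,

    W = C/2 (exp(Q) - 1),
    Q = b_ff E_ff^2 + b_xx (E_ss^2 + E_nn^2 + E_sn^2 + E_ns^2)
      + b_fx (E_fn^2 + E_nf^2 + E_fs^2 + E_sf^2),

with E the Green–Lagrange strain in the fiber (f), sheet (s), sheet-normal
(n) frame.  Active response: length- and time-dependent tension along the
fiber direction,

    P_act = T0_LV * Ca0^2 / (Ca0^2 + ECa50(l)^2) * Ct(t, l),

with Ct = (1 - cos omega)/2 rising over [0, t0) and relaxing over
[t0, t0 + t_r), t_r = m*l + b, and the length-dependent calcium
sensitivity ECa50 = Ca0_max / sqrt(exp(B_len (l - l0)) - 1).

Default parameter values are surrogates from the Guccione/Shavik model
family, flagged as supplementary-table surrogates; every value is
overridable per run.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import numpy as np

_FSN = ("f", "s", "n")


class StrainOverflowError(FloatingPointError):
    """Raised when the Fung exponent exceeds the configured cap."""


@dataclass(frozen=True)
class PassiveParams:
    """Fung-law stiffness parameters.  C in kPa; exponents dimensionless."""

    C: float = 0.876  # kPa (Guccione-family surrogate)
    b_ff: float = 18.48
    b_xx: float = 3.58
    b_fx: float = 1.627
    Q_cap: float = 50.0  # overflow guard on the exponent

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError("C must be positive")
        if min(self.b_ff, self.b_xx, self.b_fx) < 0:
            raise ValueError("Fung exponents must be non-negative")

    @property
    def exponent_matrix(self) -> np.ndarray:
        """B[i,j] such that Q = sum_ij B_ij E_ij^2 in (f, s, n) ordering."""
        b = np.empty((3, 3))
        b[0, 0] = self.b_ff
        b[1:, 1:] = self.b_xx
        b[0, 1:] = b[1:, 0] = self.b_fx
        return b

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PassiveParams":
        return cls(**d)

    def isotropic_limit(self, b: float | None = None) -> "PassiveParams":
        """All exponents equal: Q = b ||E||^2, an isotropic Fung solid."""
        b = self.b_xx if b is None else b
        return replace(self, b_ff=b, b_xx=b, b_fx=b)


def _check_symmetric(E: np.ndarray, tol: float = 1e-12):
    if np.abs(E - np.swapaxes(E, -1, -2)).max() > tol * max(
        1.0, float(np.abs(E).max())
    ):
        raise ValueError("Green–Lagrange strain must be symmetric")


def fung_exponent(E: np.ndarray, p: PassiveParams) -> np.ndarray:
    """Q(E); raises when the configured cap is exceeded."""
    B = p.exponent_matrix
    Q = np.einsum("ij,...ij->...", B, np.asarray(E) ** 2)
    if np.any(Q > p.Q_cap):
        worst = np.unravel_index(np.argmax(Q), Q.shape) if Q.ndim else ()
        raise StrainOverflowError(
            f"Fung exponent Q = {float(np.max(Q)):.3g} exceeds the cap "
            f"{p.Q_cap:g} (strain state index {worst})"
        )
    return Q


def passive_energy(E: np.ndarray, p: PassiveParams) -> np.ndarray:
    """Strain energy density W in kPa for fiber-frame strain E (...,3,3)."""
    E = np.asarray(E, dtype=float)
    _check_symmetric(E)
    return 0.5 * p.C * np.expm1(fung_exponent(E, p))


def passive_stress(E: np.ndarray, p: PassiveParams) -> np.ndarray:
    """Second Piola–Kirchhoff stress S = dW/dE in the fiber frame (kPa)."""
    E = np.asarray(E, dtype=float)
    _check_symmetric(E)
    B = p.exponent_matrix
    eQ = np.exp(fung_exponent(E, p))
    return p.C * eQ[..., None, None] * B * E


def passive_tangent(E: np.ndarray, p: PassiveParams) -> np.ndarray:
    """Material tangent dS/dE (..., 3, 3, 3, 3) in the fiber frame."""
    E = np.asarray(E, dtype=float)
    B = p.exponent_matrix
    eQ = np.exp(fung_exponent(E, p))
    BE = B * E
    eye = np.eye(3)
    I4s = 0.5 * (
        np.einsum("ik,jl->ijkl", eye, eye) + np.einsum("il,jk->ijkl", eye, eye)
    )
    term1 = B[..., :, :, None, None] * I4s
    term2 = 2.0 * np.einsum("...ij,...kl->...ijkl", BE, BE)
    return p.C * eQ[..., None, None, None, None] * (term1 + term2)


@dataclass(frozen=True)
class ActiveParams:
    """Calcium-activation active-tension parameters.

    Units: T0_LV kPa; Ca0, Ca0_max uM; B_len 1/um; l0, l_ref um;
    t0, b_time, cycle_length ms; m ms/um.  Fetal defaults assume the
    400 ms cardiac cycle; t0 = 140.5 ms is the fetal time to peak tension.
    """

    T0_LV: float = 40.0  # kPa, within the fetal 23.9-59.2 kPa bracket
    Ca0: float = 4.35  # uM
    Ca0_max: float = 4.35  # uM
    B_len: float = 4.75  # 1/um
    l0: float = 1.58  # um, length below which no tension develops
    l_ref: float = 1.85  # um, sarcomere length in the unloaded state
    t0: float = 140.5  # ms, time to peak tension
    m: float = 524.5  # ms/um, relaxation-duration slope (cycle-scaled)
    b_time: float = -800.0  # ms, relaxation-duration intercept
    cycle_length: float = 400.0  # ms

    def __post_init__(self):
        if self.T0_LV < 0:
            raise ValueError("T0_LV must be non-negative")
        if not 0 < self.t0 < self.cycle_length:
            raise ValueError("t0 must lie inside the cycle")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ActiveParams":
        return cls(**d)

    def sarcomere_length(self, stretch) -> np.ndarray:
        """l = l_ref * lambda_f from the fiber stretch ratio."""
        return self.l_ref * np.asarray(stretch, dtype=float)


def adult_active_params() -> ActiveParams:
    """Surrogate adult parameter set for the 800 ms cycle."""
    return ActiveParams(
        T0_LV=100.0, t0=281.0, m=1049.0, b_time=-1600.0, cycle_length=800.0
    )


@dataclass(frozen=True)
class ActivationState:
    t: float
    l: float
    omega: float
    t_r: float
    Ct: float
    ECa50: float


def relaxation_duration(l, p: ActiveParams) -> np.ndarray:
    """t_r = m l + b (ms)."""
    t_r = p.m * np.asarray(l, dtype=float) + p.b_time
    if np.any(t_r <= 0):
        raise ValueError(
            f"non-positive relaxation duration t_r for sarcomere length {l}"
        )
    return t_r


def eca50(l, p: ActiveParams) -> np.ndarray:
    """Length-dependent calcium sensitivity (uM)."""
    arg = np.expm1(p.B_len * (np.asarray(l, dtype=float) - p.l0))
    if np.any(arg <= 0):
        raise ValueError(
            "sarcomere length at or below l0: ECa50 undefined (no tension "
            "development in this regime)"
        )
    return p.Ca0_max / np.sqrt(arg)


def activation_timecourse(t, l, p: ActiveParams) -> ActivationState:
    """Activation phase omega and Ct at cycle time t (ms), length l (um)."""
    t = float(t)
    l = float(l)
    if not 0 <= t < p.cycle_length:
        raise ValueError("t must satisfy 0 <= t < cycle_length")
    t_r = float(relaxation_duration(l, p))
    if t < p.t0:
        omega = np.pi * t / p.t0
    elif t < p.t0 + t_r:
        omega = np.pi * (t - p.t0 + t_r) / t_r
    else:
        omega = 0.0
    Ct = 0.5 * (1.0 - np.cos(omega))
    return ActivationState(t=t, l=l, omega=omega, t_r=t_r, Ct=Ct,
                           ECa50=float(eca50(l, p)))


def ct_curve(t, l, p: ActiveParams) -> np.ndarray:
    """Vectorised Ct over arrays of cycle times/lengths."""
    t = np.asarray(t, dtype=float)
    l = np.broadcast_to(np.asarray(l, dtype=float), t.shape)
    t_r = relaxation_duration(l, p)
    omega = np.where(
        t < p.t0,
        np.pi * t / p.t0,
        np.where(t < p.t0 + t_r, np.pi * (t - p.t0 + t_r) / t_r, 0.0),
    )
    return 0.5 * (1.0 - np.cos(omega))


def active_stress(t, l, p: ActiveParams) -> np.ndarray:
    """Active fiber tension P_act (kPa) at cycle time t, sarcomere length l.

    Vectorised over l; below the tension-development length l0 the active
    stress is zero (the sensitivity law saturates ECa50 -> infinity there).
    """
    t = float(t) % p.cycle_length
    l = np.asarray(l, dtype=float)
    t_r = relaxation_duration(np.maximum(l, p.l0 + 1e-9), p)
    omega = np.where(
        t < p.t0,
        np.pi * t / p.t0,
        np.where(t < p.t0 + t_r, np.pi * (t - p.t0 + t_r) / t_r, 0.0),
    )
    Ct = 0.5 * (1.0 - np.cos(omega))
    develops = l > p.l0
    arg = np.expm1(p.B_len * (np.where(develops, l, p.l0 + 1.0) - p.l0))
    eca50_sq = p.Ca0_max**2 / arg
    scale = p.Ca0**2 / (p.Ca0**2 + eca50_sq)
    return np.where(develops, p.T0_LV * scale * Ct, 0.0)


def active_stress_dl(t, l, p: ActiveParams, dl: float = 1e-6) -> np.ndarray:
    """Central-difference derivative dP_act/dl used in solver tangents."""
    return (active_stress(t, l + dl, p) - active_stress(t, l - dl, p)) / (2 * dl)
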