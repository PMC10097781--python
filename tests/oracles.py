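"""Independent semi-analytic oracles used to cross-check the FE solver.

The thick-walled incompressible sphere under internal pressure admits a
1D radial-quadrature solution: with inner radius a0 -> a, every material
shell maps as r(r0) = (r0^3 + a^3 - a0^3)^(1/3), the principal stretches
are (lambda_r, lambda_t, lambda_t) = ((r0/r)^2, r/r0, r/r0), and

    P = int_{a0}^{b0} 2 (sigma_t - sigma_r) / r * (r0/r)^2 dr0,

where the hydrostatic part cancels in sigma_t - sigma_r.  The material is
the isotropic limit of the Fung law: W = C/2 (exp(b ||E||^2) - 1).
"""

import numpy as np


def isotropic_fung_sphere_pressure(
    a0: float, b0: float, cavity_volume_mm3: float, C: float, b: float,
    n_quad: int = 2000,
) -> float:
    """Internal pressure (kPa) of the inflated incompressible sphere.

    ``cavity_volume_mm3`` is the FULL-sphere cavity volume (4/3 pi a^3).
    """
    a = (3.0 * cavity_volume_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    r0 = np.linspace(a0, b0, n_quad)
    r = (r0**3 + a**3 - a0**3) ** (1.0 / 3.0)
    lam_t = r / r0
    lam_r = (r0 / r) ** 2
    E_t = 0.5 * (lam_t**2 - 1.0)
    E_r = 0.5 * (lam_r**2 - 1.0)
    Q = b * (E_r**2 + 2.0 * E_t**2)
    eQ = np.exp(Q)
    S_t = C * b * E_t * eQ
    S_r = C * b * E_r * eQ
    sig_diff = lam_t**2 * S_t - lam_r**2 * S_r
    integrand = 2.0 * sig_diff / r * (r0 / r) ** 2
    return float(np.trapezoid(integrand, r0))
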