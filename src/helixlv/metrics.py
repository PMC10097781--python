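"""Biomechanical outcome metrics, helix-configuration maps, and comparisons.

Four optimality criteria are computed per simulated cycle:

* stroke work — area of the pressure–volume loop (mJ; maximized),
* peak myofiber stress — temporal peak of the volume-averaged Cauchy
  stress projected on the deformed fiber direction (kPa; maximized),
* deformational burden — amplitude of the change in volume-averaged
  passive strain-energy density between end-diastole and end-systole
  (kPa; minimized),
* transmural strain variance — variance of fiber-direction strain
  (end-systole against end-diastole) across a mid-ventricular transverse
  slab (dimensionless; minimized).

Global longitudinal/circumferential strains (end-systolic, end-diastolic
reference) feed the FE-versus-echo strain error

    ER = (eps_long_FE - eps_long_echo)^2 + (eps_circ_FE - eps_circ_echo)^2.

Metric values gathered over a (tau_bar, tau_diff) grid form maps with a
bicubic-spline interpolant, a located optimum, and SSIM comparison between
map pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

MMHG_ML_TO_MJ = 0.133322

CRITERIA = {
    "max_stroke_work": ("stroke_work", "max"),
    "max_myofiber_stress": ("peak_myofiber_stress", "max"),
    "min_deform_burden": ("deform_energy_amplitude", "min"),
    "min_strain_variance": ("transmural_strain_variance", "min"),
}


@dataclass(frozen=True)
class StrainSummary:
    """Global end-systolic Green–Lagrange strains, end-diastole reference."""

    eps_long: float  # fraction
    eps_circ: float  # fraction
    source: str = "fe"
    units: str = "fraction"

    def as_percent(self) -> tuple[float, float]:
        return 100.0 * self.eps_long, 100.0 * self.eps_circ


@dataclass(frozen=True)
class BiomechMetrics:
    stroke_work: float  # mJ
    peak_myofiber_stress: float  # kPa
    deform_energy_amplitude: float  # kPa
    transmural_strain_variance: float  # dimensionless

    def to_dict(self) -> dict:
        return {
            "stroke_work": self.stroke_work,
            "peak_myofiber_stress": self.peak_myofiber_stress,
            "deform_energy_amplitude": self.deform_energy_amplitude,
            "transmural_strain_variance": self.transmural_strain_variance,
        }


# --------------------------------------------------------------- PV loop


def compute_stroke_work(volume_ml, pressure_mmhg=None, closure_tol=0.02) -> float:
    """Stroke work (mJ) as the shoelace area of the closed (V, p) polygon.

    Accepts a PVLoop-like object or explicit volume/pressure arrays.  The
    loop must close (first and last points within ``closure_tol`` of the
    excursion); counterclockwise (forward work) loops give positive area,
    a reversed traversal triggers an orientation warning and the absolute
    value is returned.
    """
    if pressure_mmhg is None:
        loop = volume_ml
        volume_ml, pressure_mmhg = loop.volume_ml, loop.pressure_mmhg
    V = np.asarray(volume_ml, dtype=float)
    p = np.asarray(pressure_mmhg, dtype=float)
    if V.shape != p.shape or V.ndim != 1 or len(V) < 3:
        raise ValueError("need matching 1D volume and pressure arrays")
    v_span = max(np.ptp(V), 1e-12)
    p_span = max(np.ptp(p), 1e-12)
    if p_span > 1e-9 and (
        abs(V[0] - V[-1]) > closure_tol * v_span
        or abs(p[0] - p[-1]) > closure_tol * p_span
    ):
        raise ValueError(
            "PV loop is not closed: endpoints differ by "
            f"dV = {abs(V[0] - V[-1]):.3g} ml, dp = {abs(p[0] - p[-1]):.3g} mmHg"
        )
    area = 0.5 * float(np.sum(V * np.roll(p, -1) - np.roll(V, -1) * p))
    # a forward beat (fill low, eject high) runs counterclockwise in
    # (V, p) and gives a positive shoelace area
    if area < 0:
        warnings.warn("PV loop traversed in reverse orientation; "
                      "reporting |area|", stacklevel=2)
    return abs(area) * MMHG_ML_TO_MJ


# ----------------------------------------------------- field-based metrics


def volume_average(weights: np.ndarray, values: np.ndarray) -> float:
    """Volume-weighted average of a quadrature-point field."""
    return float(np.sum(weights * values) / np.sum(weights))


def _ed_es(result):
    return result.states[result.ed_index], result.states[result.es_index]


def compute_peak_myofiber_stress(result) -> float:
    """Temporal peak of the wall-averaged deformed-fiber Cauchy stress (kPa)."""
    solver = result.solver
    w = solver.quad_weights()
    peak = -np.inf
    for st in result.states:
        sig_ff = solver.cauchy_fiber_stress(st.u, st.p_mult, st.activation_time)
        peak = max(peak, volume_average(w, sig_ff))
    if not np.isfinite(peak):
        raise ValueError("no states with stress data")
    return float(peak)


def compute_deformational_burden(result) -> float:
    """|W_bar(ES) - W_bar(ED)|, W the passive energy density (kPa)."""
    solver = result.solver
    ed, es = _ed_es(result)
    w = solver.quad_weights()
    w_ed = volume_average(w, solver.passive_energy_density(ed.u))
    w_es = volume_average(w, solver.passive_energy_density(es.u))
    return float(abs(w_es - w_ed))


def directional_relative_strain(solver, u_ref, u_cur, directions) -> np.ndarray:
    """Green–Lagrange strain of material line elements between two states.

    For reference-configuration unit directions d: the stretch ratio
    lambda = |F_cur d| / |F_ref d| gives e = (lambda^2 - 1)/2, the strain
    of the current state measured against the (deformed) reference state.
    """
    F_ref = solver.kinematics(u_ref)[0]
    F_cur = solver.kinematics(u_cur)[0]
    lam_ref = np.linalg.norm(np.einsum("eqij,eqj->eqi", F_ref, directions), axis=-1)
    lam_cur = np.linalg.norm(np.einsum("eqij,eqj->eqi", F_cur, directions), axis=-1)
    ratio = lam_cur / lam_ref
    return 0.5 * (ratio**2 - 1.0)


def compute_transmural_strain_variance(
    result, slab_half_width_fraction: float = 0.05
) -> float:
    """Variance of ES-vs-ED fiber-direction strain on a mid-ventricle slab.

    The slab is normal to the long axis at 50% of the cavity length with a
    half-width of ``slab_half_width_fraction`` of the cavity length; the
    variance is unweighted over the quadrature points inside.
    """
    solver = result.solver
    mesh = solver.mesh
    ed, es = _ed_es(result)
    e_f = directional_relative_strain(solver, ed.u, es.u, solver.f0)

    from .fibers import quadrature_point_coords

    xq = quadrature_point_coords(mesh, solver.cfg.quadrature_degree)
    z = xq[..., 2]
    z_min, z_max = mesh.points[:, 2].min(), mesh.points[:, 2].max()
    length = z_max - z_min
    z_mid = z_max - 0.5 * length
    sel = np.abs(z - z_mid) <= slab_half_width_fraction * length
    if not np.any(sel):
        raise ValueError("mid-ventricular slab contains no quadrature points")
    return float(np.var(e_f[sel]))


def compute_global_strains(result) -> StrainSummary:
    """Volume-averaged global (long, circ) ES strains, ED reference."""
    solver = result.solver
    frames = solver.fibers.frames
    if frames is None:
        raise ValueError("fiber field carries no local frames")
    ed, es = _ed_es(result)
    w = solver.quad_weights()
    e_ll = directional_relative_strain(solver, ed.u, es.u, frames.l)
    e_cc = directional_relative_strain(solver, ed.u, es.u, frames.c)
    return StrainSummary(
        eps_long=volume_average(w, e_ll),
        eps_circ=volume_average(w, e_cc),
        source="fe",
    )


def compute_biomech_metrics(result) -> BiomechMetrics:
    return BiomechMetrics(
        stroke_work=compute_stroke_work(result.loop),
        peak_myofiber_stress=compute_peak_myofiber_stress(result),
        deform_energy_amplitude=compute_deformational_burden(result),
        transmural_strain_variance=compute_transmural_strain_variance(result),
    )


def strain_error(fe: StrainSummary, echo: StrainSummary) -> float:
    """FE-versus-image strain error ER (squared-difference sum, fractions)."""
    if fe.units != echo.units:
        raise ValueError(f"unit mismatch: {fe.units!r} vs {echo.units!r}")
    return float(
        (fe.eps_long - echo.eps_long) ** 2 + (fe.eps_circ - echo.eps_circ) ** 2
    )


# ------------------------------------------------------------------- maps


@dataclass
class OptimalPoint:
    tau_bar: float
    tau_diff: float
    value: float
    direction: str  # "max" | "min"
    on_boundary: bool


@dataclass
class HelixMap:
    """Metric values on a (tau_bar, tau_diff) grid with an interpolant."""

    tau_bar: np.ndarray  # (nx,) degrees, ascending
    tau_diff: np.ndarray  # (ny,) degrees, ascending
    values: np.ndarray  # (nx, ny); NaN where masked
    metric: str = ""

    def __post_init__(self):
        self.tau_bar = np.asarray(self.tau_bar, dtype=float)
        self.tau_diff = np.asarray(self.tau_diff, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.tau_bar), len(self.tau_diff)):
            raise ValueError("values shape does not match the grid")
        self._interp = None

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def _build_interp(self):
        from scipy.interpolate import RBFInterpolator, RectBivariateSpline

        if self.mask.all() and len(self.tau_bar) >= 2 and len(self.tau_diff) >= 2:
            kx = min(3, len(self.tau_bar) - 1)
            ky = min(3, len(self.tau_diff) - 1)
            spl = RectBivariateSpline(
                self.tau_bar, self.tau_diff, self.values, kx=kx, ky=ky, s=0
            )
            self._interp = lambda tb, td: spl(tb, td, grid=False)
        else:
            tb, td = np.meshgrid(self.tau_bar, self.tau_diff, indexing="ij")
            pts = np.stack([tb[self.mask], td[self.mask]], axis=-1)
            if len(pts) < 3:
                raise ValueError("too few evaluated nodes to interpolate")
            rbf = RBFInterpolator(pts, self.values[self.mask],
                                  kernel="thin_plate_spline")
            self._interp = lambda x, y: rbf(
                np.stack([np.atleast_1d(x), np.atleast_1d(y)], axis=-1)
            )

    def evaluate(self, tau_bar, tau_diff) -> np.ndarray:
        if self._interp is None:
            self._build_interp()
        out = np.asarray(self._interp(tau_bar, tau_diff), dtype=float)
        return out if out.shape else float(out)

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "tau_bar_deg": self.tau_bar.tolist(),
            "tau_diff_deg": self.tau_diff.tolist(),
            "values": [
                [None if not np.isfinite(v) else float(v) for v in row]
                for row in self.values
            ],
        }


def sweep_helix_map(
    evaluate_config,
    tau_bar_values,
    tau_diff_values,
    metric_names=None,
    max_failed_fraction: float = 0.2,
    on_failure: str = "mask",
) -> dict[str, HelixMap]:
    """Run ``evaluate_config(HelixConfig) -> {metric: value}`` over a grid.

    Failed grid points are masked (recorded as NaN); more than
    ``max_failed_fraction`` failures aborts the sweep.
    """
    from .fibers import HelixConfig

    tb = np.asarray(tau_bar_values, dtype=float)
    td = np.asarray(tau_diff_values, dtype=float)
    if tb.size == 0 or td.size == 0:
        raise ValueError("empty helix grid")
    results: dict[str, np.ndarray] = {}
    n_failed = 0
    for i, b in enumerate(tb):
        for j, d in enumerate(td):
            try:
                vals = evaluate_config(HelixConfig(float(b), float(d)))
            except Exception as exc:
                if on_failure == "raise":
                    raise
                n_failed += 1
                if n_failed > max_failed_fraction * tb.size * td.size:
                    raise RuntimeError(
                        f"more than {max_failed_fraction:.0%} of grid points "
                        f"failed (last: {exc})"
                    ) from exc
                continue
            for name, v in vals.items():
                if name not in results:
                    results[name] = np.full((len(tb), len(td)), np.nan)
                results[name][i, j] = v
    if metric_names is not None:
        results = {k: v for k, v in results.items() if k in metric_names}
    return {
        name: HelixMap(tb.copy(), td.copy(), grid, metric=name)
        for name, grid in results.items()
    }


def find_optimal_point(hmap: HelixMap, criterion: str,
                       flat_tol: float = 1e-12) -> OptimalPoint:
    """Continuous optimum of the map interpolant within the grid hull.

    ``criterion`` is one of the named optimality criteria or plain "max"/"min".
    The optimum is flagged as on-boundary when it sits on the hull edge.
    """
    from scipy.optimize import minimize

    if criterion in CRITERIA:
        direction = CRITERIA[criterion][1]
    elif criterion in ("max", "min"):
        direction = criterion
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    vals = hmap.values[hmap.mask]
    if vals.size == 0:
        raise ValueError("empty map")
    if np.ptp(vals) < flat_tol:
        raise ValueError("no distinct optimum: map is flat within tolerance")

    sign = -1.0 if direction == "max" else 1.0
    fun = lambda x: sign * float(hmap.evaluate(x[0], x[1]))

    # multistart from a fine grid to avoid local optima of the spline
    tb_f = np.linspace(hmap.tau_bar[0], hmap.tau_bar[-1],
                       max(41, 6 * len(hmap.tau_bar)))
    td_f = np.linspace(hmap.tau_diff[0], hmap.tau_diff[-1],
                       max(41, 6 * len(hmap.tau_diff)))
    TB, TD = np.meshgrid(tb_f, td_f, indexing="ij")
    Z = np.asarray(hmap.evaluate(TB.ravel(), TD.ravel())).reshape(TB.shape)
    k = np.argmin(sign * Z)
    x0 = np.array([TB.ravel()[k], TD.ravel()[k]])

    bounds = [
        (hmap.tau_bar[0], hmap.tau_bar[-1]),
        (hmap.tau_diff[0], hmap.tau_diff[-1]),
    ]
    res = minimize(fun, x0, bounds=bounds, method="L-BFGS-B")
    x = res.x
    span_b = hmap.tau_bar[-1] - hmap.tau_bar[0]
    span_d = hmap.tau_diff[-1] - hmap.tau_diff[0]
    on_edge = (
        min(x[0] - bounds[0][0], bounds[0][1] - x[0]) < 1e-6 * max(span_b, 1.0)
        or min(x[1] - bounds[1][0], bounds[1][1] - x[1]) < 1e-6 * max(span_d, 1.0)
    )
    return OptimalPoint(
        tau_bar=float(x[0]),
        tau_diff=float(x[1]),
        value=float(hmap.evaluate(x[0], x[1])),
        direction=direction,
        on_boundary=bool(on_edge),
    )


def map_ssim(a: HelixMap, b: HelixMap) -> float:
    """SSIM between two maps on the same grid (min–max normalized pair).

    Gaussian-weighted 3-node window with standard stabilization constants;
    identical maps score exactly 1.
    """
    if not (
        np.array_equal(a.tau_bar, b.tau_bar)
        and np.array_equal(a.tau_diff, b.tau_diff)
    ):
        raise ValueError("maps are on different grids")
    if not (a.mask.all() and b.mask.all()):
        raise ValueError("SSIM requires fully evaluated maps")
    from skimage.metrics import structural_similarity

    def norm(v):
        lo, hi = v.min(), v.max()
        return (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)

    va, vb = norm(a.values), norm(b.values)
    if np.array_equal(va, vb):
        return 1.0
    return float(
        structural_similarity(
            va, vb, data_range=1.0, win_size=3, gaussian_weights=True,
            sigma=0.5,
        )
    )
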