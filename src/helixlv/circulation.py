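"""Closed-loop lumped-parameter (0D) model of the fetal circulation.

The network follows the Pennati-style fetal topology: left and right hearts
pump in parallel, coupled through the foramen ovale (right atrium to left
atrium) and the ductus arteriosus (pulmonary artery to descending aorta);
the placenta dominates the systemic bed.  Chambers are time-varying
elastances (the LV can instead be driven by an external FE model through a
pressure port); vascular segments are R–C elements; valves are smoothed
ideal diodes.

All default parameter values are surrogates from the cited Pennati model
family, recalibrated only through the global resistance/compliance scale
factors (k_R, k_C); every value is overridable.

Units: pressure mmHg, volume ml, time s internally (ms at interfaces),
resistance mmHg·s/ml, compliance ml/mmHg, elastance mmHg/ml.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp


@dataclass(frozen=True)
class ElastanceChamber:
    """Time-varying elastance chamber: P = E(t) (V - V0).

    E(t) ramps between Emin and Emax with a raised-cosine activation over
    ``duration`` starting at ``onset`` (fractions of the cycle).
    """

    Emin: float  # mmHg/ml
    Emax: float  # mmHg/ml
    V0: float  # ml, unstressed volume
    onset: float = 0.0  # fraction of cycle
    duration: float = 0.45  # fraction of cycle

    def activation(self, t_frac) -> np.ndarray:
        s = (np.asarray(t_frac) - self.onset) % 1.0
        inside = s < self.duration
        return np.where(
            inside, 0.5 * (1.0 - np.cos(2 * np.pi * s / self.duration)), 0.0
        )

    def elastance(self, t_frac) -> np.ndarray:
        return self.Emin + (self.Emax - self.Emin) * self.activation(t_frac)

    def pressure(self, V, t_frac) -> np.ndarray:
        return self.elastance(t_frac) * (np.asarray(V) - self.V0)


@dataclass(frozen=True)
class Compliance:
    """Passive vascular compartment: P = (V - V0)/C."""

    C: float  # ml/mmHg
    V0: float = 0.0  # ml

    def pressure(self, V) -> np.ndarray:
        return (np.asarray(V) - self.V0) / self.C


@dataclass(frozen=True)
class Branch:
    """Resistive connection; ``valve`` makes it a smoothed ideal diode."""

    name: str
    src: str
    dst: str
    R: float  # mmHg·s/ml
    valve: bool = False


@dataclass(frozen=True)
class CirculationParams:
    chambers: dict[str, ElastanceChamber]
    compliances: dict[str, Compliance]
    branches: tuple[Branch, ...]
    cycle_length: float = 400.0  # ms
    k_R: float = 1.0
    k_C: float = 1.0
    valve_smoothing: float = 0.01  # mmHg

    def node_names(self) -> list[str]:
        return list(self.chambers) + list(self.compliances)

    def validate(self):
        nodes = set(self.node_names())
        for br in self.branches:
            if br.src not in nodes or br.dst not in nodes:
                raise ValueError(f"branch {br.name!r} references unknown node")
            if br.R <= 0:
                raise ValueError(f"branch {br.name!r} has non-positive resistance")
        for name, c in self.compliances.items():
            if c.C <= 0:
                raise ValueError(f"compliance {name!r} must be positive")
        # closedness: every node must appear in at least one branch end
        touched = {br.src for br in self.branches} | {br.dst for br in self.branches}
        if touched != nodes:
            raise ValueError("network is not closed: isolated nodes present")


def apply_scale_factors(p: CirculationParams, k_R: float, k_C: float) -> CirculationParams:
    """Scale every resistance by k_R and every compliance by k_C."""
    if k_R <= 0 or k_C <= 0:
        raise ValueError("scale factors must be positive")
    branches = tuple(replace(br, R=br.R * k_R) for br in p.branches)
    compliances = {
        name: replace(c, C=c.C * k_C) for name, c in p.compliances.items()
    }
    return replace(p, branches=branches, compliances=compliances,
                   k_R=p.k_R * k_R, k_C=p.k_C * k_C)


def fetal_circulation_params(cycle_length: float = 400.0) -> CirculationParams:
    """Surrogate fetal network sized for a ~32 WG fetus.

    Targets physiologic scales (LV systolic ~40-45 mmHg, stroke volume
    ~1.5-1.7 ml at a 400 ms cycle, right-heart dominance through the
    fetal shunts); not a reproduction of any supplementary table.
    """
    chambers = {
        "LV": ElastanceChamber(Emin=2.3, Emax=38.0, V0=0.35, onset=0.0, duration=0.45),
        "RV": ElastanceChamber(Emin=2.0, Emax=32.0, V0=0.40, onset=0.0, duration=0.45),
        "LA": ElastanceChamber(Emin=1.2, Emax=3.0, V0=0.35, onset=0.88, duration=0.12),
        "RA": ElastanceChamber(Emin=1.2, Emax=3.0, V0=0.40, onset=0.88, duration=0.12),
    }
    compliances = {
        "AA": Compliance(C=0.045),  # ascending aorta + arch
        "AoD": Compliance(C=0.065),  # descending aorta
        "PA": Compliance(C=0.055),  # pulmonary trunk
        "Lungs": Compliance(C=0.12),  # pulmonary vascular bed
        "UB": Compliance(C=0.25),  # upper body / cerebral bed
        "Plac": Compliance(C=0.8),  # placenta + lower body
        "IVC": Compliance(C=0.55),
        "SVC": Compliance(C=0.35),
    }
    branches = (
        Branch("mitral", "LA", "LV", R=0.12, valve=True),
        Branch("aortic", "LV", "AA", R=0.10, valve=True),
        Branch("tricuspid", "RA", "RV", R=0.10, valve=True),
        Branch("pulmonic", "RV", "PA", R=0.09, valve=True),
        Branch("foramen_ovale", "RA", "LA", R=0.35, valve=True),
        Branch("ductus_arteriosus", "PA", "AoD", R=0.45),
        Branch("aortic_arch", "AA", "AoD", R=0.45),
        Branch("brachiocephalic", "AA", "UB", R=14.0),
        Branch("upper_venous", "UB", "SVC", R=1.2),
        Branch("svc_return", "SVC", "RA", R=0.25),
        Branch("pulm_arterial", "PA", "Lungs", R=16.0),
        Branch("pulm_venous", "Lungs", "LA", R=1.6),
        Branch("descending", "AoD", "Plac", R=5.2),
        Branch("placental_venous", "Plac", "IVC", R=1.0),
        Branch("ivc_return", "IVC", "RA", R=0.18),
    )
    p = CirculationParams(
        chambers=chambers,
        compliances=compliances,
        branches=branches,
        cycle_length=cycle_length,
    )
    p.validate()
    return p


def _initial_volumes(p: CirculationParams) -> dict[str, float]:
    v = {}
    for name, ch in p.chambers.items():
        v[name] = ch.V0 + 4.0 / ch.Emin  # ~4 mmHg filling
    for name, c in p.compliances.items():
        # prime arteries higher than veins for a fast spin-up
        base = {"AA": 35.0, "AoD": 35.0, "PA": 35.0}.get(name, 4.0)
        v[name] = c.V0 + base * c.C
    return v


@dataclass
class LVPort:
    """Coupling port replacing the LV elastance with an external FE model.

    The port holds the externally supplied LV pressure; the network
    integrates the LV volume from the valve flows, and the FE model is
    solved to that volume to return the next pressure.
    """

    pressure: float = 5.0  # mmHg


@dataclass
class CirculationState:
    """Time series over the simulated cycles (interfaces in ms)."""

    time_ms: np.ndarray
    volumes: dict[str, np.ndarray]
    pressures: dict[str, np.ndarray]
    flows: dict[str, np.ndarray]
    cycle_length_ms: float

    def to_frame(self) -> pd.DataFrame:
        cols = {"time_ms": self.time_ms}
        cols.update({f"V_{k}_ml": v for k, v in self.volumes.items()})
        cols.update({f"P_{k}_mmHg": v for k, v in self.pressures.items()})
        cols.update({f"Q_{k}_ml_per_s": v for k, v in self.flows.items()})
        return pd.DataFrame(cols)

    def cycle_slice(self, i: int) -> np.ndarray:
        T = self.cycle_length_ms
        return (self.time_ms >= i * T) & (self.time_ms < (i + 1) * T)

    def chamber_edv(self, name: str, cycle: int) -> float:
        sl = self.cycle_slice(cycle)
        return float(self.volumes[name][sl].max())

    def total_volume(self) -> np.ndarray:
        return np.sum([v for v in self.volumes.values()], axis=0)


def _network_rhs(p: CirculationParams, names, lv_pressure=None):
    idx = {n: i for i, n in enumerate(names)}
    eps = p.valve_smoothing

    def pressures(t_s, V):
        T = p.cycle_length / 1000.0
        t_frac = (t_s / T) % 1.0
        P = np.empty(len(names))
        for n, ch in p.chambers.items():
            if n == "LV" and lv_pressure is not None:
                P[idx[n]] = lv_pressure(t_s)
            else:
                P[idx[n]] = ch.pressure(V[idx[n]], t_frac)
        for n, c in p.compliances.items():
            P[idx[n]] = c.pressure(V[idx[n]])
        return P

    def flows(t_s, V):
        P = pressures(t_s, V)
        q = np.empty(len(p.branches))
        for k, br in enumerate(p.branches):
            dp = P[idx[br.src]] - P[idx[br.dst]]
            if br.valve:
                q[k] = (dp + np.sqrt(dp * dp + eps * eps)) / (2.0 * br.R)
            else:
                q[k] = dp / br.R
        return q, P

    def rhs(t_s, V):
        q, _ = flows(t_s, V)
        dV = np.zeros(len(names))
        for k, br in enumerate(p.branches):
            dV[idx[br.src]] -= q[k]
            dV[idx[br.dst]] += q[k]
        return dV

    return rhs, flows, pressures, idx


def simulate_circulation(
    p: CirculationParams,
    n_cycles: int = 12,
    samples_per_cycle: int = 200,
    initial_volumes: dict[str, float] | None = None,
    lv_pressure=None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    check_steady_state: bool = True,
) -> CirculationState:
    """Integrate the closed loop for ``n_cycles`` cycles.

    ``lv_pressure``, if given, is a callable t_s -> mmHg replacing the LV
    elastance (the FE coupling mode).  Raises if the integrator fails or,
    when ``check_steady_state``, if chamber end-diastolic volumes still
    change by more than 1% over the final cycle.
    """
    p.validate()
    names = p.node_names()
    rhs, flows_fn, _, idx = _network_rhs(p, names, lv_pressure)
    v0map = initial_volumes or _initial_volumes(p)
    V0 = np.array([v0map[n] for n in names])

    T = p.cycle_length / 1000.0
    t_end = n_cycles * T
    t_eval = np.linspace(0.0, t_end, n_cycles * samples_per_cycle + 1)
    sol = solve_ivp(
        rhs, (0.0, t_end), V0, method="BDF", t_eval=t_eval, rtol=rtol, atol=atol,
        max_step=T / 20.0,
    )
    if not sol.success:
        raise RuntimeError(f"circulation integration failed: {sol.message}")

    V = sol.y
    n_t = V.shape[1]
    qs = np.empty((len(p.branches), n_t))
    Ps = np.empty((len(names), n_t))
    for j in range(n_t):
        qs[:, j], Ps[:, j] = flows_fn(sol.t[j], V[:, j])

    state = CirculationState(
        time_ms=sol.t * 1000.0,
        volumes={n: V[idx[n]] for n in names},
        pressures={n: Ps[idx[n]] for n in names},
        flows={br.name: qs[k] for k, br in enumerate(p.branches)},
        cycle_length_ms=p.cycle_length,
    )

    total = state.total_volume()
    drift = np.abs(total - total[0]).max() / total[0]
    if drift > 1e-6 * n_cycles:
        raise RuntimeError(f"volume conservation drift {drift:.2e} too large")

    if check_steady_state and n_cycles >= 2:
        for name in p.chambers:
            if lv_pressure is not None and name == "LV":
                continue
            e1 = state.chamber_edv(name, n_cycles - 2)
            e2 = state.chamber_edv(name, n_cycles - 1)
            if abs(e2 - e1) / max(e1, 1e-9) > 0.01:
                raise RuntimeError(
                    f"{name} EDV still changes by "
                    f"{abs(e2 - e1) / e1:.2%} in the final cycle"
                )
    return state


def extract_pv_loop(state: CirculationState, chamber: str = "LV", cycle: int = -1):
    """(time_ms, pressure, volume) arrays of one chamber over one cycle."""
    n_cyc = int(round(state.time_ms[-1] / state.cycle_length_ms))
    i = cycle % n_cyc
    sl = state.cycle_slice(i)
    return (
        state.time_ms[sl],
        state.pressures[chamber][sl],
        state.volumes[chamber][sl],
    )
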