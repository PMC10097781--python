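"""Synthetic stand-ins for echo-derived inputs.

Real inputs come from 4D fetal echocardiography: smoothed LV volume-over-
time waveforms (motion tracking produces no isovolumetric plateaus),
global longitudinal/circumferential strains, and mildly asymmetric LV
shapes.  This module emulates those inputs so the whole pipeline runs and
is testable without any download: a C1 periodic volume waveform built from
a raised-cosine ejection and biphasic (early/late filling) raised-cosine
diastole; Gaussian-noised "image-derived" strains; and a volume-preserving
septal-lean shear for asymmetric geometry fixtures.

Fetal defaults: EDV 2.2 ml, cycle length 400 ms, stroke volume ~1.0 ml;
adult defaults: EDV 132 ml, stroke volume 81.8 ml, cycle 800 ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import GeometryError, LVMesh, apply_septal_lean


@dataclass(frozen=True)
class WaveformSpec:
    """Periodic LV volume waveform parameters.

    ``systolic_fraction`` is the ejection duration as a fraction of the
    cycle; ``early_filling_fraction`` balances early (E) versus late (A)
    diastolic filling.
    """

    edv: float = 2.2  # ml
    esv: float = 1.2  # ml
    cycle_length: float = 400.0  # ms
    systolic_fraction: float = 0.35
    early_filling_fraction: float = 0.6
    samples_per_cycle: int = 200

    def __post_init__(self):
        if not self.edv > self.esv > 0:
            raise ValueError("need EDV > ESV > 0")
        if not 0.0 < self.systolic_fraction < 1.0:
            raise ValueError("systolic_fraction must lie in (0, 1)")
        if not 0.0 <= self.early_filling_fraction <= 1.0:
            raise ValueError("early_filling_fraction must lie in [0, 1]")
        if self.samples_per_cycle < 8:
            raise ValueError("too few samples per cycle")


def adult_waveform_spec() -> WaveformSpec:
    return WaveformSpec(edv=132.0, esv=132.0 - 81.8, cycle_length=800.0)


@dataclass
class VolumeWaveform:
    """Sampled periodic volume waveform with an exact analytic evaluator."""

    times: np.ndarray  # ms, one period [0, T)
    volumes: np.ndarray  # ml
    spec: WaveformSpec

    @property
    def cycle_length(self) -> float:
        return self.spec.cycle_length

    @property
    def edv(self) -> float:
        return self.spec.edv

    @property
    def esv(self) -> float:
        return self.spec.esv

    @property
    def es_time(self) -> float:
        """Time of end-systole (minimum volume): end of ejection."""
        return self.spec.systolic_fraction * self.spec.cycle_length

    def volume_at(self, t_ms) -> np.ndarray:
        return _volume_model(np.asarray(t_ms, dtype=float), self.spec)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time_ms": self.times, "volume_ml": self.volumes})


def _raised_cosine(x) -> np.ndarray:
    """Monotone C1 ramp 0 -> 1 on [0, 1] with zero end slopes."""
    x = np.clip(x, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * x))


def _volume_model(t, spec: WaveformSpec) -> np.ndarray:
    T = spec.cycle_length
    t = np.mod(t, T)
    sv = spec.edv - spec.esv
    ts = spec.systolic_fraction * T

    # ejection: EDV -> ESV as a single raised cosine (C1 at both ends)
    in_sys = t < ts
    v_sys = spec.edv - sv * _raised_cosine(t / ts)

    # filling: biphasic E/A raised cosines, each C1, joined with zero slope
    s = (t - ts) / (T - ts)
    b = spec.early_filling_fraction
    v_dia = spec.esv + sv * (
        b * _raised_cosine(2.0 * s) + (1.0 - b) * _raised_cosine(2.0 * s - 1.0)
    )
    return np.where(in_sys, v_sys, v_dia)


def generate_volume_waveform(spec: WaveformSpec | None = None) -> VolumeWaveform:
    """Build the smoothed periodic waveform (ED at t = 0, no plateaus)."""
    spec = spec or WaveformSpec()
    t = np.linspace(0.0, spec.cycle_length, spec.samples_per_cycle,
                    endpoint=False)
    v = _volume_model(t, spec)
    wf = VolumeWaveform(times=t, volumes=v, spec=spec)
    # construction invariants
    tv = _volume_model(np.linspace(0, spec.cycle_length, 4001), spec)
    if abs(tv.max() - spec.edv) > 1e-3 * spec.edv or abs(
        tv.min() - spec.esv
    ) > 1e-3 * spec.esv:
        raise AssertionError("waveform extrema drifted from EDV/ESV")
    return wf


@dataclass(frozen=True)
class SyntheticStrainSpec:
    """Ground-truth global strains plus Gaussian observation noise."""

    eps_long: float  # fraction
    eps_circ: float  # fraction
    noise_sd: float = 0.0  # fraction
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def generate_synthetic_echo_strains(spec: SyntheticStrainSpec):
    """Noisy "image-derived" (eps_long, eps_circ); reproducible per seed."""
    from .metrics import StrainSummary

    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sd, size=2) if spec.noise_sd > 0 else (
        np.zeros(2)
    )
    return StrainSummary(
        eps_long=spec.eps_long + noise[0],
        eps_circ=spec.eps_circ + noise[1],
        source="synthetic-echo",
    )


def make_asymmetric_fixture(mesh: LVMesh, lean: float) -> LVMesh:
    """Shear the apex sideways to emulate a leaning, straight-septum LV.

    Volume-preserving (the shear is a function of z only); labels survive;
    raises if the lean inverts elements.
    """
    width = float(np.ptp(mesh.points[:, 0]))
    if abs(lean) > 0.5 * width:
        raise GeometryError("lean too large relative to the cavity width")
    return apply_septal_lean(mesh, lean)
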