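"""Run orchestration: single cases, helix-map sweeps, analysis, manifests.

A run is defined by a ``RunConfig`` (YAML/JSON-serializable); outputs land
in a run directory containing per-point PV loops and metric CSVs, map
JSON/CSV exports, and a manifest recording the status of every grid point
plus the configuration hash, so interrupted sweeps can be resumed.
Units at all interfaces: mm, ml, ms, mmHg, kPa, degrees.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .constitutive import ActiveParams, PassiveParams
from .fibers import HelixConfig, make_fiber_field
from .geometry import fetal_geometry_spec, generate_idealized_lv
from .io import read_msh, write_pv_loop
from .mechanics import NewtonError, SolverConfig, run_volume_constrained_cycle
from .metrics import (
    CRITERIA,
    HelixMap,
    compute_biomech_metrics,
    find_optimal_point,
    map_ssim,
    sweep_helix_map,
)
from .synthetic import WaveformSpec, generate_volume_waveform

DEFAULT_GRID = tuple(float(x) for x in np.arange(-90.0, 181.0, 15.0))
SMOKE_GRID = (-45.0, 45.0, 135.0)  # coarse 3x3 preset
LITERATURE_CONFIG = HelixConfig(10.0, 123.0)  # average fetal configuration


@dataclass
class RunConfig:
    shape: str = "symmetric"
    mesh_path: str | None = None  # overrides shape when given
    mesh_divisions: tuple[int, int, int] | None = None  # coarse test meshes
    tau_bar_grid: tuple = SMOKE_GRID
    tau_diff_grid: tuple = SMOKE_GRID
    driver: str = "volume_constrained"  # | "coupled"
    passive: dict = field(default_factory=dict)
    active: dict = field(default_factory=dict)
    waveform: dict = field(default_factory=dict)
    waveform_csv: str | None = None
    solver: dict = field(default_factory=dict)
    metrics: tuple = tuple(name for name, _ in CRITERIA.values())
    output_dir: str = "runs/out"
    resume: bool = False

    def validate(self):
        if self.driver not in ("volume_constrained", "coupled"):
            raise ValueError(f"unknown driver {self.driver!r}")
        if self.driver == "volume_constrained" and not (
            self.waveform or self.waveform_csv is not None
        ):
            raise ValueError(
                "volume_constrained driver needs a waveform spec or CSV"
            )
        if self.mesh_path is not None and not Path(self.mesh_path).exists():
            raise ValueError(f"mesh path {self.mesh_path!r} does not exist")
        if self.waveform_csv is not None and not Path(self.waveform_csv).exists():
            raise ValueError(f"waveform CSV {self.waveform_csv!r} does not exist")

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("resume", None)  # runtime flags don't change the science
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("tau_bar_grid", "tau_diff_grid", "metrics",
                    "mesh_divisions"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def _build_mesh(cfg: RunConfig):
    if cfg.mesh_path:
        return read_msh(cfg.mesh_path)
    spec = fetal_geometry_spec(cfg.shape)
    if cfg.mesh_divisions:
        nc, nl, nt = cfg.mesh_divisions
        return generate_idealized_lv(
            spec, n_circ=nc, n_long=nl, n_trans=nt, enforce_min_elements=False
        )
    return generate_idealized_lv(spec)


def _build_waveform(cfg: RunConfig):
    if cfg.waveform_csv:
        df = pd.read_csv(cfg.waveform_csv)
        t, v = df["time_ms"].to_numpy(), df["volume_ml"].to_numpy()
        spec = WaveformSpec(
            edv=float(v.max()), esv=float(v.min()),
            cycle_length=float(t[-1] + (t[1] - t[0])),
            samples_per_cycle=len(t),
        )
        wf = generate_volume_waveform(spec)
        return wf
    return generate_volume_waveform(WaveformSpec(**cfg.waveform))


@dataclass
class RunManifest:
    config_hash: str
    version: str
    points: dict  # "tb,td" -> {"status": ..., "files": [...]}

    @staticmethod
    def key(point: HelixConfig) -> str:
        return f"{point.tau_bar:g},{point.tau_diff:g}"

    def counts(self) -> dict:
        out = {"done": 0, "failed": 0, "masked": 0}
        for rec in self.points.values():
            out[rec["status"]] = out.get(rec["status"], 0) + 1
        return out

    def save(self, path):
        Path(path).write_text(json.dumps(
            {"config_hash": self.config_hash, "version": self.version,
             "points": self.points},
            indent=2, sort_keys=True,
        ))

    @classmethod
    def load(cls, path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        return cls(d["config_hash"], d["version"], d["points"])


class CaseRunner:
    """Holds the shared mesh/waveform; runs one helix configuration."""

    def __init__(self, cfg: RunConfig):
        cfg.validate()
        self.cfg = cfg
        self.mesh = _build_mesh(cfg)
        self.waveform = _build_waveform(cfg)
        self.passive = PassiveParams(**cfg.passive)
        self.active = ActiveParams(**cfg.active)
        self.solver_cfg = SolverConfig(**cfg.solver)
        self.outdir = Path(cfg.output_dir)
        self.outdir.mkdir(parents=True, exist_ok=True)

    def run_point(self, point: HelixConfig):
        fibers, _, _ = make_fiber_field(
            self.mesh, point, self.solver_cfg.quadrature_degree
        )
        if self.cfg.driver == "coupled":
            from .circulation import fetal_circulation_params
            from .mechanics import run_coupled_cycle

            result, _ = run_coupled_cycle(
                self.mesh, fibers, self.passive, self.active,
                fetal_circulation_params(self.waveform.cycle_length),
                self.solver_cfg,
            )
        else:
            result = run_volume_constrained_cycle(
                self.mesh, fibers, self.passive, self.active,
                self.waveform, self.solver_cfg,
            )
        return result

    def point_dir(self, point: HelixConfig) -> Path:
        d = self.outdir / f"tb{point.tau_bar:+08.2f}_td{point.tau_diff:+08.2f}"
        d.mkdir(parents=True, exist_ok=True)
        return d


def run_case(cfg: RunConfig, point: HelixConfig, runner: CaseRunner | None = None):
    """Run one helix configuration; write PV loop + metrics; return metrics."""
    runner = runner or CaseRunner(cfg)
    result = runner.run_point(point)
    metrics = compute_biomech_metrics(result)

    d = runner.point_dir(point)
    write_pv_loop(d / "pv_loop.csv", result.loop.time_ms,
                  result.loop.pressure_mmhg, result.loop.volume_ml)
    row = {"tau_bar_deg": point.tau_bar, "tau_diff_deg": point.tau_diff}
    row.update(metrics.to_dict())
    pd.DataFrame([row]).to_csv(d / "metrics.csv", index=False)
    return metrics, d


def run_sweep(cfg: RunConfig) -> tuple[dict[str, HelixMap], RunManifest]:
    """Sweep the helix grid; resumable; returns maps and the manifest."""
    runner = CaseRunner(cfg)
    manifest_path = runner.outdir / "manifest.json"
    manifest = RunManifest(cfg.config_hash(), __version__, {})
    if cfg.resume and manifest_path.exists():
        prev = RunManifest.load(manifest_path)
        if prev.config_hash == manifest.config_hash:
            manifest = prev

    def evaluate(point: HelixConfig) -> dict:
        key = RunManifest.key(point)
        rec = manifest.points.get(key)
        d = runner.point_dir(point)
        if rec and rec["status"] == "done" and (d / "metrics.csv").exists():
            row = pd.read_csv(d / "metrics.csv").iloc[0]
            return {k: float(row[k]) for k in runner.cfg.metrics}
        try:
            metrics, _ = run_case(cfg, point, runner)
        except (NewtonError, RuntimeError) as exc:
            manifest.points[key] = {"status": "failed", "error": str(exc)}
            manifest.save(manifest_path)
            raise
        manifest.points[key] = {
            "status": "done",
            "files": [str(d / "pv_loop.csv"), str(d / "metrics.csv")],
        }
        manifest.save(manifest_path)
        return {k: v for k, v in metrics.to_dict().items()
                if k in runner.cfg.metrics}

    maps = sweep_helix_map(
        evaluate, cfg.tau_bar_grid, cfg.tau_diff_grid,
        metric_names=runner.cfg.metrics,
    )
    for key in [RunManifest.key(HelixConfig(b, d))
                for b in cfg.tau_bar_grid for d in cfg.tau_diff_grid]:
        rec = manifest.points.get(key)
        if rec and rec["status"] == "failed":
            manifest.points[key]["status"] = "masked"
    manifest.save(manifest_path)

    for name, hm in maps.items():
        (runner.outdir / f"map_{name}.json").write_text(
            json.dumps(hm.to_dict(), indent=2)
        )
        _map_to_csv(hm, runner.outdir / f"map_{name}.csv")
    return maps, manifest


def _map_to_csv(hm: HelixMap, path):
    rows = []
    for i, b in enumerate(hm.tau_bar):
        for j, d in enumerate(hm.tau_diff):
            rows.append({
                "tau_bar_deg": b, "tau_diff_deg": d,
                hm.metric or "value": hm.values[i, j],
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def load_map(path) -> HelixMap:
    d = json.loads(Path(path).read_text())
    values = np.array(
        [[np.nan if v is None else v for v in row] for row in d["values"]]
    )
    return HelixMap(np.array(d["tau_bar_deg"]), np.array(d["tau_diff_deg"]),
                    values, metric=d.get("metric", ""))


def analyze_maps(maps: dict[str, HelixMap]) -> dict:
    """Locate the four criterion optima (where the metric map is present)."""
    out = {}
    for crit, (metric, _) in CRITERIA.items():
        if metric in maps:
            opt = find_optimal_point(maps[metric], crit)
            out[crit] = {
                "tau_bar_deg": opt.tau_bar,
                "tau_diff_deg": opt.tau_diff,
                "value": opt.value,
                "on_boundary": opt.on_boundary,
            }
    return out


def compare_map_sets(ref: dict[str, HelixMap], other: dict[str, HelixMap]) -> dict:
    """SSIM of each shared metric map, the reference set first."""
    return {
        name: map_ssim(ref[name], other[name])
        for name in sorted(set(ref) & set(other))
    }
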