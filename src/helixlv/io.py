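"""Mesh and configuration I/O.

Meshes are exchanged in the Gmsh 2.2 ASCII dialect (tet10 volume elements,
tri6 boundary faces with physical surface tags "endo", "epi", "base").
Parameter files are YAML/JSON mappings with explicit units in comments.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .geometry import LVMesh

_SURFACE_TAGS = {"endo": 1, "epi": 2, "base": 3}
_VOLUME_TAG = 4
_TRI6 = 9
_TET10 = 11


def write_msh(path, mesh: LVMesh, point_data: dict[str, np.ndarray] | None = None):
    """Write an LV mesh (and optional per-node vector/scalar fields)."""
    path = Path(path)
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat"]
    lines += ["$PhysicalNames", str(len(_SURFACE_TAGS) + 1)]
    for name, tag in _SURFACE_TAGS.items():
        lines.append(f'2 {tag} "{name}"')
    lines.append(f'3 {_VOLUME_TAG} "wall"')
    lines.append("$EndPhysicalNames")

    lines += ["$Nodes", str(mesh.n_points)]
    for i, p in enumerate(mesh.points, start=1):
        lines.append(f"{i} {p[0]:.16g} {p[1]:.16g} {p[2]:.16g}")
    lines.append("$EndNodes")

    elems = []
    eid = 1
    for label, tag in _SURFACE_TAGS.items():
        for face in mesh.facets.get(label, ()):
            nodes = " ".join(str(n + 1) for n in face)
            elems.append(f"{eid} {_TRI6} 2 {tag} {tag} {nodes}")
            eid += 1
    for cell in mesh.cells:
        nodes = " ".join(str(n + 1) for n in cell)
        elems.append(f"{eid} {_TET10} 2 {_VOLUME_TAG} {_VOLUME_TAG} {nodes}")
        eid += 1
    lines += ["$Elements", str(len(elems)), *elems, "$EndElements"]

    for name, data in (point_data or {}).items():
        data = np.asarray(data, dtype=float)
        comps = 1 if data.ndim == 1 else data.shape[1]
        lines += ["$NodeData", "1", f'"{name}"', "1", "0.0", "3", "0",
                  str(comps), str(mesh.n_points)]
        for i in range(mesh.n_points):
            row = np.atleast_1d(data[i])
            lines.append(str(i + 1) + " " + " ".join(f"{v:.16g}" for v in row))
        lines.append("$EndNodeData")

    path.write_text("\n".join(lines) + "\n")


def read_msh(path) -> LVMesh:
    """Read a Gmsh 2.2 ASCII mesh written by :func:`write_msh`."""
    text = Path(path).read_text().split("\n")
    it = iter(text)

    def seek(tag):
        for line in it:
            if line.strip() == tag:
                return True
        return False

    phys_names = {}
    lines = list(text)
    if "$PhysicalNames" in lines:
        i = lines.index("$PhysicalNames")
        n = int(lines[i + 1])
        for row in lines[i + 2 : i + 2 + n]:
            parts = row.split()
            phys_names[int(parts[1])] = parts[2].strip('"')
    tag_to_label = {v: k for k, v in _SURFACE_TAGS.items()}
    for tag, name in phys_names.items():
        if name in _SURFACE_TAGS:
            tag_to_label[tag] = name

    i = lines.index("$Nodes")
    n_nodes = int(lines[i + 1])
    points = np.empty((n_nodes, 3))
    for k, row in enumerate(lines[i + 2 : i + 2 + n_nodes]):
        parts = row.split()
        points[k] = [float(x) for x in parts[1:4]]

    i = lines.index("$Elements")
    n_el = int(lines[i + 1])
    cells, facets = [], {"endo": [], "epi": [], "base": []}
    for row in lines[i + 2 : i + 2 + n_el]:
        parts = [int(x) for x in row.split()]
        etype, ntags = parts[1], parts[2]
        tags = parts[3 : 3 + ntags]
        nodes = [x - 1 for x in parts[3 + ntags :]]
        if etype == _TET10:
            cells.append(nodes)
        elif etype == _TRI6:
            label = tag_to_label.get(tags[0] if tags else -1)
            if label:
                facets[label].append(nodes)
    return LVMesh(
        points=points,
        cells=np.array(cells, dtype=np.int64),
        facets={k: np.array(v, dtype=np.int64) for k, v in facets.items()},
    )


def load_params(path) -> dict:
    """Load a YAML or JSON parameter mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def dump_params(obj: dict, path):
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(obj, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(obj, sort_keys=True))


def write_pv_loop(path, time_ms, pressure_mmhg, volume_ml):
    """PV loop as CSV with unit-bearing headers."""
    import pandas as pd

    pd.DataFrame(
        {"time_ms": time_ms, "pressure_mmHg": pressure_mmhg, "volume_ml": volume_ml}
    ).to_csv(path, index=False)
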