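"""Point-cloud readers for plain-text XYZ, JSON, and ASCII OBJ/PLY vertices.

Only vertex positions are read from mesh formats; faces, normals and colors
are ignored.  Binary PLY is not supported.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np


def _load_xyz(text: str) -> np.ndarray:
    rows = []
    for line in text.strip().splitlines():
        parts = line.split()
        if not parts or parts[0].startswith("#"):
            continue
        rows.append([float(v) for v in parts[-3:]])  # tolerate a leading label
    return np.array(rows, dtype=float)


def _load_obj_vertices(text: str) -> np.ndarray:
    rows = []
    for line in text.splitlines():
        parts = line.split()
        if parts and parts[0] == "v":
            rows.append([float(v) for v in parts[1:4]])
    if not rows:
        raise ValueError("no vertex ('v') lines found in OBJ file")
    return np.array(rows, dtype=float)


def _load_ply_vertices(text: str) -> np.ndarray:
    lines = text.splitlines()
    if not lines or lines[0].strip() != "ply":
        raise ValueError("not a PLY file")
    n_vertices = None
    coord_idx: dict[str, int] = {}
    prop_count = 0
    in_vertex_element = False
    body_start = None
    for i, line in enumerate(lines[1:], start=1):
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "format" and parts[1] != "ascii":
            raise ValueError("only ASCII PLY is supported")
        if parts[0] == "element":
            in_vertex_element = parts[1] == "vertex"
            if in_vertex_element:
                n_vertices = int(parts[2])
        elif parts[0] == "property" and in_vertex_element:
            if parts[-1] in ("x", "y", "z"):
                coord_idx[parts[-1]] = prop_count
            prop_count += 1
        elif parts[0] == "end_header":
            body_start = i + 1
            break
    if n_vertices is None or body_start is None or set(coord_idx) != {"x", "y", "z"}:
        raise ValueError("PLY header lacks a vertex element with x/y/z properties")
    rows = []
    for line in lines[body_start : body_start + n_vertices]:
        vals = line.split()
        rows.append([float(vals[coord_idx[c]]) for c in ("x", "y", "z")])
    return np.array(rows, dtype=float)


def load_cloud(path: Union[str, Path]) -> np.ndarray:
    """Read an (n, 3) point cloud from .xyz/.txt, .json, .obj or ASCII .ply."""
    path = Path(path)
    text = path.read_text()
    suffix = path.suffix.lower()
    if suffix == ".obj":
        return _load_obj_vertices(text)
    if suffix == ".ply":
        return _load_ply_vertices(text)
    if suffix == ".json":
        data = json.loads(text)
        if isinstance(data, dict):
            return np.array(list(data.values()), dtype=float)
        return np.array(data, dtype=float)
    return _load_xyz(text)


def save_cloud(points: np.ndarray, path: Union[str, Path]) -> None:
    """Write an (n, 3) cloud as plain-text XYZ."""
    np.savetxt(path, np.atleast_2d(points), fmt="%.9g")
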