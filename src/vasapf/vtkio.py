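"""Minimal legacy-ASCII VTK unstructured-grid writer/reader.

Only the subset this package emits is supported: POINTS, CELLS (quad/hex),
POINT_DATA vectors+scalars, CELL_DATA scalars.  Output is bit-deterministic
(fixed ``%.17g`` formatting) so seeded reruns produce identical files.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np

_CELL_TYPE = {4: 9, 8: 12}   # quad4, hex8


def write_vtk(mesh, point_data: dict, cell_data: dict, path,
              comment: str = "vasapf output") -> None:
    coords = np.asarray(mesh.coords, dtype=float)
    if coords.shape[1] == 2:
        coords = np.column_stack([coords, np.zeros(len(coords))])
    elems = np.asarray(mesh.elems)
    nen = elems.shape[1]
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(comment.replace("\n", " ") + "\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(coords)} double\n")
        for row in coords:
            fh.write(" ".join("%.17g" % v for v in row) + "\n")
        fh.write(f"CELLS {len(elems)} {len(elems) * (nen + 1)}\n")
        for row in elems:
            fh.write(str(nen) + " " + " ".join(str(v) for v in row) + "\n")
        fh.write(f"CELL_TYPES {len(elems)}\n")
        for _ in range(len(elems)):
            fh.write(f"{_CELL_TYPE[nen]}\n")

        def dump(data: dict, n: int, header: str):
            if not data:
                return
            fh.write(f"{header} {n}\n")
            for name, arr in data.items():
                arr = np.asarray(arr, dtype=float)
                if arr.ndim == 2:
                    vec = arr
                    if vec.shape[1] == 2:
                        vec = np.column_stack([vec, np.zeros(len(vec))])
                    fh.write(f"VECTORS {name} double\n")
                    for row in vec:
                        fh.write(" ".join("%.17g" % v for v in row) + "\n")
                else:
                    fh.write(f"SCALARS {name} double 1\n")
                    fh.write("LOOKUP_TABLE default\n")
                    for v in arr:
                        fh.write("%.17g\n" % v)

        dump(point_data, len(coords), "POINT_DATA")
        dump(cell_data, len(elems), "CELL_DATA")


def read_vtk(path):
    """Read back a file produced by :func:`write_vtk`.  Returns
    (points (n,3), cells (ne,nen), point_data, cell_data)."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0

    def tokens():
        nonlocal i
        while i < len(lines):
            t = lines[i].split()
            i += 1
            if t:
                yield t

    it = tokens()
    pts = cells = None
    point_data, cell_data = {}, {}
    target = None
    for tok in it:
        key = tok[0].upper()
        if key == "POINTS":
            n = int(tok[1])
            pts = np.array([[float(v) for v in next(it)] for _ in range(n)])
        elif key == "CELLS":
            n = int(tok[1])
            rows = [next(it) for _ in range(n)]
            cells = np.array([[int(v) for v in r[1:]] for r in rows])
        elif key == "CELL_TYPES":
            for _ in range(int(tok[1])):
                next(it)
        elif key == "POINT_DATA":
            target = point_data
        elif key == "CELL_DATA":
            target = cell_data
        elif key == "VECTORS":
            n = len(pts) if target is point_data else len(cells)
            target[tok[1]] = np.array([[float(v) for v in next(it)]
                                       for _ in range(n)])
        elif key == "SCALARS":
            name = tok[1]
            next(it)   # LOOKUP_TABLE
            n = len(pts) if target is point_data else len(cells)
            target[name] = np.array([float(next(it)[0]) for _ in range(n)])
    return pts, cells, point_data, cell_data


def write_manifest(path, entries: list) -> None:
    """Time-series manifest: list of {step, time, file}."""
    Path(path).write_text(json.dumps(entries, indent=1, sort_keys=True))
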