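"""Output writers: unit-annotated CSV tables and legacy-ASCII VTK grids.

All writes are atomic (temp file + rename) so a crashed run never leaves a
truncated artifact behind.
"""

from __future__ import annotations

import json
import os
import tempfile
from contextlib import contextmanager
from pathlib import Path

import numpy as np

__all__ = ["atomic_write", "write_table", "write_vtk_structured",
           "write_manifest"]


@contextmanager
def atomic_write(path, mode="w"):
    """Write to a temp file in the target directory, rename on success."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name + ".tmp")
    try:
        with os.fdopen(fd, mode) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        os.unlink(tmp)
        raise


def write_table(path, columns: dict[str, np.ndarray], units: dict[str, str]):
    """CSV with a ``name [unit]`` header per column."""
    names = list(columns)
    header = ",".join(f"{n} [{units.get(n, '-')}]" for n in names)
    data = np.column_stack([np.asarray(columns[n], float) for n in names])
    with atomic_write(path) as fh:
        fh.write(header + "\n")
        np.savetxt(fh, data, delimiter=",", fmt="%.9e")


def write_vtk_structured(path, x: np.ndarray, y: np.ndarray,
                         fields: dict[str, np.ndarray]):
    """Legacy-ASCII VTK structured grid of 2-D nodal fields.

    ``fields`` maps names to (nx, ny) arrays on the tensor grid ``x, y``;
    complex fields are split into ``<name>_re`` / ``<name>_im``.
    """
    nx, ny = len(x), len(y)
    split = {}
    for name, arr in fields.items():
        if np.iscomplexobj(arr):
            split[name + "_re"] = arr.real
            split[name + "_im"] = arr.imag
        else:
            split[name] = np.asarray(arr, float)
    for name, arr in split.items():
        if arr.shape != (nx, ny):
            raise ValueError(f"field {name!r} shape {arr.shape} != ({nx}, {ny})")
    with atomic_write(path) as fh:
        fh.write("# vtk DataFile Version 3.0\ncochstream field export\n"
                 "ASCII\nDATASET STRUCTURED_GRID\n")
        fh.write(f"DIMENSIONS {nx} {ny} 1\n")
        fh.write(f"POINTS {nx * ny} double\n")
        X, Y = np.meshgrid(x, y, indexing="xy")   # VTK: x fastest
        pts = np.column_stack([X.ravel(), Y.ravel(), np.zeros(X.size)])
        np.savetxt(fh, pts, fmt="%.9e")
        fh.write(f"POINT_DATA {nx * ny}\n")
        for name, arr in split.items():
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, arr.T.ravel()[:, None], fmt="%.9e")


def write_manifest(path, config_dict: dict, seed: int | None, extra=None):
    """Run manifest: resolved configuration, code version, seed."""
    from . import __version__

    doc = {
        "cochstream_version": __version__,
        "seed": seed,
        "config": config_dict,
    }
    if extra:
        doc.update(extra)
    with atomic_write(path) as fh:
        json.dump(doc, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
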