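"""Raster I/O: ESRI ASCII grids with a JSON sidecar for stack metadata.

The ASCII grid (.asc) format stores one layer per file with a six-line
header (ncols, nrows, xllcorner, yllcorner, cellsize, NODATA_value).  A
covariate stack is written as a directory of .asc files plus a
``stack.json`` naming the layers, scenario id and grid convention; a
suitability surface is one .asc plus a ``<name>.json`` sidecar.  Values
round-trip to better than 1e-6; the nodata mask and georeferencing
round-trip exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .grids import CovariateStack, SuitabilitySurface

__all__ = [
    "write_ascii_grid",
    "read_ascii_grid",
    "write_stack",
    "read_stack",
    "write_surface",
    "read_surface",
]

NODATA = -9999.0


def write_ascii_grid(
    path: str | Path,
    values: np.ndarray,
    mask: np.ndarray,
    cell_size: float,
    origin: tuple[float, float],
    nodata: float = NODATA,
) -> None:
    """Write one layer as an ESRI ASCII grid (cell-centre origin convention)."""
    values = np.asarray(values, dtype=float)
    n_rows, n_cols = values.shape
    x0, y0 = origin
    # origin is the NW cell centre; the format wants the lower-left corner
    xll = x0 - cell_size / 2.0
    yll = y0 - (n_rows - 1) * cell_size - cell_size / 2.0
    out = values.copy()
    out[np.asarray(mask, dtype=bool)] = nodata
    header = (
        f"ncols {n_cols}\n"
        f"nrows {n_rows}\n"
        f"xllcorner {xll!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {cell_size!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, np.ndarray, float, tuple[float, float]]:
    """Read an ESRI ASCII grid -> (values, mask, cell_size, origin)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    values = values.reshape(n_rows, n_cols)
    cell = header["cellsize"]
    nodata = header.get("nodata_value", NODATA)
    mask = values == nodata
    values = values.copy()
    values[mask] = 0.0
    x0 = header["xllcorner"] + cell / 2.0
    y0 = header["yllcorner"] + cell / 2.0 + (n_rows - 1) * cell
    return values, mask, cell, (x0, y0)


def write_stack(directory: str | Path, stack: CovariateStack) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, grid in stack.layers.items():
        write_ascii_grid(directory / f"{name}.asc", grid, stack.mask, stack.cell_size, stack.origin)
    meta = {
        "layers": sorted(stack.layers),
        "scenario_id": stack.scenario_id,
        "cell_size": stack.cell_size,
        "origin": list(stack.origin),
        "convention": "projected metres, cell-centre registration, row 0 = north",
    }
    (directory / "stack.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_stack(directory: str | Path) -> CovariateStack:
    """Read a stack directory; all layers must share extent and mask."""
    directory = Path(directory)
    meta = json.loads((directory / "stack.json").read_text())
    layers: dict[str, np.ndarray] = {}
    ref = None
    mask = None
    for name in meta["layers"]:
        values, m, cell, origin = read_ascii_grid(directory / f"{name}.asc")
        geo = (values.shape, cell, origin)
        if ref is None:
            ref, mask = geo, m
        elif geo != ref or not np.array_equal(m, mask):
            raise ValueError(f"layer {name!r} extent/mask differs from the other layers")
        layers[name] = values
    return CovariateStack(
        cell_size=meta["cell_size"],
        origin=tuple(meta["origin"]),
        layers=layers,
        mask=mask,
        scenario_id=meta["scenario_id"],
    )


def write_surface(path: str | Path, surface: SuitabilitySurface) -> None:
    path = Path(path)
    write_ascii_grid(path, surface.values, surface.mask, surface.cell_size, surface.origin)
    meta = {
        "species": surface.species,
        "scenario_id": surface.scenario_id,
        "output_kind": surface.output_kind,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_surface(path: str | Path) -> SuitabilitySurface:
    path = Path(path)
    values, mask, cell, origin = read_ascii_grid(path)
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return SuitabilitySurface(
        values=values,
        mask=mask,
        species=meta.get("species", ""),
        scenario_id=meta.get("scenario_id", "current"),
        output_kind=meta.get("output_kind", "logistic"),
        cell_size=cell,
        origin=origin,
    )
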