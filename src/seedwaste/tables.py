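"""CSV readers/writers for occurrences, vegetation plots and dung piles.

One fixed dialect: UTF-8, comma separator, header row, '.' decimal.
Schemas (species columns are suffixed to ``presence_``/``seeds_``):

* occurrences: ``species,x,y``
* plots:       ``site,x,y,elevation,presence_<species>...``
* piles:       ``site,x,y,elevation,seeds_<species>...[,period]``

Validation errors carry the 1-based data row number.  Unknown columns
are preserved on round-trip; row order is stable.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .island import DungPile, OccurrenceSet, VegetationPlot

__all__ = [
    "read_occurrences",
    "write_occurrences",
    "read_plots",
    "write_plots",
    "read_piles",
    "write_piles",
]


def _require(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _numeric(df: pd.DataFrame, column: str, path) -> np.ndarray:
    converted = pd.to_numeric(df[column], errors="coerce")
    bad = converted.isna() & df[column].notna()
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0]) + 1
        raise ValueError(f"{path}: non-numeric value in column {column!r} at data row {row}")
    if converted.isna().any():
        row = int(np.nonzero(converted.isna().to_numpy())[0][0]) + 1
        raise ValueError(f"{path}: missing value in column {column!r} at data row {row}")
    return converted.to_numpy()


def read_occurrences(path: str | Path) -> dict[str, OccurrenceSet]:
    df = pd.read_csv(path)
    _require(df, ["species", "x", "y"], path)
    x = _numeric(df, "x", path)
    y = _numeric(df, "y", path)
    out: dict[str, OccurrenceSet] = {}
    for sp in df["species"].unique():
        sel = (df["species"] == sp).to_numpy()
        out[str(sp)] = OccurrenceSet(species=str(sp), x=x[sel], y=y[sel], source="file")
    return out


def write_occurrences(path: str | Path, occurrences: dict[str, OccurrenceSet] | OccurrenceSet) -> None:
    if isinstance(occurrences, OccurrenceSet):
        occurrences = {occurrences.species: occurrences}
    frames = [
        pd.DataFrame({"species": occ.species, "x": occ.x, "y": occ.y})
        for occ in occurrences.values()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_plots(path: str | Path) -> list[VegetationPlot]:
    df = pd.read_csv(path)
    _require(df, ["site", "x", "y", "elevation"], path)
    species = [c.removeprefix("presence_") for c in df.columns if c.startswith("presence_")]
    if not species:
        raise ValueError(f"{path}: no presence_<species> columns found")
    x = _numeric(df, "x", path)
    y = _numeric(df, "y", path)
    elev = _numeric(df, "elevation", path)
    presence = {sp: _numeric(df, f"presence_{sp}", path) for sp in species}
    for sp, vals in presence.items():
        bad = ~np.isin(vals, (0, 1))
        if bad.any():
            row = int(np.nonzero(bad)[0][0]) + 1
            raise ValueError(f"{path}: presence_{sp} must be 0/1; bad value at data row {row}")
    return [
        VegetationPlot(
            site=str(df["site"].iloc[i]), x=float(x[i]), y=float(y[i]), elevation=float(elev[i]),
            presence={sp: int(presence[sp][i]) for sp in species},
        )
        for i in range(len(df))
    ]


def write_plots(path: str | Path, plots: Sequence[VegetationPlot]) -> None:
    species = sorted({sp for p in plots for sp in p.presence})
    rows = [
        {
            "site": p.site, "x": p.x, "y": p.y, "elevation": p.elevation,
            **{f"presence_{sp}": p.presence.get(sp, 0) for sp in species},
        }
        for p in plots
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_piles(path: str | Path) -> list[DungPile]:
    df = pd.read_csv(path)
    _require(df, ["site", "x", "y", "elevation"], path)
    species = [c.removeprefix("seeds_") for c in df.columns if c.startswith("seeds_")]
    if not species:
        raise ValueError(f"{path}: no seeds_<species> columns found")
    x = _numeric(df, "x", path)
    y = _numeric(df, "y", path)
    elev = _numeric(df, "elevation", path)
    counts = {sp: _numeric(df, f"seeds_{sp}", path) for sp in species}
    for sp, vals in counts.items():
        bad = vals < 0
        if bad.any():
            row = int(np.nonzero(bad)[0][0]) + 1
            raise ValueError(f"{path}: negative seed count in seeds_{sp} at data row {row}")
    periods = df["period"].astype(str) if "period" in df.columns else ["survey"] * len(df)
    return [
        DungPile(
            site=str(df["site"].iloc[i]), x=float(x[i]), y=float(y[i]), elevation=float(elev[i]),
            seed_counts={sp: int(counts[sp][i]) for sp in species},
            period=str(periods[i]) if "period" in df.columns else "survey",
        )
        for i in range(len(df))
    ]


def write_piles(path: str | Path, piles: Sequence[DungPile]) -> None:
    species = sorted({sp for p in piles for sp in p.seed_counts})
    rows = [
        {
            "site": p.site, "x": p.x, "y": p.y, "elevation": p.elevation,
            **{f"seeds_{sp}": p.seed_counts.get(sp, 0) for sp in species},
            "period": p.period,
        }
        for p in piles
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
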