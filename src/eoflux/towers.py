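"""Eddy-covariance tower records and their CSV I/O.

A tower record holds one day (or one 8-day composite) of the surface energy
budget at a flux site: net radiation Rn, ground heat flux G, and the
uncorrected turbulent fluxes H_ori and LE_ori, all in W/m². Records carry a
biome code from the eight-class set used for grouped validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = ["TowerRecord", "BIOME_CODES", "read_towers", "write_towers"]

# Eight biome classes (deciduous/evergreen needleleaf forest share a class;
# both spellings are accepted).
BIOME_CODES = frozenset(
    {"CRO", "DBF", "DNF", "ENF", "EBF", "MF", "SAW", "SHR", "GRA"}
)

_REQUIRED_COLUMNS = ("time", "Rn", "G", "H", "LE", "biome")


@dataclass
class TowerRecord:
    """One time step of tower energy-budget observations (all fluxes W/m²)."""

    time: object
    Rn: float
    G: float
    H_ori: float
    LE_ori: float
    biome: str
    lat: float = np.nan
    lon: float = np.nan
    row: int | None = None  # pixel indices into a co-registered grid, if known
    col: int | None = None
    incomplete: bool = False

    def __post_init__(self) -> None:
        if self.biome not in BIOME_CODES:
            raise ValidationError(f"unknown biome code {self.biome!r}")
        terms = (self.Rn, self.G, self.H_ori, self.LE_ori)
        if any(t is None or not np.isfinite(t) for t in terms):
            self.incomplete = True


def read_towers(path: str | Path) -> list[TowerRecord]:
    """Read tower records from CSV.

    The file must have header columns ``time, Rn, G, H, LE, biome``
    (``lat``, ``lon``, ``row``, ``col`` optional). Rows with a missing
    energy term are returned flagged ``incomplete``, never dropped. An
    unknown biome code raises :class:`ValidationError` naming the row.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    records: list[TowerRecord] = []
    for i, r in df.iterrows():
        biome = str(r["biome"]).strip().upper()
        if biome not in BIOME_CODES:
            raise ValidationError(
                f"{path}: row {i}: unknown biome code {r['biome']!r} "
                f"(expected one of {sorted(BIOME_CODES)})"
            )
        records.append(
            TowerRecord(
                time=pd.to_datetime(r["time"]) if not _is_number(r["time"]) else r["time"],
                Rn=_to_float(r["Rn"]),
                G=_to_float(r["G"]),
                H_ori=_to_float(r["H"]),
                LE_ori=_to_float(r["LE"]),
                biome=biome,
                lat=_to_float(r.get("lat", np.nan)),
                lon=_to_float(r.get("lon", np.nan)),
                row=int(r["row"]) if "row" in df.columns and pd.notna(r["row"]) else None,
                col=int(r["col"]) if "col" in df.columns and pd.notna(r["col"]) else None,
            )
        )
    return records


def write_towers(records: list[TowerRecord], path: str | Path) -> None:
    """Write tower records to CSV (columns time, Rn, G, H, LE, biome, ...)."""
    df = pd.DataFrame(
        {
            "time": [r.time for r in records],
            "Rn": [r.Rn for r in records],
            "G": [r.G for r in records],
            "H": [r.H_ori for r in records],
            "LE": [r.LE_ori for r in records],
            "biome": [r.biome for r in records],
            "lat": [r.lat for r in records],
            "lon": [r.lon for r in records],
            "row": [r.row for r in records],
            "col": [r.col for r in records],
        }
    )
    df.to_csv(path, index=False)


def _to_float(x) -> float:
    try:
        v = float(x)
    except (TypeError, ValueError):
        return np.nan
    return v


def _is_number(x) -> bool:
    return isinstance(x, (int, float, np.integer, np.floating))
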