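"""Reading and writing per-point left-ventricular mapping exports.

The native CARTO export format is proprietary; this module defines a plain
tab-separated dialect carrying the same per-point payload: position (mm),
catheter orientation angles (degrees), unipolar and bipolar voltage (mV),
local activation time (ms, may be negative relative to the cycle reference)
and tissue impedance (Ω).  Files ending in ``.gz`` are handled transparently.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable

import numpy as np

COLUMNS = ("x", "y", "z", "alpha", "beta", "gamma", "uni_v", "bip_v", "lat", "imp")

__all__ = ["COLUMNS", "MapPoint", "EamExport", "read_export", "write_export"]


@dataclass(frozen=True)
class MapPoint:
    """One acquired endocardial point with its six measurement channels."""

    x: float
    y: float
    z: float
    alpha: float
    beta: float
    gamma: float
    uni_v: float
    bip_v: float
    lat: float
    imp: float

    def __post_init__(self) -> None:
        for name in COLUMNS:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"MapPoint field {name!r} is not finite: {v!r}")
        if self.uni_v < 0 or self.bip_v < 0:
            raise ValueError("voltages must be non-negative")
        if self.imp <= 0:
            raise ValueError("impedance must be positive")

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, name) for name in COLUMNS)


@dataclass
class EamExport:
    """An ordered collection of mapped points for one patient."""

    patient_id: str
    points: list[MapPoint]
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if len(self.points) == 0:
            raise ValueError("an export must contain at least one point")

    def __len__(self) -> int:
        return len(self.points)

    def positions(self) -> np.ndarray:
        """(n, 3) array of x/y/z coordinates in mm."""
        return np.array([(p.x, p.y, p.z) for p in self.points], dtype=float)

    def channel(self, name: str) -> np.ndarray:
        if name not in COLUMNS:
            raise KeyError(f"unknown channel {name!r}")
        return np.array([getattr(p, name) for p in self.points], dtype=float)

    def as_array(self) -> np.ndarray:
        """(n, 10) array in canonical column order."""
        return np.array([p.as_tuple() for p in self.points], dtype=float)


def _open(path: Path, mode: str) -> IO[str]:
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_export(path: str | Path, patient_id: str | None = None) -> EamExport:
    """Parse one export file.

    Leading ``# key=value`` lines become metadata; ``patient_id`` is taken from
    a ``# patient_id=...`` line unless overridden by the argument.
    """
    path = Path(path)
    metadata: dict[str, str] = {}
    with _open(path, "r") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty export file")
    i = 0
    while i < len(lines) and lines[i].startswith("#"):
        body = lines[i][1:].strip()
        if "=" in body:
            k, v = body.split("=", 1)
            metadata[k.strip()] = v.strip()
        i += 1
    if i >= len(lines):
        raise ValueError(f"{path}: no header row found")
    header = tuple(lines[i].split("\t"))
    missing = [c for c in COLUMNS if c not in header]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    extra = [c for c in header if c not in COLUMNS]
    if extra:
        raise ValueError(f"{path}: unknown column(s) {', '.join(extra)}")
    col_pos = {c: header.index(c) for c in COLUMNS}
    points: list[MapPoint] = []
    for row_no, ln in enumerate(lines[i + 1 :], start=1):
        cells = ln.split("\t")
        if len(cells) != len(header):
            raise ValueError(f"{path}: row {row_no} has {len(cells)} cells, expected {len(header)}")
        try:
            vals = {c: float(cells[col_pos[c]]) for c in COLUMNS}
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric cell in row {row_no}") from exc
        points.append(MapPoint(**vals))
    if not points:
        raise ValueError(f"{path}: export contains a header but no data rows")
    pid = patient_id or metadata.get("patient_id") or path.stem
    return EamExport(patient_id=pid, points=points, metadata=metadata)


def write_export(export: EamExport, path: str | Path) -> None:
    """Write a tab-separated export with fixed 6-decimal formatting."""
    path = Path(path)
    meta = dict(export.metadata)
    meta.setdefault("patient_id", export.patient_id)
    with _open(path, "w") as fh:
        for k in sorted(meta):
            fh.write(f"# {k}={meta[k]}\n")
        fh.write("\t".join(COLUMNS) + "\n")
        for p in export.points:
            fh.write("\t".join(f"{v:.6f}" for v in p.as_tuple()) + "\n")
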