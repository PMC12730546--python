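"""Readers and writers for spectra, scan maps, and assignment tables.

Formats are deliberately plain: spectra are two-column delimited text
(wavenumber cm^-1, intensity) with optional ``# key: value`` metadata
comments; maps are TSV matrices with a JSON sidecar carrying pixel size,
units and provenance; assignment tables are CSV with columns
``low_cm1, high_cm1, assignment``.  Writers and readers round-trip exactly.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .correlate import CurrentMap, HeightMap, ScanMap
from .spectra import AssignmentTable, RamanSpectrum

__all__ = [
    "FormatError",
    "read_spectrum",
    "write_spectrum",
    "read_map",
    "write_map",
    "read_assignment_table",
    "write_assignment_table",
]


class FormatError(ValueError):
    """A file failed validation; the message names the offending line."""


_NUM = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _sniff_delimiter(line: str) -> str | None:
    if "\t" in line:
        return "\t"
    if "," in line:
        return ","
    return None  # whitespace


def read_spectrum(path) -> RamanSpectrum:
    """Read a two-column wavenumber/intensity file (CSV, TSV or whitespace).

    Lines starting with ``#`` are treated as comments; ``# key: value``
    comments are collected into the spectrum metadata.  A single non-numeric
    header row is allowed and skipped.
    """
    path = Path(path)
    meta: dict = {}
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*([^:]+):\s*(.*)$", line)
                if m:
                    key, val = m.group(1).strip(), m.group(2).strip()
                    try:
                        meta[key] = json.loads(val)
                    except (json.JSONDecodeError, ValueError):
                        meta[key] = val
                continue
            delim = _sniff_delimiter(line)
            parts = [p for p in (line.split(delim) if delim else line.split()) if p]
            if len(parts) != 2:
                raise FormatError(
                    f"{path.name}:{lineno}: expected 2 columns, found {len(parts)}"
                )
            if not (_NUM.match(parts[0]) and _NUM.match(parts[1])):
                if not rows:  # header row
                    continue
                raise FormatError(f"{path.name}:{lineno}: non-numeric entry {parts!r}")
            rows.append((float(parts[0]), float(parts[1])))
    if len(rows) < 2:
        raise FormatError(f"{path.name}: fewer than 2 data rows")
    arr = np.asarray(rows)
    if np.any(np.diff(arr[:, 0]) <= 0):
        bad = int(np.argmax(np.diff(arr[:, 0]) <= 0)) + 2
        raise FormatError(f"{path.name}: wavenumber axis not increasing at data row {bad}")
    return RamanSpectrum(arr[:, 0], arr[:, 1], metadata=meta)


def write_spectrum(path, spec: RamanSpectrum) -> None:
    """Write a spectrum as CSV with ``# key: value`` metadata comment lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, val in spec.metadata.items():
            if val is None:
                continue
            fh.write(f"# {key}: {json.dumps(val) if not isinstance(val, str) else val}\n")
        fh.write("wavenumber_cm-1,intensity\n")
        for s, i in zip(spec.shift, spec.intensity):
            fh.write(f"{float(s)!r},{float(i)!r}\n")


def read_map(path) -> ScanMap:
    """Read a TSV map matrix and its ``<path>.json`` sidecar.

    The sidecar must provide ``pixel_size_nm``; its ``kind`` field selects
    :class:`HeightMap` (``"height"``) or :class:`CurrentMap` (``"current"``).
    Ragged rows are reported with their line number.
    """
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FormatError(f"{path.name}: missing sidecar {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    rows = []
    width = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if width is None:
                width = len(parts)
            elif len(parts) != width:
                raise FormatError(
                    f"{path.name}:{lineno}: ragged row ({len(parts)} values, expected {width})"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise FormatError(f"{path.name}:{lineno}: {exc}") from None
    data = np.asarray(rows)
    kind = meta.get("kind", "height")
    cls = {"height": HeightMap, "current": CurrentMap}.get(kind)
    if cls is None:
        raise FormatError(f"{sidecar.name}: unknown map kind {kind!r}")
    return cls(data, float(meta["pixel_size_nm"]), meta={k: v for k, v in meta.items()})


def write_map(path, m: ScanMap, kind: str | None = None) -> None:
    """Write a map as a TSV matrix plus JSON sidecar (pixel size, unit, provenance)."""
    path = Path(path)
    np.savetxt(path, m.data, delimiter="\t", fmt="%.6f")
    if kind is None:
        kind = "height" if isinstance(m, HeightMap) else "current"
    meta = {
        "kind": kind,
        "pixel_size_nm": m.pixel_size,
        "unit": m.unit,
        "shape": list(m.shape),
        **{k: v for k, v in m.meta.items() if _json_safe(v)},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def read_assignment_table(path) -> AssignmentTable:
    """Load a band-assignment CSV (``low_cm1, high_cm1, assignment``)."""
    df = pd.read_csv(path)
    missing = {"low_cm1", "high_cm1", "assignment"} - set(df.columns)
    if missing:
        raise FormatError(f"assignment table missing columns {sorted(missing)}")
    return AssignmentTable.from_frame(df)


def write_assignment_table(path, table: AssignmentTable) -> None:
    table.to_frame().to_csv(path, index=False)
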