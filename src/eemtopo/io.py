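"""Readers and writers for gridded surface files and texture-record tables.

Two on-disk dialects are supported:

* **Dialect A** (``"grid"``) — a self-describing plain-text format: a
  key/value header (``nx``, ``ny``, ``dx_um``, ``dy_um``, ``unit``,
  ``nodata`` and optional scan metadata) followed by an ``ny x nx``
  whitespace-separated height matrix, one grid row per line.  Heights are
  stored in the declared unit; non-measured points are written as the
  declared ``nodata`` sentinel.
* **Dialect B** (``"sdf"``) — an ASCII surface data file in the
  aBCR/aISO style used by metrology-software exports (header records
  ``NumPoints``, ``NumProfiles``, ``Xscale``/``Yscale``/``Zscale`` in
  metres, ``*``-terminated sections).  Non-measured points are written as
  the token ``BAD``.  Scan metadata travels in the trailer section.

Whatever the file-native unit, in-memory heights and spacings are µm.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np
import pandas as pd

from .surfaces import Area, HeightMap, Phase, ScanMetadata, TextureRecord

_UNIT_TO_UM = {"m": 1e6, "mm": 1e3, "um": 1.0, "µm": 1.0, "nm": 1e-3}

_DIALECTS = ("grid", "sdf")


class SurfaceParseError(ValueError):
    """Raised when a surface file fails to parse; names the offending field."""


def read_surface(path: str | Path, dialect: str = "grid") -> tuple[HeightMap, ScanMetadata | None]:
    """Read a gridded surface file, returning heights in µm.

    Returns the surface and the scan metadata if the file carries it
    (``None`` otherwise).
    """
    path = Path(path)
    if dialect == "grid":
        return _read_grid(path)
    if dialect == "sdf":
        return _read_sdf(path)
    raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")


def write_surface(
    surface: HeightMap,
    path: str | Path,
    metadata: ScanMetadata | None = None,
    dialect: str = "grid",
) -> None:
    """Write a surface so that :func:`read_surface` round-trips it bit-faithfully."""
    path = Path(path)
    if dialect == "grid":
        _write_grid(surface, metadata, path)
    elif dialect == "sdf":
        _write_sdf(surface, metadata, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")


# ---------------------------------------------------------------- dialect A


def _read_grid(path: Path) -> tuple[HeightMap, ScanMetadata | None]:
    header: dict[str, str] = {}
    data_lines: list[str] = []
    in_data = False
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if in_data:
            data_lines.append(line)
        elif line == "data:":
            in_data = True
        else:
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise SurfaceParseError(f"malformed header line {line!r}")
            header[parts[0]] = parts[1]

    def _get(key: str, cast, required: bool = True, default=None):
        if key not in header:
            if required:
                raise SurfaceParseError(f"missing header field {key!r}")
            return default
        try:
            return cast(header[key])
        except ValueError as exc:
            raise SurfaceParseError(f"invalid value for header field {key!r}: {header[key]!r}") from exc

    nx = _get("nx", int)
    ny = _get("ny", int)
    dx = _get("dx_um", float)
    dy = _get("dy_um", float)
    unit = _get("unit", str, required=False, default="um")
    if unit not in _UNIT_TO_UM:
        raise SurfaceParseError(f"unknown unit {unit!r} in header field 'unit'")
    nodata = _get("nodata", str, required=False, default="nan")
    ox = _get("origin_x_um", float, required=False, default=0.0)
    oy = _get("origin_y_um", float, required=False, default=0.0)

    if len(data_lines) != ny:
        raise SurfaceParseError(f"expected ny={ny} data rows, found {len(data_lines)}")
    heights = np.empty((ny, nx), dtype=float)
    valid = np.ones((ny, nx), dtype=bool)
    for i, line in enumerate(data_lines):
        tokens = line.split()
        if len(tokens) != nx:
            raise SurfaceParseError(f"data row {i} has {len(tokens)} values, header nx={nx}")
        for j, tok in enumerate(tokens):
            if tok == nodata or tok.lower() == "nan":
                heights[i, j] = np.nan
                valid[i, j] = False
            else:
                try:
                    heights[i, j] = float(tok)
                except ValueError as exc:
                    raise SurfaceParseError(f"non-numeric value {tok!r} at data row {i}") from exc
    heights *= _UNIT_TO_UM[unit]

    metadata = None
    if "specimen" in header:
        metadata = ScanMetadata(
            specimen=header["specimen"],
            area=Area(_get("area", str)),
            location=_get("location", int),
            phase=Phase(_get("phase", str)),
        )
    return HeightMap(heights, dx=dx, dy=dy, valid=valid, origin_offset=(ox, oy)), metadata


def _write_grid(surface: HeightMap, metadata: ScanMetadata | None, path: Path) -> None:
    lines = [
        "# eemtopo surface grid v1",
        f"nx {surface.nx}",
        f"ny {surface.ny}",
        f"dx_um {surface.dx!r}",
        f"dy_um {surface.dy!r}",
        "unit um",
        "nodata NA",
        f"origin_x_um {surface.origin_offset[0]!r}",
        f"origin_y_um {surface.origin_offset[1]!r}",
    ]
    if metadata is not None:
        lines += [
            f"specimen {metadata.specimen}",
            f"area {metadata.area.value}",
            f"location {metadata.location}",
            f"phase {metadata.phase.value}",
        ]
    lines.append("data:")
    for i in range(surface.ny):
        row = [
            repr(float(surface.heights[i, j])) if surface.valid[i, j] else "NA"
            for j in range(surface.nx)
        ]
        lines.append(" ".join(row))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------- dialect B


def _read_sdf(path: Path) -> tuple[HeightMap, ScanMetadata | None]:
    text = path.read_text()
    lines = text.splitlines()
    if not lines or lines[0].strip() not in ("aBCR-1.0", "aISO-1.0", "aBCR-1.0 ISO-25178-71"):
        raise SurfaceParseError("missing or unknown SDF version line (field 'version')")
    sections: list[list[str]] = [[]]
    for line in lines[1:]:
        if line.strip() == "*":
            sections.append([])
        else:
            sections[-1].append(line)
    if len(sections) < 2:
        raise SurfaceParseError("SDF file lacks a '*'-terminated header section")
    header: dict[str, str] = {}
    for line in sections[0]:
        line = line.strip()
        if not line or line.startswith(";"):
            continue
        if "=" not in line:
            raise SurfaceParseError(f"malformed SDF header record {line!r}")
        key, value = line.split("=", 1)
        header[key.strip()] = value.strip()

    def _get(key: str, cast):
        if key not in header:
            raise SurfaceParseError(f"missing SDF header record {key!r}")
        try:
            return cast(header[key])
        except ValueError as exc:
            raise SurfaceParseError(f"invalid SDF header record {key!r}: {header[key]!r}") from exc

    nx = _get("NumPoints", int)
    ny = _get("NumProfiles", int)
    xscale = _get("Xscale", float)  # metres per sample step
    yscale = _get("Yscale", float)
    zscale = _get("Zscale", float)  # metres per stored z unit

    tokens = " ".join(sections[1]).split()
    if len(tokens) != nx * ny:
        raise SurfaceParseError(f"SDF data section has {len(tokens)} values, expected {nx * ny}")
    heights = np.empty(nx * ny, dtype=float)
    valid = np.ones(nx * ny, dtype=bool)
    for k, tok in enumerate(tokens):
        if tok.upper() == "BAD" or tok.lower() == "nan":
            heights[k] = np.nan
            valid[k] = False
        else:
            try:
                heights[k] = float(tok)
            except ValueError as exc:
                raise SurfaceParseError(f"non-numeric SDF data value {tok!r}") from exc
    heights = heights.reshape(ny, nx) * (zscale * 1e6)  # -> µm, single rounding
    valid = valid.reshape(ny, nx)

    metadata = None
    if len(sections) > 2:
        trailer: dict[str, str] = {}
        for line in sections[2]:
            line = line.strip().lstrip(";").strip()
            if "=" in line:
                key, value = line.split("=", 1)
                trailer[key.strip()] = value.strip()
        if "specimen" in trailer:
            metadata = ScanMetadata(
                specimen=trailer["specimen"],
                area=Area(trailer["area"]),
                location=int(trailer["location"]),
                phase=Phase(trailer["phase"]),
            )
    surface = HeightMap(
        heights, dx=xscale * 1e6, dy=yscale * 1e6, valid=valid.reshape(ny, nx)
    )
    return surface, metadata


def _write_sdf(surface: HeightMap, metadata: ScanMetadata | None, path: Path) -> None:
    now = _dt.datetime(2000, 1, 1).strftime("%d%m%Y%H%M")  # fixed stamp: byte-stable output
    header = [
        "aBCR-1.0",
        "ManufacID = eemtopo",
        f"CreateDate = {now}",
        f"ModDate = {now}",
        f"NumPoints = {surface.nx}",
        f"NumProfiles = {surface.ny}",
        f"Xscale = {surface.dx * 1e-6!r}",
        f"Yscale = {surface.dy * 1e-6!r}",
        "Zscale = 1e-06",
        "Zresolution = -1",
        "Compression = 0",
        "DataType = 7",
        "CheckType = 0",
        "*",
    ]
    data = []
    for i in range(surface.ny):
        row = [
            repr(float(surface.heights[i, j])) if surface.valid[i, j] else "BAD"
            for j in range(surface.nx)
        ]
        data.append(" ".join(row))
    trailer = ["*"]
    if metadata is not None:
        trailer += [
            f"; specimen = {metadata.specimen}",
            f"; area = {metadata.area.value}",
            f"; location = {metadata.location}",
            f"; phase = {metadata.phase.value}",
        ]
    trailer.append("*")
    path.write_text("\n".join(header + data + trailer) + "\n")


# ------------------------------------------------------- texture record CSV


def records_to_dataframe(records: list[TextureRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        rows.append(
            {
                "specimen": rec.metadata.specimen,
                "area": rec.metadata.area.value,
                "location": rec.metadata.location,
                "phase": rec.metadata.phase.value,
                "Sa": rec.Sa,
                "Spc": rec.Spc,
                "Sha": rec.Sha,
                "Smrk1": rec.Smrk1,
                "settings_fingerprint": rec.settings_fingerprint,
            }
        )
    return pd.DataFrame(rows)


def dataframe_to_records(df: pd.DataFrame) -> list[TextureRecord]:
    records = []
    for _, row in df.iterrows():
        records.append(
            TextureRecord(
                metadata=ScanMetadata(
                    specimen=str(row["specimen"]),
                    area=Area(row["area"]),
                    location=int(row["location"]),
                    phase=Phase(row["phase"]),
                ),
                Sa=float(row["Sa"]),
                Spc=float(row["Spc"]),
                Sha=float(row["Sha"]),
                Smrk1=float(row["Smrk1"]),
                settings_fingerprint=str(row.get("settings_fingerprint", "")),
            )
        )
    return records


def write_records_csv(records: list[TextureRecord], path: str | Path) -> None:
    records_to_dataframe(records).to_csv(path, index=False)


def read_records_csv(path: str | Path) -> list[TextureRecord]:
    return dataframe_to_records(pd.read_csv(path, keep_default_na=True))
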