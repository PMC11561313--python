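"""File formats: ESRI ASCII grids, occurrence CSVs, JSON reports.

Rasters are stored as one single-band ESRI ASCII grid (.asc) per layer --
a plain-text, widely interchangeable raster format.  Values are written as
float32 with enough significant digits that a write/read round-trip is
bit-exact at float32 precision.  Occurrences travel as CSV with the header
``species,lon,lat``.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .grids import EnvGrid, MembershipSurface, OccurrenceSet

__all__ = ["write_ascii_grid", "read_ascii_grid", "write_env_grid", "read_raster_stack",
           "write_surface", "read_surface", "read_occurrences", "write_occurrences",
           "write_report"]

NODATA = -9999.0


def write_ascii_grid(values: np.ndarray, path, origin_lon: float, origin_lat: float,
                     cell_size: float) -> None:
    """Write one 2-D array (NaN = nodata) as an ESRI ASCII grid."""
    values = np.asarray(values, dtype=np.float32)
    n_rows, n_cols = values.shape
    yll = origin_lat - n_rows * cell_size
    out = values.copy()
    out[~np.isfinite(out)] = NODATA
    with open(path, "w") as fh:
        fh.write(f"ncols {n_cols}\n")
        fh.write(f"nrows {n_rows}\n")
        fh.write(f"xllcorner {origin_lon!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {cell_size!r}\n")
        fh.write(f"NODATA_value {NODATA:g}\n")
        for row in out:
            # %.9g round-trips float32 exactly
            fh.write(" ".join(f"{v:.9g}" for v in row) + "\n")


def read_ascii_grid(path):
    """Read an ESRI ASCII grid; returns (values float32 with NaN nodata, header dict)."""
    header = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    required = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")
    missing = [k for k in required if k not in header]
    if missing:
        raise ValueError(f"{path}: ASCII grid header missing {missing}")
    values = np.loadtxt(lines[i:], dtype=np.float32)
    values = values.reshape(int(header["nrows"]), int(header["ncols"]))
    nodata = header.get("nodata_value")
    if nodata is not None:
        values[values == np.float32(nodata)] = np.nan
    return values, header


def _origin_from_header(h) -> tuple[float, float, float]:
    cell = h["cellsize"]
    return h["xllcorner"], h["yllcorner"] + h["nrows"] * cell, cell


def write_env_grid(grid: EnvGrid, out_dir) -> list[Path]:
    """One .asc per layer, named after the layer."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in grid.layer_names:
        vals = grid.layers[name].copy()
        vals[grid.nodata_mask] = np.nan
        p = out_dir / f"{name}.asc"
        write_ascii_grid(vals, p, grid.origin_lon, grid.origin_lat, grid.cell_size)
        paths.append(p)
    return paths


def read_raster_stack(raster_dir) -> EnvGrid:
    """Read every .asc in a directory into a co-registered EnvGrid.

    All layers must share shape, corner coordinates and cell size; the
    nodata mask is the union of the per-layer masks.
    """
    raster_dir = Path(raster_dir)
    files = sorted(raster_dir.glob("*.asc"))
    if not files:
        raise FileNotFoundError(f"no .asc rasters found in {raster_dir}")
    layers, ref_header, ref_name = {}, None, None
    for f in files:
        vals, header = read_ascii_grid(f)
        geo = {k: header[k] for k in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")}
        if ref_header is None:
            ref_header, ref_name = geo, f.name
        elif geo != ref_header:
            raise ValueError(
                f"raster {f.name} is not co-registered with {ref_name}: {geo} vs {ref_header}")
        layers[f.stem] = vals.astype(float)
    mask = np.zeros_like(next(iter(layers.values())), dtype=bool)
    for vals in layers.values():
        mask |= ~np.isfinite(vals)
    lon, lat, cell = _origin_from_header(ref_header)
    return EnvGrid(layers=layers, origin_lon=lon, origin_lat=lat,
                   cell_size=cell, nodata_mask=mask)


def write_surface(surface: MembershipSurface, path) -> None:
    write_ascii_grid(surface.values, path, surface.origin_lon,
                     surface.origin_lat, surface.cell_size)


def read_surface(path, kind: str = "probability", **provenance) -> MembershipSurface:
    vals, header = read_ascii_grid(path)
    lon, lat, cell = _origin_from_header(header)
    return MembershipSurface(values=vals.astype(float), kind=kind, origin_lon=lon,
                             origin_lat=lat, cell_size=cell, provenance=provenance)


def read_occurrences(path, species: str | None = None) -> OccurrenceSet:
    """Read ``species,lon,lat`` CSV; malformed rows are reported with line numbers."""
    pts, sp_ids, errors = [], [], []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header[:3]] != ["species", "lon", "lat"]:
            raise ValueError(f"{path}: expected header 'species,lon,lat', got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row or not "".join(row).strip():
                continue
            if len(row) < 3:
                errors.append(f"line {lineno}: expected 3 fields, got {len(row)}")
                continue
            try:
                lon, lat = float(row[1]), float(row[2])
            except ValueError:
                errors.append(f"line {lineno}: non-numeric coordinate {row[1]!r},{row[2]!r}")
                continue
            if species is None or row[0] == species:
                sp_ids.append(row[0])
                pts.append((lon, lat))
    if errors:
        raise ValueError(f"{path}: malformed rows: " + "; ".join(errors))
    sp = species if species is not None else (sp_ids[0] if sp_ids else "unknown")
    return OccurrenceSet(species_id=sp, points=np.array(pts).reshape(-1, 2))


def write_occurrences(occ: OccurrenceSet, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["species", "lon", "lat"])
        for lon, lat in occ.points:
            w.writerow([occ.species_id, repr(float(lon)), repr(float(lat))])


def _jsonable(obj):
    import pandas as pd
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.where(pd.notna(obj), None).to_dict(orient="index"))
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_report(obj, path) -> None:
    """JSON report with deterministic key order."""
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")
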