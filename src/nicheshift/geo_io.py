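"""Raster and occurrence-table input/output.

Rasters are exchanged as ESRI ASCII grids (``.asc``): a six-line header
(``ncols``, ``nrows``, ``xllcorner``, ``yllcorner``, ``cellsize``,
``NODATA_value``, case-insensitive) followed by ``nrows`` rows of
``ncols`` whitespace-separated numbers, the first row being the
northernmost. Occurrences are plain CSV with a ``taxon,lon,lat`` header.

Coordinate convention: geographic lon/lat in decimal degrees, corner
registration (``xllcorner``/``yllcorner`` is the outer corner of the
lower-left cell). Cell ``(r, c)`` covers the half-open box
``[x_min + c*s, x_min + (c+1)*s) x [y_min + (R-1-r)*s, y_min + (R-r)*s)``
so every in-extent point maps to exactly one cell, and row 0 is the
northernmost row in memory, matching the file layout. Nodata cells are
held as NaN in memory; the sentinel is only used on disk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GridGeometry",
    "RasterStack",
    "OccurrenceSet",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_occurrences",
    "write_occurrences",
    "extract_at_points",
    "dedupe_per_pixel",
]


class GridFormatError(ValueError):
    """Raised for malformed ASCII grid files."""


@dataclass(frozen=True)
class GridGeometry:
    """Shared geometry of an aligned raster stack."""

    n_rows: int
    n_cols: int
    x_min: float
    y_min: float
    cell_size: float

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def x_max(self) -> float:
        return self.x_min + self.n_cols * self.cell_size

    @property
    def y_max(self) -> float:
        return self.y_min + self.n_rows * self.cell_size

    def cell_of(self, lon: float, lat: float) -> tuple[int, int] | None:
        """Map a point to its containing (row, col), or None if outside."""
        c = int(np.floor((lon - self.x_min) / self.cell_size))
        r_from_bottom = int(np.floor((lat - self.y_min) / self.cell_size))
        r = self.n_rows - 1 - r_from_bottom
        if 0 <= r < self.n_rows and 0 <= c < self.n_cols:
            return r, c
        return None

    def cell_center(self, r: int, c: int) -> tuple[float, float]:
        lon = self.x_min + (c + 0.5) * self.cell_size
        lat = self.y_min + (self.n_rows - r - 0.5) * self.cell_size
        return lon, lat

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Lon/lat of every cell center, each shaped (n_rows, n_cols)."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        lon = self.x_min + (cols + 0.5) * self.cell_size
        lat = self.y_min + (self.n_rows - rows - 0.5) * self.cell_size
        return np.meshgrid(lon, lat)


@dataclass
class RasterStack:
    """Named, aligned 2-D layers sharing one :class:`GridGeometry`.

    ``nodata`` is the on-disk sentinel; in memory nodata cells are NaN.
    """

    geometry: GridGeometry
    layers: dict[str, np.ndarray] = field(default_factory=dict)
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        for name, arr in self.layers.items():
            self._check_shape(name, arr)

    def _check_shape(self, name: str, arr: np.ndarray) -> None:
        expected = (self.geometry.n_rows, self.geometry.n_cols)
        if arr.shape != expected:
            raise ValueError(
                f"layer {name!r} has shape {arr.shape}, geometry expects {expected}"
            )

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def add_layer(self, name: str, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        self._check_shape(name, values)
        self.layers[name] = values

    def valid_mask(self) -> np.ndarray:
        """Boolean grid: True where every layer has finite data."""
        mask = np.ones((self.geometry.n_rows, self.geometry.n_cols), dtype=bool)
        for arr in self.layers.values():
            mask &= np.isfinite(arr)
        return mask

    def to_table(self, mask: np.ndarray | None = None) -> pd.DataFrame:
        """Flatten off-nodata cells to a point x layer table.

        Includes ``row``/``col``/``lon``/``lat`` columns; restricted to
        ``mask`` (boolean grid) if given.
        """
        valid = self.valid_mask()
        if mask is not None:
            valid &= mask.astype(bool)
        rr, cc = np.nonzero(valid)
        lon, lat = self.geometry.cell_centers()
        data = {"row": rr, "col": cc, "lon": lon[rr, cc], "lat": lat[rr, cc]}
        for name, arr in self.layers.items():
            data[name] = arr[rr, cc]
        return pd.DataFrame(data)

    def select(self, names: list[str]) -> "RasterStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"layers not in stack: {missing}")
        return RasterStack(
            geometry=self.geometry,
            layers={n: self.layers[n] for n in names},
            nodata=self.nodata,
        )


@dataclass
class OccurrenceSet:
    """A taxon's presence records as lon/lat points."""

    taxon_id: str
    points: np.ndarray  # (n, 2) lon, lat
    era: str | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size and self.points.shape[1] != 2:
            raise ValueError("points must be (n, 2) lon/lat")
        if self.points.size and not np.all(np.isfinite(self.points)):
            raise ValueError("occurrence coordinates must be finite")

    def __len__(self) -> int:
        return 0 if self.points.size == 0 else self.points.shape[0]


_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_ascii_grid(path) -> RasterStack:
    """Read one ESRI ASCII grid into a single-layer stack.

    The layer is named after the file stem. ``xllcenter`` registration is
    rejected rather than silently reinterpreted.
    """
    import pathlib

    path = pathlib.Path(path)
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    nodata = -9999.0
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if not parts:
            continue
        key = parts[0].lower()
        if key in ("xllcenter", "yllcenter"):
            raise GridFormatError(
                f"{path}: cell-center registration ({parts[0]}) is not supported; "
                "convert to xllcorner/yllcorner"
            )
        if key in _HEADER_KEYS or key == "nodata_value":
            if len(parts) != 2:
                raise GridFormatError(f"{path}: bad header line {line!r}")
            try:
                header[key] = float(parts[1])
            except ValueError as exc:
                raise GridFormatError(f"{path}: non-numeric header {line!r}") from exc
        else:
            break  # first data row
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise GridFormatError(f"{path}: header missing keys {missing}")
    nodata = header.get("nodata_value", nodata)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    for line in lines[i:]:
        parts = line.split()
        if not parts:
            continue
        try:
            row = np.array([float(v) for v in parts])
        except ValueError as exc:
            raise GridFormatError(f"{path}: non-numeric cell in row {len(rows)}") from exc
        if row.size != n_cols:
            raise GridFormatError(
                f"{path}: row {len(rows)} has {row.size} values, expected {n_cols}"
            )
        rows.append(row)
    if len(rows) != n_rows:
        raise GridFormatError(f"{path}: {len(rows)} data rows, header says {n_rows}")
    values = np.vstack(rows)
    values[values == nodata] = np.nan
    geom = GridGeometry(
        n_rows=n_rows,
        n_cols=n_cols,
        x_min=header["xllcorner"],
        y_min=header["yllcorner"],
        cell_size=header["cellsize"],
    )
    return RasterStack(geometry=geom, layers={path.stem: values}, nodata=nodata)


def write_ascii_grid(layer: np.ndarray, geometry: GridGeometry, path,
                     nodata: float = -9999.0) -> None:
    """Write one layer as an ESRI ASCII grid with full float precision."""
    layer = np.asarray(layer, dtype=float)
    if layer.shape != (geometry.n_rows, geometry.n_cols):
        raise ValueError("layer shape does not match geometry")
    out = np.where(np.isfinite(layer), layer, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {geometry.n_cols}\n")
        fh.write(f"nrows {geometry.n_rows}\n")
        fh.write(f"xllcorner {geometry.x_min!r}\n")
        fh.write(f"yllcorner {geometry.y_min!r}\n")
        fh.write(f"cellsize {geometry.cell_size!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_stack(directory, names: list[str] | None = None) -> RasterStack:
    """Read every ``.asc`` file in a directory into one aligned stack."""
    import pathlib

    directory = pathlib.Path(directory)
    paths = sorted(directory.glob("*.asc"))
    if names is not None:
        by_stem = {p.stem: p for p in paths}
        paths = [by_stem[n] for n in names]
    if not paths:
        raise FileNotFoundError(f"no .asc files in {directory}")
    stack = read_ascii_grid(paths[0])
    for p in paths[1:]:
        single = read_ascii_grid(p)
        if single.geometry != stack.geometry:
            raise ValueError(f"{p}: geometry differs from {paths[0]}")
        stack.add_layer(p.stem, single.layers[p.stem])
    return stack


def write_stack(stack: RasterStack, directory) -> None:
    import pathlib

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, arr in stack.layers.items():
        write_ascii_grid(arr, stack.geometry, directory / f"{name}.asc",
                         nodata=stack.nodata)


def read_occurrences(path) -> dict[str, OccurrenceSet]:
    """Read a ``taxon,lon,lat`` CSV, one :class:`OccurrenceSet` per taxon.

    Rows with blank or non-numeric coordinates are dropped with a logged
    count; a file with no valid rows is an error.
    """
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    for required in ("taxon", "lon", "lat"):
        if required not in cols:
            raise ValueError(f"{path}: missing column {required!r}")
    taxon = df[cols["taxon"]].astype(str)
    lon = pd.to_numeric(df[cols["lon"]], errors="coerce")
    lat = pd.to_numeric(df[cols["lat"]], errors="coerce")
    ok = lon.notna() & lat.notna() & np.isfinite(lon) & np.isfinite(lat)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("%s: dropped %d rows with invalid coordinates", path, n_dropped)
    if not ok.any():
        raise ValueError(f"{path}: no valid occurrence rows")
    out: dict[str, OccurrenceSet] = {}
    for tx, grp in pd.DataFrame({"taxon": taxon[ok], "lon": lon[ok], "lat": lat[ok]}).groupby(
        "taxon", sort=False
    ):
        out[str(tx)] = OccurrenceSet(
            taxon_id=str(tx), points=grp[["lon", "lat"]].to_numpy()
        )
    return out


def write_occurrences(occ_sets, path) -> None:
    """Write one or more occurrence sets back to ``taxon,lon,lat`` CSV."""
    if isinstance(occ_sets, OccurrenceSet):
        occ_sets = [occ_sets]
    frames = [
        pd.DataFrame({"taxon": occ.taxon_id, "lon": occ.points[:, 0], "lat": occ.points[:, 1]})
        for occ in occ_sets
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def extract_at_points(stack: RasterStack, points: np.ndarray) -> pd.DataFrame:
    """Look up layer values at the cells containing each point.

    Returns one row per point, in input order, with ``point_id``, ``lon``,
    ``lat``, one column per layer, and a ``flag`` column: ``ok``,
    ``outside`` (not in the raster extent) or ``nodata`` (at least one
    layer undefined there). Flagged points keep their row; values are NaN.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.size == 0:
        raise ValueError("empty point list")
    geom = stack.geometry
    n = points.shape[0]
    records = {name: np.full(n, np.nan) for name in stack.layers}
    flags = np.full(n, "ok", dtype=object)
    for i, (lon, lat) in enumerate(points):
        cell = geom.cell_of(lon, lat)
        if cell is None:
            flags[i] = "outside"
            continue
        r, c = cell
        vals = {name: arr[r, c] for name, arr in stack.layers.items()}
        if any(not np.isfinite(v) for v in vals.values()):
            flags[i] = "nodata"
        for name, v in vals.items():
            records[name][i] = v
    out = pd.DataFrame({"point_id": np.arange(n), "lon": points[:, 0], "lat": points[:, 1]})
    for name in stack.layers:
        out[name] = records[name]
    out["flag"] = flags
    return out


def dedupe_per_pixel(occ: OccurrenceSet, geometry: GridGeometry) -> OccurrenceSet:
    """Thin occurrences to at most one record per raster cell.

    The first-seen record in each occupied cell is retained, so the result
    is deterministic for a given input order; points outside the extent are
    dropped. Idempotent.
    """
    seen: set[tuple[int, int]] = set()
    keep: list[int] = []
    for i, (lon, lat) in enumerate(occ.points):
        cell = geometry.cell_of(lon, lat)
        if cell is None or cell in seen:
            continue
        seen.add(cell)
        keep.append(i)
    return OccurrenceSet(
        taxon_id=occ.taxon_id,
        points=occ.points[keep] if keep else np.empty((0, 2)),
        era=occ.era,
    )
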