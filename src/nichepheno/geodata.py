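"""Raster and table I/O, occurrence preparation, and background sampling.

All coordinates are WGS84 longitude/latitude in decimal degrees. Rasters are
exchanged as ESRI ASCII grids (one layer per ``.asc`` file) with a shared
extent, cell size and no-data mask; in memory a set of aligned layers is an
:class:`EnvRasterStack`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# km per degree of latitude (spherical approximation); longitude is scaled
# by cos(latitude) at the point of use.
KM_PER_DEG_LAT = 110.574
KM_PER_DEG_LON_EQ = 111.320

DEFAULT_NODATA = -9999.0


class RasterParseError(ValueError):
    """Malformed ESRI ASCII grid; message carries the offending line number."""


class AlignmentError(ValueError):
    """Grids that should share extent/cell size/mask do not."""


# ---------------------------------------------------------------------------
# Raster stack container
# ---------------------------------------------------------------------------

@dataclass
class EnvRasterStack:
    """Named gridded environmental layers sharing one extent and mask.

    ``values`` has shape ``(n_layers, nrows, ncols)`` with row 0 the
    northernmost row (ESRI ASCII convention).  ``nodata_mask`` is True where
    cells carry no data; the mask is common to all layers.
    """

    layer_names: list[str]
    values: np.ndarray
    extent: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax
    cell_size: float
    nodata_mask: np.ndarray
    layer_info: dict = field(default_factory=dict)  # optional provenance

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("values must be (n_layers, nrows, ncols)")
        if len(self.layer_names) != self.values.shape[0]:
            raise ValueError("layer_names length mismatch")
        if self.nodata_mask.shape != self.values.shape[1:]:
            raise AlignmentError("nodata_mask shape mismatch")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[1:]

    @property
    def n_layers(self) -> int:
        return self.values.shape[0]

    def layer(self, name: str) -> np.ndarray:
        return self.values[self.layer_names.index(name)]

    def cell_of(self, lon, lat):
        """Row/col indices of the cells containing the given coordinates."""
        xmin, ymin, xmax, ymax = self.extent
        col = np.floor((np.asarray(lon) - xmin) / self.cell_size).astype(int)
        row = np.floor((ymax - np.asarray(lat)) / self.cell_size).astype(int)
        return row, col

    def center_of(self, row, col):
        """Lon/lat of cell centers."""
        xmin, ymin, xmax, ymax = self.extent
        lon = xmin + (np.asarray(col) + 0.5) * self.cell_size
        lat = ymax - (np.asarray(row) + 0.5) * self.cell_size
        return lon, lat

    def contains(self, lon, lat) -> np.ndarray:
        xmin, ymin, xmax, ymax = self.extent
        lon = np.asarray(lon)
        lat = np.asarray(lat)
        return (lon >= xmin) & (lon < xmax) & (lat > ymin) & (lat <= ymax)

    def valid_cells(self) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of all data cells."""
        rows, cols = np.nonzero(~self.nodata_mask)
        return rows, cols

    def cell_table(self) -> pd.DataFrame:
        """Environment matrix over all valid cells (one row per cell)."""
        rows, cols = self.valid_cells()
        lon, lat = self.center_of(rows, cols)
        data = {"lon": lon, "lat": lat, "row": rows, "col": cols}
        for i, name in enumerate(self.layer_names):
            data[name] = self.values[i, rows, cols]
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

def write_ascii_grid(values: np.ndarray, extent, cell_size: float, path,
                     nodata: float = DEFAULT_NODATA) -> None:
    """Write one layer as an ESRI ASCII grid (NaN cells become NODATA)."""
    values = np.asarray(values, dtype=float)
    nrows, ncols = values.shape
    xmin, ymin, _, _ = extent
    out = np.where(np.isnan(values), nodata, values)
    with open(path, "w") as fh:
        fh.write(f"NCOLS {ncols}\n")
        fh.write(f"NROWS {nrows}\n")
        fh.write(f"XLLCORNER {float(xmin)!r}\n")
        fh.write(f"YLLCORNER {float(ymin)!r}\n")
        fh.write(f"CELLSIZE {float(cell_size)!r}\n")
        fh.write(f"NODATA_VALUE {float(nodata)!r}\n")
        for r in range(nrows):
            fh.write(" ".join(repr(float(v)) for v in out[r]) + "\n")


def read_ascii_grid(path):
    """Read an ESRI ASCII grid.

    Returns ``(values, extent, cell_size)`` where nodata cells are NaN.
    Raises :class:`RasterParseError` with the line number on malformed input.
    """
    header: dict[str, float] = {}
    keys = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
            "nodata_value")
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            key = tokens[0].lower()
            if key in keys:
                if len(tokens) != 2:
                    raise RasterParseError(
                        f"{path}: header line {lineno} malformed: {line!r}")
                try:
                    header[key] = float(tokens[1])
                except ValueError as exc:
                    raise RasterParseError(
                        f"{path}: header line {lineno}: {exc}") from exc
            else:
                try:
                    rows.append(np.array([float(t) for t in tokens]))
                except ValueError as exc:
                    raise RasterParseError(
                        f"{path}: data line {lineno}: {exc}") from exc
    for k in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if k not in header:
            raise RasterParseError(f"{path}: missing header field {k.upper()}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if len(rows) != nrows or any(len(r) != ncols for r in rows):
        raise RasterParseError(
            f"{path}: data block is not {nrows}x{ncols}")
    values = np.vstack(rows)
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    values = np.where(values == nodata, np.nan, values)
    cell = header["cellsize"]
    xmin, ymin = header["xllcorner"], header["yllcorner"]
    extent = (xmin, ymin, xmin + ncols * cell, ymin + nrows * cell)
    return values, extent, cell


def write_stack(stack: EnvRasterStack, outdir) -> list[Path]:
    """Write every layer of the stack as ``<outdir>/<layer>.asc``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, name in enumerate(stack.layer_names):
        vals = np.where(stack.nodata_mask, np.nan, stack.values[i])
        p = outdir / f"{name}.asc"
        write_ascii_grid(vals, stack.extent, stack.cell_size, p)
        paths.append(p)
    return paths


def read_stack(paths: Iterable, names: Sequence[str] | None = None
               ) -> EnvRasterStack:
    """Assemble an :class:`EnvRasterStack` from aligned ``.asc`` files."""
    paths = [Path(p) for p in paths]
    if names is None:
        names = [p.stem for p in paths]
    layers, ref = [], None
    for p in paths:
        values, extent, cell = read_ascii_grid(p)
        if ref is None:
            ref = (extent, cell, values.shape)
        else:
            if (not np.allclose(ref[0], extent) or ref[2] != values.shape
                    or not math.isclose(ref[1], cell, rel_tol=1e-9)):
                raise AlignmentError(
                    f"{p}: extent/cellsize/shape differ from {paths[0]}")
        layers.append(values)
    arr = np.stack(layers)
    mask = np.any(np.isnan(arr), axis=0)
    arr = np.where(mask, np.nan, arr)
    return EnvRasterStack(list(names), arr, ref[0], ref[1], mask)


# ---------------------------------------------------------------------------
# Occurrences
# ---------------------------------------------------------------------------

@dataclass
class OccurrenceSet:
    """Presence and background records.

    ``records`` columns: ``population_id, lon, lat, role`` with role one of
    ``center``, ``grid``, ``background``.  ``bias_weights`` (optional) holds
    one weight per background record.
    """

    records: pd.DataFrame
    bias_weights: np.ndarray | None = None
    n_dropped: int = 0

    def presences(self) -> pd.DataFrame:
        return self.records[self.records["role"] != "background"]

    def background(self) -> pd.DataFrame:
        return self.records[self.records["role"] == "background"]


def _lattice_offsets_km(spacing_km: float, n_extra: int):
    """Offsets (dx_km, dy_km) for grid records around a site.

    The lattice is the 3x3 node set at ``spacing_km``; the eight surrounding
    nodes come first (row-major, north to south), the central node last, so
    ``n_extra=9`` uses all nine nodes (the ninth duplicating the recorded
    point, which keeps ten records per site).
    """
    if not 0 <= n_extra <= 9:
        raise ValueError("n_extra must be between 0 and 9")
    ring = [(dx * spacing_km, dy * spacing_km)
            for dy in (1, 0, -1) for dx in (-1, 0, 1) if not (dx == dy == 0)]
    return (ring + [(0.0, 0.0)])[:n_extra]


def expand_occurrences(sites: pd.DataFrame, n_extra: int = 9,
                       spacing_km: float = 1.2,
                       extent: tuple | None = None) -> OccurrenceSet:
    """Expand each site into a center record plus lattice grid records.

    One coordinate is recorded per population (the village center); grid
    records on a 3x3 lattice around it broaden the sampled environment.
    Records falling outside ``extent`` (if given) are dropped with a warning
    and counted in ``n_dropped``.
    """
    if sites.empty:
        raise ValueError("sites table is empty")
    offsets = _lattice_offsets_km(spacing_km, n_extra)
    rows = []
    for _, s in sites.iterrows():
        rows.append((s["population_id"], s["lon"], s["lat"], "center"))
        coslat = math.cos(math.radians(s["lat"]))
        for dx, dy in offsets:
            lon = s["lon"] + dx / (KM_PER_DEG_LON_EQ * coslat)
            lat = s["lat"] + dy / KM_PER_DEG_LAT
            rows.append((s["population_id"], lon, lat, "grid"))
    rec = pd.DataFrame(rows, columns=["population_id", "lon", "lat", "role"])
    n_dropped = 0
    if extent is not None:
        xmin, ymin, xmax, ymax = extent
        inside = ((rec["lon"] >= xmin) & (rec["lon"] < xmax)
                  & (rec["lat"] > ymin) & (rec["lat"] <= ymax))
        n_dropped = int((~inside).sum())
        if n_dropped:
            warnings.warn(f"{n_dropped} expanded occurrence(s) fell outside "
                          "the raster extent and were dropped")
            rec = rec[inside].reset_index(drop=True)
    return OccurrenceSet(rec, n_dropped=n_dropped)


def extract_env(occ: OccurrenceSet | pd.DataFrame,
                stack: EnvRasterStack) -> pd.DataFrame:
    """Environmental values at each record's cell.

    Preserves record order and tags; records on no-data cells (or off-grid)
    are removed and counted in the ``n_dropped`` attribute of the result.
    """
    rec = occ.records if isinstance(occ, OccurrenceSet) else occ
    if rec.empty:
        raise ValueError("no records to extract")
    inside = stack.contains(rec["lon"].to_numpy(), rec["lat"].to_numpy())
    rec_in = rec[inside]
    row, col = stack.cell_of(rec_in["lon"].to_numpy(),
                             rec_in["lat"].to_numpy())
    valid = ~stack.nodata_mask[row, col]
    out = rec_in[valid].reset_index(drop=True).copy()
    if out.empty:
        raise ValueError("all records fall on no-data cells")
    r, c = row[valid], col[valid]
    for i, name in enumerate(stack.layer_names):
        out[name] = stack.values[i, r, c]
    out.attrs["n_dropped"] = int(len(rec) - len(out))
    return out


# ---------------------------------------------------------------------------
# Bias surface and background sampling
# ---------------------------------------------------------------------------

@dataclass
class BiasSurface:
    """Non-negative sampling weights aligned to a raster stack (max 1)."""

    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(w[~np.isnan(w)])):
            raise ValueError("bias weights must be finite")
        if np.nanmax(w) <= 0:
            raise ValueError("bias weights must not be all zero")
        self.weights = w


def silverman_bandwidth(coords: np.ndarray) -> float:
    """Scalar Silverman rule-of-thumb bandwidth (degrees) for 2-D points."""
    n = len(coords)
    if n < 2:
        return 0.05
    sd = coords.std(axis=0, ddof=1).mean()
    return max(float(sd * (4.0 / (3.0 * n)) ** 0.2), 1e-6)


def kernel_bias(occ: OccurrenceSet | pd.DataFrame, stack: EnvRasterStack,
                bandwidth: float | None = None) -> BiasSurface:
    """Gaussian kernel density of presence records at every cell, max-scaled.

    Background points sampled with these weights fall preferentially near
    presences, countering geographic sampling bias.
    """
    rec = occ.presences() if isinstance(occ, OccurrenceSet) else occ
    if rec.empty:
        raise ValueError("need at least one presence record")
    pts = rec[["lon", "lat"]].to_numpy(dtype=float)
    if bandwidth is None:
        bandwidth = silverman_bandwidth(pts)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    nrows, ncols = stack.shape
    rows, cols = np.meshgrid(np.arange(nrows), np.arange(ncols),
                             indexing="ij")
    lon, lat = stack.center_of(rows.ravel(), cols.ravel())
    d2 = ((lon[:, None] - pts[None, :, 0]) ** 2
          + (lat[:, None] - pts[None, :, 1]) ** 2)
    dens = np.exp(-d2 / (2.0 * bandwidth ** 2)).sum(axis=1)
    dens = dens.reshape(nrows, ncols)
    dens[stack.nodata_mask] = np.nan
    dens = dens / np.nanmax(dens)
    return BiasSurface(dens)


def sample_background(stack: EnvRasterStack, n: int = 10_000,
                      bias: BiasSurface | None = None,
                      seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Sample background cells, uniformly or proportional to bias weights.

    Sampling is without replacement over valid cells; ``n`` is capped by an
    error if it exceeds the number of cells with positive weight.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    rows, cols = stack.valid_cells()
    if bias is not None:
        w = bias.weights[rows, cols]
        w = np.where(np.isnan(w), 0.0, w)
        keep = w > 0
        rows, cols, w = rows[keep], cols[keep], w[keep]
        p = w / w.sum()
    else:
        p = None
    if n > len(rows):
        raise ValueError(
            f"requested {n} background points but only {len(rows)} "
            "cells are available")
    idx = rng.choice(len(rows), size=n, replace=False, p=p)
    idx = np.sort(idx)  # deterministic order independent of draw order
    lon, lat = stack.center_of(rows[idx], cols[idx])
    return pd.DataFrame({"population_id": "background", "lon": lon,
                         "lat": lat, "role": "background",
                         "row": rows[idx], "col": cols[idx]})
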