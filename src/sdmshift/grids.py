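"""Geographic raster grids: I/O, point extraction, covariate filtering, land-use aggregation.

All grids live on a plain-carree (WGS84 lon/lat) lattice with square cells,
rows ordered north to south and columns west to east.  Cell containment uses
half-open ``[west, east) x (south, north]`` intervals so every point belongs
to exactly one cell.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "GridSpec",
    "RasterGrid",
    "LayerStack",
    "EcosystemFractions",
    "GridAlignmentError",
    "RasterFormatError",
    "read_raster",
    "write_raster",
    "extract_at_points",
    "correlation_filter",
    "aggregate_landuse",
    "DEFAULT_STATE_MAPPING",
]


class GridAlignmentError(ValueError):
    """Two layers that must share a lattice do not."""


class RasterFormatError(ValueError):
    """A raster file is malformed or not geographically referenced."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a geographic raster lattice.

    Parameters
    ----------
    n_rows, n_cols
        Lattice dimensions; rows run north to south.
    west, north
        Outer (upper-left) corner in decimal degrees.
    cell_deg
        Angular size of the square cells, degrees.
    nodata
        Sentinel marking missing cells.
    """

    n_rows: int
    n_cols: int
    west: float
    north: float
    cell_deg: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.cell_deg <= 0:
            raise ValueError("cell size must be positive")
        if not (-180.0 <= self.west < 180.0):
            raise ValueError("west corner outside [-180, 180)")
        if not (-90.0 < self.north <= 90.0):
            raise ValueError("north corner outside (-90, 90]")
        if self.n_rows * self.cell_deg > 180.0 + 1e-9:
            raise ValueError("grid extends past the south pole")
        if self.n_cols * self.cell_deg > 360.0 + 1e-9:
            raise ValueError("grid wraps past 360 degrees of longitude")

    @property
    def south(self) -> float:
        return self.north - self.n_rows * self.cell_deg

    @property
    def east(self) -> float:
        return self.west + self.n_cols * self.cell_deg

    def lat_centers(self) -> np.ndarray:
        """Cell-center latitudes, north to south."""
        return self.north - (np.arange(self.n_rows) + 0.5) * self.cell_deg

    def lon_centers(self) -> np.ndarray:
        return self.west + (np.arange(self.n_cols) + 0.5) * self.cell_deg

    def locate(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map points to (row, col) under the half-open containment convention.

        Returns (row, col, inside) where ``inside`` flags points within the
        grid extent.  Longitude edges are half-open on the west side,
        latitude edges half-open on the south side, so the shared edge
        between two cells belongs to the west/north cell's neighbour per
        ``[lo, hi)`` / ``(lo, hi]``.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        tx = (lon - self.west) / self.cell_deg
        ty = (self.north - lat) / self.cell_deg
        col = np.floor(tx).astype(int)
        # latitude intervals are (south, north]: a point exactly on an
        # interior horizontal edge belongs to the row below it, which is what
        # floor of the top-down offset already yields; the north edge itself
        # (ty == 0) falls in row 0 and the south edge (ty == n_rows) outside
        row = np.floor(ty).astype(int)
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        return row, col, inside


@dataclass
class RasterGrid:
    """A named raster layer: values on a :class:`GridSpec` lattice.

    Missing cells are stored as NaN internally; ``spec.nodata`` is only a
    file-format sentinel.
    """

    spec: GridSpec
    values: np.ndarray
    name: str = "layer"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.spec.n_rows, self.spec.n_cols):
            raise GridAlignmentError(
                f"layer {self.name!r}: values shape {self.values.shape} does not match "
                f"spec ({self.spec.n_rows}, {self.spec.n_cols})"
            )
        if not self.name:
            raise ValueError("layer name must be non-empty")

    @property
    def data_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def with_values(self, values: np.ndarray, name: str | None = None) -> "RasterGrid":
        return RasterGrid(self.spec, values, name if name is not None else self.name)


@dataclass
class LayerStack:
    """Co-registered named raster layers plus scenario/period tags."""

    layers: dict[str, RasterGrid] = field(default_factory=dict)
    scenario: str = "near_current"
    period: str = ""

    def __post_init__(self) -> None:
        specs = {lyr.spec for lyr in self.layers.values()}
        if len(specs) > 1:
            raise GridAlignmentError("layers in a stack must share one GridSpec")

    @property
    def spec(self) -> GridSpec:
        if not self.layers:
            raise ValueError("empty stack has no GridSpec")
        return next(iter(self.layers.values())).spec

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def add(self, layer: RasterGrid) -> None:
        if self.layers and layer.spec != self.spec:
            raise GridAlignmentError(
                f"layer {layer.name!r} does not align with the stack lattice"
            )
        if layer.name in self.layers:
            raise ValueError(f"duplicate layer name {layer.name!r}")
        self.layers[layer.name] = layer

    def __getitem__(self, name: str) -> RasterGrid:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __len__(self) -> int:
        return len(self.layers)

    def complete_mask(self) -> np.ndarray:
        """Cells with data in every layer."""
        mask = np.ones((self.spec.n_rows, self.spec.n_cols), dtype=bool)
        for lyr in self.layers.values():
            mask &= lyr.data_mask
        return mask


@dataclass
class EcosystemFractions:
    """Per-cell fractions of the four ecosystems used for overlay accounting."""

    forest: RasterGrid
    cropland: RasterGrid
    grassland: RasterGrid
    urban: RasterGrid

    def __post_init__(self) -> None:
        specs = {g.spec for g in self.as_dict().values()}
        if len(specs) > 1:
            raise GridAlignmentError("ecosystem fraction layers must share one GridSpec")
        total = np.zeros_like(self.forest.values)
        for g in self.as_dict().values():
            vals = g.values
            with np.errstate(invalid="ignore"):
                if np.nanmin(vals) < -1e-9 or np.nanmax(vals) > 1 + 1e-9:
                    raise ValueError(f"fractions of {g.name!r} outside [0, 1]")
            total = total + np.nan_to_num(vals)
        if np.nanmax(total) > 1 + 1e-6:
            raise ValueError("per-cell ecosystem fractions sum above 1")

    def as_dict(self) -> dict[str, RasterGrid]:
        return {
            "forest": self.forest,
            "cropland": self.cropland,
            "grassland": self.grassland,
            "urban": self.urban,
        }


# ---------------------------------------------------------------------------
# raster I/O


def _read_ascii_grid(path: Path, name: str) -> RasterGrid:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line:
                raise RasterFormatError(f"{path}: truncated ASCII grid")
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
                "yllcenter", "cellsize", "nodata_value", "dx", "dy",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        data = np.loadtxt(fh, dtype=float)
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise RasterFormatError(f"{path}: missing ASCII grid header field {key}")
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    cell = header["cellsize"]
    if "xllcorner" in header:
        west = header["xllcorner"]
    elif "xllcenter" in header:
        west = header["xllcenter"] - cell / 2
    else:
        raise RasterFormatError(f"{path}: no x georeference")
    if "yllcorner" in header:
        south = header["yllcorner"]
    elif "yllcenter" in header:
        south = header["yllcenter"] - cell / 2
    else:
        raise RasterFormatError(f"{path}: no y georeference")
    nodata = header.get("nodata_value", -9999.0)
    data = np.atleast_2d(data)
    if data.shape != (n_rows, n_cols):
        raise RasterFormatError(
            f"{path}: data block {data.shape} does not match header ({n_rows}, {n_cols})"
        )
    spec = GridSpec(n_rows, n_cols, west, south + n_rows * cell, cell, nodata)
    values = np.where(data == nodata, np.nan, data)
    return RasterGrid(spec, values, name)


def _write_ascii_grid(grid: RasterGrid, path: Path) -> None:
    spec = grid.spec
    out = np.where(np.isfinite(grid.values), grid.values, spec.nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {spec.n_cols}\n")
        fh.write(f"nrows {spec.n_rows}\n")
        fh.write(f"xllcorner {spec.west!r}\n")
        fh.write(f"yllcorner {spec.south!r}\n")
        fh.write(f"cellsize {spec.cell_deg!r}\n")
        fh.write(f"NODATA_value {spec.nodata!r}\n")
        np.savetxt(fh, out, fmt="%.17g")


_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922


def _read_geotiff(path: Path, name: str) -> RasterGrid:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray().astype(float)
        tags = {t.code: t.value for t in page.tags.values()}
    if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
        raise RasterFormatError(f"{path}: GeoTIFF lacks georeferencing tags")
    sx, sy = float(tags[_TAG_PIXEL_SCALE][0]), float(tags[_TAG_PIXEL_SCALE][1])
    if abs(sx - sy) > 1e-9:
        raise RasterFormatError(f"{path}: non-square cells ({sx} x {sy})")
    tie = tags[_TAG_TIEPOINT]
    west = float(tie[3]) - float(tie[0]) * sx
    north = float(tie[4]) + float(tie[1]) * sy
    if data.ndim != 2:
        raise RasterFormatError(f"{path}: expected a single-band raster")
    nodata = -9999.0
    if 42113 in tags:  # GDAL_NODATA ascii tag
        try:
            nodata = float(str(tags[42113]).strip("\x00 "))
        except ValueError:
            pass
    spec = GridSpec(data.shape[0], data.shape[1], west, north, sx, nodata)
    values = np.where(np.isclose(data, nodata), np.nan, data)
    return RasterGrid(spec, values, name)


def _write_geotiff(grid: RasterGrid, path: Path) -> None:
    spec = grid.spec
    out = np.where(np.isfinite(grid.values), grid.values, spec.nodata).astype(np.float64)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (spec.cell_deg, spec.cell_deg, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, spec.west, spec.north, 0.0)),
        (42113, "s", 0, str(spec.nodata)),
    ]
    tifffile.imwrite(path, out, extratags=extratags)


def read_raster(path: str | Path, format: str | None = None, name: str | None = None) -> RasterGrid:
    """Read a single-band geographic raster.

    ``format`` is ``"geotiff"`` or ``"ascii_grid"``; inferred from the file
    suffix when omitted (.tif/.tiff vs anything else).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "geotiff" if path.suffix.lower() in {".tif", ".tiff"} else "ascii_grid"
    layer_name = name if name is not None else path.stem
    if format == "geotiff":
        return _read_geotiff(path, layer_name)
    if format == "ascii_grid":
        return _read_ascii_grid(path, layer_name)
    raise ValueError(f"unknown raster format {format!r}")


def write_raster(grid: RasterGrid, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "geotiff" if path.suffix.lower() in {".tif", ".tiff"} else "ascii_grid"
    if format == "geotiff":
        _write_geotiff(grid, path)
    elif format == "ascii_grid":
        _write_ascii_grid(grid, path)
    else:
        raise ValueError(f"unknown raster format {format!r}")


def read_stack(manifest: str | Path, scenario: str = "near_current", period: str = "") -> LayerStack:
    """Read a stack declared by a JSON manifest mapping layer name to path."""
    manifest = Path(manifest)
    mapping = json.loads(manifest.read_text())
    stack = LayerStack(scenario=scenario, period=period)
    for name, rel in mapping.items():
        stack.add(read_raster(manifest.parent / rel, name=name))
    return stack


# ---------------------------------------------------------------------------
# point extraction


def extract_at_points(stack: LayerStack, points) -> tuple[np.ndarray, np.ndarray]:
    """Extract stack values at point locations.

    Parameters
    ----------
    stack
        Non-empty layer stack.
    points
        Anything with ``longitude`` / ``latitude`` columns (an occurrence
        table's dataframe) or a (n, 2) array of lon/lat.

    Returns
    -------
    X : (n_points, n_layers) array with NaN where masked
    valid : boolean mask of points inside the grid with data in every layer
    """
    if len(stack) == 0:
        raise ValueError("cannot extract from an empty stack")
    if hasattr(points, "longitude"):
        lon = np.asarray(points.longitude, dtype=float)
        lat = np.asarray(points.latitude, dtype=float)
    elif isinstance(points, pd.DataFrame):
        lon = points["longitude"].to_numpy(float)
        lat = points["latitude"].to_numpy(float)
    else:
        arr = np.asarray(points, dtype=float)
        lon, lat = arr[:, 0], arr[:, 1]
    row, col, inside = stack.spec.locate(lon, lat)
    n = len(lon)
    X = np.full((n, len(stack)), np.nan)
    r, c = row[inside], col[inside]
    for j, name in enumerate(stack.names):
        X[inside, j] = stack[name].values[r, c]
    valid = inside & np.all(np.isfinite(X), axis=1)
    return X, valid


# ---------------------------------------------------------------------------
# covariate selection


def _pairwise_pearson(X: np.ndarray) -> np.ndarray:
    """Pairwise-complete Pearson correlation; zero-variance pairs get r = 0."""
    n, p = X.shape
    R = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            ok = np.isfinite(X[:, i]) & np.isfinite(X[:, j])
            if ok.sum() < 2:
                r = 0.0
            else:
                xi, xj = X[ok, i], X[ok, j]
                si, sj = xi.std(), xj.std()
                if si == 0 or sj == 0:
                    r = 0.0
                else:
                    r = float(np.corrcoef(xi, xj)[0, 1])
            R[i, j] = R[j, i] = r
    return R


def correlation_filter(
    X: np.ndarray,
    names: list[str],
    contributions: dict[str, float],
    r_threshold: float = 0.8,
) -> tuple[list[str], dict]:
    """Greedy Pearson-correlation pruning of covariates.

    Covariates are visited in order of descending contribution (ties broken
    alphabetically) and kept unless their absolute correlation with an
    already-kept covariate exceeds ``r_threshold``.

    Returns the kept names (in contribution order) and a report recording
    drops and zero-variance flags.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples to compute correlations")
    missing = [n for n in names if n not in contributions]
    if missing:
        raise ValueError(f"contributions missing for layers: {missing}")
    order = sorted(range(len(names)), key=lambda i: (-contributions[names[i]], names[i]))
    R = _pairwise_pearson(X)
    constant = [names[i] for i in range(len(names)) if np.nanstd(X[:, i]) == 0]
    kept: list[int] = []
    dropped: list[dict] = []
    for i in order:
        clash = next((j for j in kept if abs(R[i, j]) > r_threshold), None)
        if clash is None:
            kept.append(i)
        else:
            dropped.append(
                {"layer": names[i], "against": names[clash], "r": float(R[i, clash])}
            )
    report = {"dropped": dropped, "constant_layers": constant, "r_threshold": r_threshold}
    return [names[i] for i in kept], report


# ---------------------------------------------------------------------------
# land-use aggregation

#: LUH2 state names -> ecosystem groups
DEFAULT_STATE_MAPPING: dict[str, str] = {
    "primf": "forest",
    "secdf": "forest",
    "c3ann": "cropland",
    "c4ann": "cropland",
    "c3per": "cropland",
    "c4per": "cropland",
    "c3nfx": "cropland",
    "range": "grassland",
    "pastr": "grassland",
    "urban": "urban",
}


def aggregate_landuse(
    states: LayerStack, mapping: dict[str, str] | None = None
) -> EcosystemFractions:
    """Sum LUH2-style per-cell state fractions into the four ecosystems.

    ``mapping`` maps state layer name to one of forest / cropland /
    grassland / urban; states absent from the mapping are ignored, but every
    mapped state must be present in the stack.
    """
    mapping = DEFAULT_STATE_MAPPING if mapping is None else mapping
    missing = [s for s in mapping if s not in states]
    if missing:
        raise KeyError(f"land-use stack is missing mapped state layers: {missing}")
    spec = states.spec
    sums = {
        eco: np.zeros((spec.n_rows, spec.n_cols))
        for eco in ("forest", "cropland", "grassland", "urban")
    }
    for state, eco in mapping.items():
        if eco not in sums:
            raise ValueError(f"unknown ecosystem {eco!r} for state {state!r}")
        sums[eco] = sums[eco] + states[state].values
    out = {}
    for eco, vals in sums.items():
        out[eco] = RasterGrid(spec, np.clip(vals, 0.0, 1.0), eco)
    return EcosystemFractions(**out)
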