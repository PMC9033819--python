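"""Raster data model and I/O for co-registered indicator stacks.

A :class:`Grid` is a single-band georeferenced 2-D array with an explicit
nodata mask; a :class:`GridStack` is an ordered collection of grids sharing
one geometry.  All downstream arithmetic operates on the *joint* valid mask
(a cell missing in any indicator is excluded everywhere), and analyses run
on the flattened :class:`SampleMatrix` of jointly valid cells.

Array row 0 is the northern edge; ``origin`` is the map coordinate of the
north-west corner; cell area is ``cell_size**2`` square metres.  Supported
on-disk formats are single-band GeoTIFF (via tifffile, with the GeoTIFF
pixel-scale and tiepoint tags) and ESRI ASCII grid with the -9999 nodata
sentinel.  Grids whose geometries disagree are refused rather than
resampled: silent reprojection would corrupt the evaluation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

ASCII_NODATA = -9999.0

# GeoTIFF tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GDAL_NODATA = 42113


class GridFormatError(ValueError):
    """Raised when a raster file cannot be parsed."""


class AlignmentError(ValueError):
    """Raised when grids of a stack disagree in geometry."""


class EmptyDomainError(ValueError):
    """Raised when no jointly valid cell remains."""


@dataclass
class Grid:
    """Single-band raster with nodata mask and minimal georeference."""

    values: np.ndarray
    nodata_mask: np.ndarray
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    crs_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("Grid values must be 2-D")
        if self.values.shape != self.nodata_mask.shape:
            raise ValueError("values and nodata_mask shapes differ")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]

    def with_values(self, values: np.ndarray) -> "Grid":
        """New grid with the same geometry/mask and different values."""
        return Grid(np.asarray(values, dtype=float), self.nodata_mask.copy(),
                    self.cell_size, self.origin, self.crs_label)

    def equals(self, other: "Grid", tol: float = 1e-6) -> bool:
        if self.shape != other.shape:
            return False
        if not np.array_equal(self.nodata_mask, other.nodata_mask):
            return False
        a, b = self.values[self.valid_mask], other.values[other.valid_mask]
        return bool(np.allclose(a, b, atol=tol, rtol=0))


@dataclass
class RegionMask:
    """Named boolean sub-region; area accounting uses only valid cells."""

    name: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


class GridStack:
    """Ordered, geometry-aligned collection of indicator grids."""

    def __init__(self, grids: Mapping[str, Grid]):
        if not grids:
            raise ValueError("empty stack")
        self.grids: dict[str, Grid] = dict(grids)
        first_id, first = next(iter(self.grids.items()))
        for gid, g in self.grids.items():
            if g.shape != first.shape:
                raise AlignmentError(f"indicator {gid!r}: shape {g.shape} != {first.shape}")
            if abs(g.cell_size - first.cell_size) > 1e-6:
                raise AlignmentError(f"indicator {gid!r}: cell_size mismatch")
            if (abs(g.origin[0] - first.origin[0]) > 1e-6
                    or abs(g.origin[1] - first.origin[1]) > 1e-6):
                raise AlignmentError(f"indicator {gid!r}: origin mismatch")
        mask = np.ones(first.shape, dtype=bool)
        for g in self.grids.values():
            mask &= g.valid_mask
        self.joint_valid_mask = mask

    @property
    def indicator_ids(self) -> list[str]:
        return list(self.grids)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.grids.values())).shape

    @property
    def cell_size(self) -> float:
        return next(iter(self.grids.values())).cell_size

    @property
    def origin(self) -> tuple[float, float]:
        return next(iter(self.grids.values())).origin

    def __getitem__(self, gid: str) -> Grid:
        return self.grids[gid]

    def __len__(self) -> int:
        return len(self.grids)


@dataclass
class SampleMatrix:
    """Flattened jointly-valid cells: rows are cells, columns indicators."""

    x: np.ndarray
    cell_index: np.ndarray  # (n, 2) row/col positions, row-major order
    indicator_ids: list[str]
    grid_shape: tuple[int, int]
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def m(self) -> int:
        return self.x.shape[1]


def align_stack(grids: Mapping[str, Grid]) -> GridStack:
    """Assemble pre-aligned grids into a stack with a joint valid mask."""
    return GridStack(grids)


def flatten_valid(stack: GridStack) -> SampleMatrix:
    """Flatten the jointly valid cells to an n x m sample matrix.

    Row order is deterministic row-major over the grid, so the inverse
    mapping (``rasterize``) restores the original surfaces exactly.
    """
    mask = stack.joint_valid_mask
    if not mask.any():
        raise EmptyDomainError("no jointly valid cell in the stack")
    rows, cols = np.nonzero(mask)
    x = np.column_stack([stack[gid].values[rows, cols] for gid in stack.indicator_ids])
    cell_index = np.column_stack([rows, cols])
    return SampleMatrix(x, cell_index, stack.indicator_ids, stack.shape,
                        stack.cell_size, stack.origin)


def rasterize(sample: SampleMatrix, values: Sequence[float],
              crs_label: str = "") -> Grid:
    """Scatter per-sample values back to a grid; other cells are nodata."""
    values = np.asarray(values, dtype=float)
    if values.shape[0] != sample.n:
        raise ValueError("value count does not match sample count")
    out = np.full(sample.grid_shape, np.nan)
    mask = np.ones(sample.grid_shape, dtype=bool)
    r, c = sample.cell_index[:, 0], sample.cell_index[:, 1]
    out[r, c] = values
    mask[r, c] = False
    return Grid(out, mask, sample.cell_size, sample.origin, crs_label)


# ---------------------------------------------------------------------------
# I/O


def read_grid(path: str | Path, format: str | None = None) -> Grid:
    """Read a single-band raster (``geotiff`` or ``ascii_grid``).

    Format is inferred from the suffix when not given.  Missing
    georeference falls back to cell_size 1 / origin (0, 0) with a warning.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "ascii_grid":
        return _read_ascii(path)
    if fmt == "geotiff":
        return _read_geotiff(path)
    raise GridFormatError(f"unknown raster format {fmt!r}")


def write_grid(grid: Grid, path: str | Path, format: str | None = None) -> None:
    """Write a grid so that :func:`read_grid` recovers it (values to 1e-6)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "ascii_grid":
        _write_ascii(grid, path)
    elif fmt == "geotiff":
        _write_geotiff(grid, path)
    else:
        raise GridFormatError(f"unknown raster format {fmt!r}")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".asc", ".agr", ".txt"}:
        return "ascii_grid"
    if suffix in {".tif", ".tiff"}:
        return "geotiff"
    raise GridFormatError(f"cannot infer raster format from {path.name!r}")


def _is_integral(grid: Grid) -> bool:
    v = grid.valid_values()
    return v.size > 0 and bool(np.all(v == np.round(v))) and bool(
        np.all(np.abs(v) < 3e4))


def _read_ascii(path: Path) -> Grid:
    header: dict[str, float] = {}
    lines = path.read_text().splitlines()
    i = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
                "yllcenter", "cellsize", "nodata_value"}:
            header[parts[0].lower()] = float(parts[1])
        else:
            break
    try:
        ncols, nrows = int(header["ncols"]), int(header["nrows"])
        cell = float(header["cellsize"])
    except KeyError as exc:
        raise GridFormatError(f"{path}: missing ASCII grid header field {exc}")
    nodata = header.get("nodata_value", ASCII_NODATA)
    try:
        values = np.loadtxt(lines[i:], dtype=float)
    except ValueError as exc:
        raise GridFormatError(f"{path}: cannot parse ASCII grid body: {exc}")
    values = np.atleast_2d(values)
    if values.shape != (nrows, ncols):
        values = values.reshape(nrows, ncols)
    mask = (values == nodata) | ~np.isfinite(values)
    xll = header.get("xllcorner", header.get("xllcenter", 0.0))
    yll = header.get("yllcorner", header.get("yllcenter", 0.0))
    origin = (xll, yll + nrows * cell)  # north-west corner
    return Grid(values, mask, cell, origin)


def _write_ascii(grid: Grid, path: Path) -> None:
    nrows, ncols = grid.shape
    yll = grid.origin[1] - nrows * grid.cell_size
    values = np.where(grid.nodata_mask, ASCII_NODATA, grid.values)
    fmt = "%d" if _is_integral(grid) else "%.10g"
    header = (f"ncols {ncols}\nnrows {nrows}\n"
              f"xllcorner {grid.origin[0]:.10g}\nyllcorner {yll:.10g}\n"
              f"cellsize {grid.cell_size:.10g}\nNODATA_value {int(ASCII_NODATA)}\n")
    body = "\n".join(" ".join(fmt % v for v in row) for row in values)
    path.write_text(header + body + "\n")


def _write_geotiff(grid: Grid, path: Path) -> None:
    if _is_integral(grid):
        arr = np.where(grid.nodata_mask, ASCII_NODATA, grid.values).astype(np.int16)
    else:
        arr = np.where(grid.nodata_mask, np.nan, grid.values).astype(np.float32)
    nodata_str = str(int(ASCII_NODATA)) if arr.dtype == np.int16 else "nan"
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0), True),
        (_MODEL_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, grid.origin[0], grid.origin[1], 0.0), True),
        (_GDAL_NODATA, "s", 0, nodata_str, True),
    ]
    tifffile.imwrite(path, arr, extratags=extratags,
                     description=json.dumps({"crs": grid.crs_label}))


def _tag_value(tags, key):
    tag = tags.get(key)
    return None if tag is None else tag.value


def _read_geotiff(path: Path) -> Grid:
    try:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            arr = page.asarray()
            tags = page.tags
            scale = _tag_value(tags, _MODEL_PIXEL_SCALE)
            tie = _tag_value(tags, _MODEL_TIEPOINT)
            nod = _tag_value(tags, _GDAL_NODATA)
            desc = _tag_value(tags, "ImageDescription")
    except (tifffile.TiffFileError, OSError) as exc:
        raise GridFormatError(f"{path}: not a readable TIFF: {exc}")
    if arr.ndim != 2:
        raise GridFormatError(f"{path}: expected a single-band raster")
    if scale is not None and tie is not None:
        cell_size = float(scale[0])
        origin = (float(tie[3]), float(tie[4]))
    else:
        warnings.warn(f"{path}: no georeference tags; assuming cell_size=1, "
                      "origin=(0, 0)", stacklevel=2)
        cell_size, origin = 1.0, (0.0, 0.0)
    values = arr.astype(float)
    if nod is not None and str(nod).strip().lower() != "nan":
        mask = values == float(nod)
    else:
        mask = ~np.isfinite(values)
    crs_label = ""
    if desc is not None:
        try:
            crs_label = json.loads(desc).get("crs", "")
        except (json.JSONDecodeError, AttributeError, TypeError):
            pass
    return Grid(values, mask, cell_size, origin, crs_label)
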