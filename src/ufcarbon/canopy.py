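"""Point-grid canopy-cover estimation on categorical landcover grids.

The sampling design mirrors the national canopy survey: a 1-km2 grid is laid
over the urban area, 25% of grid cells are drawn uniformly without
replacement, and each selected cell receives 55 evenly spaced interpretation
points.  Quality-control rules: a cell with 25% or less of its area urban is
discarded, and points over cloud/distortion are removed before estimation.

Canopy cover is the fraction of retained points labelled canopy.  Two
standard errors are reported: a binomial SE treating points as independent
Bernoulli draws, and a cluster (cell-mean) SE that respects the two-stage
design.  Points within a cell are spatially structured, so the binomial SE
understates design uncertainty when cover varies between cells; both are
exposed so either convention can be reproduced.

Grids are single-band categorical rasters: GeoTIFF (read via tifffile) or a
plain-text integer matrix.  Cell/pixel indexing is 0-based, row-major;
cells are half-open pixel ranges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import NoDataError, UFCarbonError, ValidationError

# category codes
NON_URBAN = 0
OTHER_URBAN = 1
CANOPY = 2
CLOUD = 3

_URBAN_CODES = (OTHER_URBAN, CANOPY)

#: a cell qualifies only if strictly more than this fraction of it is urban
URBAN_FRACTION_CUTOFF = 0.25


@dataclass(frozen=True)
class LandcoverGrid:
    """Rectangular categorical raster with a pixel size in metres."""

    data: np.ndarray  # 2-D int array of category codes
    resolution: float = 10.0  # metres per pixel

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.ndim != 2 or arr.size == 0:
            raise ValidationError("grid must be a non-empty 2-D array")
        if not np.isin(arr, (NON_URBAN, OTHER_URBAN, CANOPY, CLOUD)).all():
            raise ValidationError("grid contains unclassified pixel values")
        object.__setattr__(self, "data", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass(frozen=True)
class Cell:
    """One sampling cell: half-open pixel bounds [row0:row1, col0:col1]."""

    index: tuple[int, int]  # (cell_row, cell_col)
    row0: int
    col0: int
    row1: int
    col1: int


@dataclass(frozen=True)
class SamplePoint:
    """One interpretation point with its label and QC status."""

    row: int
    col: int
    label: int
    cell: tuple[int, int]
    discarded: bool = False
    reason: str | None = None  # "cloud_or_distortion" | "cell_not_urban"


@dataclass(frozen=True)
class CanopyEstimate:
    """Point-sampling canopy estimate; ``fraction`` is None when no data."""

    fraction: float | None
    se: float | None  # binomial SE
    se_cluster: float | None  # cell-mean SE (None with < 2 cells)
    n_used: int
    n_discarded: int


def read_grid(path, resolution: float = 10.0) -> LandcoverGrid:
    """Read a categorical grid from GeoTIFF (.tif/.tiff) or whitespace text."""
    p = Path(path)
    if p.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = np.asarray(tifffile.imread(str(p)))
        if arr.ndim == 3:  # single-band stored with a trailing axis
            arr = arr[..., 0]
    else:
        arr = np.loadtxt(p, dtype=int)
        if arr.ndim == 1:
            arr = arr[None, :]
    return LandcoverGrid(data=arr.astype(int), resolution=resolution)


def write_grid(grid: LandcoverGrid, path) -> None:
    p = Path(path)
    if p.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(str(p), grid.data.astype(np.uint8))
    else:
        np.savetxt(p, grid.data, fmt="%d")


def iter_cells(grid: LandcoverGrid, cell_size_km: float = 1.0):
    """All complete cells of the grid (edge remainders are not sampled)."""
    px = int(round(cell_size_km * 1000.0 / grid.resolution))
    if px < 1:
        raise UFCarbonError("cell size is below one pixel")
    nrows, ncols = grid.shape
    for ci in range(nrows // px):
        for cj in range(ncols // px):
            yield Cell(
                index=(ci, cj),
                row0=ci * px,
                col0=cj * px,
                row1=(ci + 1) * px,
                col1=(cj + 1) * px,
            )


def cell_urban_fraction(grid: LandcoverGrid, cell: Cell) -> float:
    block = grid.data[cell.row0 : cell.row1, cell.col0 : cell.col1]
    return float(np.isin(block, _URBAN_CODES).mean())


def select_cells(
    grid: LandcoverGrid,
    cell_size_km: float = 1.0,
    sampling_rate: float = 0.25,
    seed: int | np.random.Generator | None = None,
) -> list[Cell]:
    """Draw cells uniformly without replacement at ``sampling_rate``.

    Cells failing the urban QC rule (<= 25% urban area) are discarded before
    sampling; round(rate x n_qualifying) cells are drawn.  Reproducible for a
    fixed seed; results are sorted by cell index.
    """
    if not 0 < sampling_rate <= 1:
        raise UFCarbonError("sampling_rate must be in (0, 1]")
    cells = list(iter_cells(grid, cell_size_km))
    if not cells:
        raise UFCarbonError("grid does not cover a single full cell")
    qualifying = [
        c for c in cells if cell_urban_fraction(grid, c) > URBAN_FRACTION_CUTOFF
    ]
    if not qualifying:
        return []
    n_draw = int(round(sampling_rate * len(qualifying)))
    n_draw = min(max(n_draw, 1), len(qualifying)) if sampling_rate > 0 else 0
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(qualifying), size=n_draw, replace=False)
    return [qualifying[i] for i in sorted(chosen)]


def _lattice_shape(n: int) -> tuple[int, int]:
    """Rows x cols factorisation of n closest to square (rows <= cols)."""
    best = (1, n)
    for r in range(1, int(math.isqrt(n)) + 1):
        if n % r == 0:
            best = (r, n // r)
    return best


def place_points(cell: Cell, n_points: int = 55) -> list[tuple[int, int]]:
    """Evenly spaced points on a regular lattice inside the cell.

    The lattice is the rows x cols factorisation of ``n_points`` closest to
    square (55 -> 5 x 11) with half-spacing margins, so adjacent cells yield
    disjoint point sets.  Deterministic given the cell.
    """
    if n_points < 1:
        raise UFCarbonError("n_points must be >= 1")
    rows, cols = _lattice_shape(n_points)
    h = cell.row1 - cell.row0
    w = cell.col1 - cell.col0
    pts = []
    for i in range(rows):
        r = cell.row0 + int((i + 0.5) * h / rows)
        for j in range(cols):
            c = cell.col0 + int((j + 0.5) * w / cols)
            pts.append((r, c))
    return pts


def sample_points(
    grid: LandcoverGrid,
    cells: list[Cell],
    n_points: int = 55,
) -> list[SamplePoint]:
    """Label lattice points in the given cells; cloud points are discarded."""
    out = []
    for cell in cells:
        for r, c in place_points(cell, n_points):
            label = int(grid.data[r, c])
            discarded = label == CLOUD
            out.append(
                SamplePoint(
                    row=r,
                    col=c,
                    label=label,
                    cell=cell.index,
                    discarded=discarded,
                    reason="cloud_or_distortion" if discarded else None,
                )
            )
    return out


def estimate_canopy(points: list[SamplePoint]) -> CanopyEstimate:
    """Canopy fraction with binomial and cluster standard errors.

    Raises :class:`NoDataError` when every point was discarded (a no-data
    outcome is not a zero-cover outcome).
    """
    kept = [p for p in points if not p.discarded]
    n_disc = len(points) - len(kept)
    if not kept:
        raise NoDataError("all sample points were discarded")
    n = len(kept)
    hits = sum(1 for p in kept if p.label == CANOPY)
    p_hat = hits / n
    se = math.sqrt(p_hat * (1.0 - p_hat) / n)

    by_cell: dict[tuple[int, int], list[int]] = {}
    for pt in kept:
        by_cell.setdefault(pt.cell, []).append(1 if pt.label == CANOPY else 0)
    se_cluster = None
    if len(by_cell) >= 2:
        means = np.array([np.mean(v) for v in by_cell.values()])
        se_cluster = float(means.std(ddof=1) / math.sqrt(len(means)))
    return CanopyEstimate(
        fraction=p_hat,
        se=se,
        se_cluster=se_cluster,
        n_used=n,
        n_discarded=n_disc,
    )


def estimate_grid_canopy(
    grid: LandcoverGrid,
    cell_size_km: float = 1.0,
    sampling_rate: float = 0.25,
    n_points: int = 55,
    seed: int | None = None,
) -> CanopyEstimate:
    """Full design: select cells, place and label points, estimate cover.

    Returns a no-data estimate (``fraction`` None) when no cell qualifies.
    """
    cells = select_cells(grid, cell_size_km, sampling_rate, seed)
    if not cells:
        return CanopyEstimate(
            fraction=None, se=None, se_cluster=None, n_used=0, n_discarded=0
        )
    return estimate_canopy(sample_points(grid, cells, n_points))
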