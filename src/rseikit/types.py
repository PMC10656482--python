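"""Core containers: land-use rasters, area tables, transfer matrices,
spectral scenes and single-indicator rasters.

Conventions
-----------
* Grids are row-major 2-D numpy arrays, origin top-left, pixel-is-area.
* Land-use class codes are fixed integers: 1=water, 2=construction,
  3=grassland, 4=cultivated, 5=forest, 6=unused; 0 marks nodata.
* Areas are km²; a 30 m Landsat cell is 0.0009 km².
* Geotransform/CRS metadata is carried opaquely and never interpreted;
  inputs are assumed pre-aligned.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError

# ---------------------------------------------------------------------------
# land-use class codes

WATER, CONSTRUCTION, GRASSLAND, CULTIVATED, FOREST, UNUSED = 1, 2, 3, 4, 5, 6
NODATA_CODE = 0

CLASS_NAMES: dict[int, str] = {
    WATER: "water",
    CONSTRUCTION: "construction",
    GRASSLAND: "grassland",
    CULTIVATED: "cultivated",
    FOREST: "forest",
    UNUSED: "unused",
}
CLASS_CODES: dict[str, int] = {name: code for code, name in CLASS_NAMES.items()}
ALL_CLASSES: tuple[int, ...] = tuple(CLASS_NAMES)

#: Land-use intensity grades for the comprehensive dynamics index: unused
#: land 1, water/forest/grassland 2, cultivated 3, construction 4.
DEFAULT_GRADING: dict[int, int] = {
    UNUSED: 1,
    WATER: 2,
    FOREST: 2,
    GRASSLAND: 2,
    CULTIVATED: 3,
    CONSTRUCTION: 4,
}


def _check_aligned(shape_a, shape_b, transform_a=None, transform_b=None) -> None:
    if tuple(shape_a) != tuple(shape_b):
        raise AlignmentError(f"grid shapes differ: {tuple(shape_a)} vs {tuple(shape_b)}")
    if transform_a is not None and transform_b is not None and transform_a != transform_b:
        raise AlignmentError("geotransforms differ between co-registered inputs")


# ---------------------------------------------------------------------------
# land-use raster


@dataclass
class LandUseRaster:
    """Categorical land-use grid for one epoch.

    Parameters
    ----------
    grid : integer array with class codes 1..6 and 0 for nodata.
    cell_area : area of one cell in km² (> 0).
    epoch : year label, e.g. 2000.
    transform, crs : opaque geo-metadata, carried through unchanged.
    """

    grid: np.ndarray
    cell_area: float = 0.0009
    epoch: int | str | None = None
    transform: tuple | None = None
    crs: str | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError("land-use grid must be 2-D")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise ValueError("land-use grid must hold integer class codes")
        if self.cell_area <= 0:
            raise ValueError("cell_area must be positive")
        codes = np.unique(self.grid)
        bad = set(codes.tolist()) - ({NODATA_CODE} | set(ALL_CLASSES))
        if bad:
            raise ValueError(f"unknown class codes in raster: {sorted(bad)}")

    @property
    def valid_mask(self) -> np.ndarray:
        return self.grid != NODATA_CODE

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape  # type: ignore[return-value]

    def class_mask(self, code: int) -> np.ndarray:
        """Boolean mask of cells carrying the given class code."""
        return self.grid == code


# ---------------------------------------------------------------------------
# area table


@dataclass
class AreaTable:
    """Per-class areas (km²) at one epoch."""

    epoch: int | str
    areas: pd.Series  # index: class codes 1..6, values: km²

    def __post_init__(self) -> None:
        s = pd.Series(self.areas, dtype=float)
        # accept name-keyed mappings too
        if s.index.dtype == object:
            s.index = [CLASS_CODES[str(k)] for k in s.index]
        s = s.reindex(ALL_CLASSES, fill_value=0.0)
        if (s < 0).any():
            raise ValueError("class areas must be nonnegative")
        self.areas = s

    @classmethod
    def from_mapping(cls, epoch, mapping: Mapping) -> "AreaTable":
        return cls(epoch=epoch, areas=pd.Series(dict(mapping), dtype=float))

    @property
    def total(self) -> float:
        return float(self.areas.sum())

    def proportions(self) -> pd.Series:
        """Class-area fractions of this epoch's own total."""
        total = self.total
        if total <= 0:
            raise ZeroDivisionError("area table total is zero; proportions undefined")
        return self.areas / total

    def named(self) -> pd.Series:
        """Areas re-indexed by class name (for reports)."""
        out = self.areas.copy()
        out.index = [CLASS_NAMES[c] for c in out.index]
        return out


# ---------------------------------------------------------------------------
# transfer matrix


@dataclass
class TransferMatrix:
    """Cross-tabulated areas (km²) by (class at epoch a, class at epoch b).

    Off-diagonal row sums are the per-class "reduce" areas (lost by the
    from-class); off-diagonal column sums are the "add" areas (gained by the
    to-class).
    """

    epoch_a: int | str
    epoch_b: int | str
    cells: pd.DataFrame  # index: from-class codes, columns: to-class codes

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.cells, dtype=float)
        if df.index.dtype == object:
            df.index = [CLASS_CODES[str(k)] for k in df.index]
        if df.columns.dtype == object:
            df.columns = [CLASS_CODES[str(k)] for k in df.columns]
        df = df.reindex(index=ALL_CLASSES, columns=ALL_CLASSES, fill_value=0.0)
        if (df.values < 0).any():
            raise ValueError("transfer-matrix cells must be nonnegative")
        self.cells = df

    @property
    def row_totals(self) -> pd.Series:
        """Epoch-a class areas implied by the matrix."""
        return self.cells.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        """Epoch-b class areas implied by the matrix."""
        return self.cells.sum(axis=0)

    @property
    def reduce_area(self) -> pd.Series:
        """Area each class lost to other classes (off-diagonal row sums)."""
        diag = pd.Series(np.diag(self.cells.values), index=self.cells.index)
        return self.row_totals - diag

    @property
    def add_area(self) -> pd.Series:
        """Area each class gained from other classes (off-diagonal column sums)."""
        diag = pd.Series(np.diag(self.cells.values), index=self.cells.columns)
        return self.col_totals - diag

    @property
    def grand_total(self) -> float:
        return float(self.cells.values.sum())

    def named(self) -> pd.DataFrame:
        out = self.cells.copy()
        out.index = [CLASS_NAMES[c] for c in out.index]
        out.columns = [CLASS_NAMES[c] for c in out.columns]
        return out


# ---------------------------------------------------------------------------
# spectral scene

REFLECTIVE_BANDS: tuple[str, ...] = ("blue", "green", "red", "nir", "swir1", "swir2")


@dataclass
class SpectralScene:
    """Co-registered surface-reflectance bands plus an optional thermal band.

    Reflectances are dimensionless, nominally in (0, 1); the thermal band is
    a raw digital-number grid to be run through the single-channel
    temperature inversion. ``sensor`` selects the tasseled-cap wetness
    coefficient set ("TM" or "OLI_TIRS").
    """

    bands: dict[str, np.ndarray]
    thermal_dn: np.ndarray | None = None
    sensor: str = "TM"
    mask: np.ndarray | None = None
    epoch: int | str | None = None
    transform: tuple | None = None
    crs: str | None = None

    def __post_init__(self) -> None:
        missing = [b for b in REFLECTIVE_BANDS if b not in self.bands]
        if missing:
            raise ValueError(f"scene is missing reflective bands: {missing}")
        shapes = {b: np.asarray(a).shape for b, a in self.bands.items()}
        ref = shapes[REFLECTIVE_BANDS[0]]
        for b, shp in shapes.items():
            if shp != ref:
                raise AlignmentError(f"band {b!r} shape {shp} != {ref}")
        self.bands = {b: np.asarray(a, dtype=float) for b, a in self.bands.items()}
        if self.thermal_dn is not None:
            self.thermal_dn = np.asarray(self.thermal_dn, dtype=float)
            _check_aligned(self.thermal_dn.shape, ref)
        if self.mask is None:
            self.mask = np.ones(ref, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            _check_aligned(self.mask.shape, ref)

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands["blue"].shape  # type: ignore[return-value]

    def band(self, name: str) -> np.ndarray:
        return self.bands[name]


# ---------------------------------------------------------------------------
# single-indicator raster


@dataclass
class IndexRaster:
    """One continuous per-cell indicator with a validity mask.

    The mask only shrinks through the pipeline: downstream operations
    intersect masks, never extend them. Values outside the mask are NaN.
    """

    name: str
    values: np.ndarray
    mask: np.ndarray | None = None
    units: str = ""
    transform: tuple | None = None
    crs: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            _check_aligned(self.mask.shape, self.values.shape)
        self.values = np.where(self.mask, self.values, np.nan)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def valid_values(self) -> np.ndarray:
        """1-D array of the values on the valid mask."""
        return self.values[self.mask]

    def with_mask(self, mask: np.ndarray) -> "IndexRaster":
        """Return a copy whose mask is intersected with ``mask``."""
        _check_aligned(np.asarray(mask).shape, self.values.shape)
        return IndexRaster(
            name=self.name,
            values=self.values,
            mask=self.mask & np.asarray(mask, dtype=bool),
            units=self.units,
            transform=self.transform,
            crs=self.crs,
        )


def check_same_grid(*items) -> None:
    """Raise AlignmentError unless all items share one shape/geotransform."""
    shapes = [it.shape for it in items]
    transforms = [getattr(it, "transform", None) for it in items]
    for shp, tr in zip(shapes[1:], transforms[1:]):
        _check_aligned(shapes[0], shp, transforms[0], tr)
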