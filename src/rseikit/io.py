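"""Raster and table I/O.

Rasters travel as TIFF files (single- or multi-band) with a small JSON
sidecar (``<file>.aux.json``) carrying geotransform, CRS, nodata and any
extra metadata; the geo-metadata is opaque to the pipeline — inputs must be
pre-aligned, and nothing here reprojects. Tables are plain comma-separated
CSV (dot decimal, UTF-8, header required); reports are JSON.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import AlignmentError, ConfigurationError
from .types import (
    ALL_CLASSES,
    CLASS_NAMES,
    NODATA_CODE,
    AreaTable,
    IndexRaster,
    LandUseRaster,
    SpectralScene,
    TransferMatrix,
    REFLECTIVE_BANDS,
)

__all__ = [
    "read_raster",
    "write_raster",
    "read_landuse",
    "write_landuse",
    "read_index",
    "write_index",
    "read_scene",
    "write_scene",
    "read_area_tables",
    "write_area_table",
    "read_transfer_matrix",
    "write_transfer_matrix",
]

_SCENE_BANDS = REFLECTIVE_BANDS + ("thermal",)


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".aux.json")


def write_raster(
    path,
    array: np.ndarray,
    transform=None,
    crs: str | None = None,
    nodata=None,
    **extra_meta,
) -> None:
    """Write a (bands?, rows, cols) array as TIFF plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(array))
    meta = {
        "transform": list(transform) if transform is not None else None,
        "crs": crs,
        "nodata": nodata,
        **extra_meta,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_raster(path, expected_bands: int | None = None):
    """Read a TIFF raster and its sidecar metadata.

    Returns (array, meta dict). ``expected_bands`` checks the leading
    dimension of a multi-band stack (1 means a plain 2-D grid).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    array = tifffile.imread(path)
    meta: dict = {"transform": None, "crs": None, "nodata": None}
    if _sidecar(path).exists():
        meta.update(json.loads(_sidecar(path).read_text()))
    if meta.get("transform") is not None:
        meta["transform"] = tuple(meta["transform"])
    if expected_bands is not None:
        n = 1 if array.ndim == 2 else array.shape[0]
        if n != expected_bands:
            raise AlignmentError(
                f"{path.name}: expected {expected_bands} band(s), found {n}"
            )
    return array, meta


def write_landuse(path, lu: LandUseRaster) -> None:
    write_raster(
        path,
        lu.grid.astype(np.int16),
        transform=lu.transform,
        crs=lu.crs,
        nodata=NODATA_CODE,
        cell_area=lu.cell_area,
        epoch=lu.epoch,
    )


def read_landuse(path, cell_area: float | None = None, epoch=None) -> LandUseRaster:
    array, meta = read_raster(path, expected_bands=1)
    return LandUseRaster(
        grid=np.asarray(array, dtype=np.int16),
        cell_area=cell_area if cell_area is not None else meta.get("cell_area") or 0.0009,
        epoch=epoch if epoch is not None else meta.get("epoch"),
        transform=meta.get("transform"),
        crs=meta.get("crs"),
    )


def write_index(path, idx: IndexRaster) -> None:
    write_raster(
        path,
        np.asarray(idx.values, dtype=np.float32),
        transform=idx.transform,
        crs=idx.crs,
        nodata="nan",
        name=idx.name,
        units=idx.units,
    )


def read_index(path, name: str | None = None) -> IndexRaster:
    array, meta = read_raster(path, expected_bands=1)
    values = np.asarray(array, dtype=float)
    return IndexRaster(
        name=name or meta.get("name") or Path(path).stem,
        values=values,
        mask=np.isfinite(values),
        units=meta.get("units", ""),
        transform=meta.get("transform"),
        crs=meta.get("crs"),
    )


def write_scene(path, scene: SpectralScene) -> None:
    """Write a scene as a 7-band stack: blue, green, red, NIR, SWIR1, SWIR2, thermal."""
    if scene.thermal_dn is None:
        raise ConfigurationError("scene has no thermal band; cannot write 7-band stack")
    stack = np.stack(
        [scene.band(b) for b in REFLECTIVE_BANDS] + [scene.thermal_dn]
    ).astype(np.float32)
    write_raster(
        path,
        stack,
        transform=scene.transform,
        crs=scene.crs,
        sensor=scene.sensor,
        epoch=scene.epoch,
        band_order=list(_SCENE_BANDS),
    )


def read_scene(path, sensor: str | None = None, epoch=None) -> SpectralScene:
    array, meta = read_raster(path, expected_bands=len(_SCENE_BANDS))
    bands = {b: np.asarray(array[i], dtype=float) for i, b in enumerate(REFLECTIVE_BANDS)}
    return SpectralScene(
        bands=bands,
        thermal_dn=np.asarray(array[len(REFLECTIVE_BANDS)], dtype=float),
        sensor=sensor or meta.get("sensor") or "TM",
        epoch=epoch if epoch is not None else meta.get("epoch"),
        transform=meta.get("transform"),
        crs=meta.get("crs"),
    )


# ---------------------------------------------------------------------------
# tables


def read_area_tables(path) -> dict[str, AreaTable]:
    """Read a per-class area CSV with a ``class`` column and one column per epoch."""
    df = pd.read_csv(path)
    if "class" not in df.columns:
        raise ConfigurationError("area CSV needs a 'class' header column")
    df = df.set_index("class")
    return {
        str(epoch): AreaTable.from_mapping(epoch, df[epoch].to_dict())
        for epoch in df.columns
    }


def write_area_table(path, *tables: AreaTable) -> None:
    df = pd.DataFrame({str(t.epoch): t.named() for t in tables})
    df.index.name = "class"
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.round(3).to_csv(path)


def read_transfer_matrix(path, epoch_a="a", epoch_b="b") -> TransferMatrix:
    """Read a transfer-matrix CSV: ``from_class`` column, to-class columns."""
    df = pd.read_csv(path)
    if "from_class" not in df.columns:
        raise ConfigurationError("transfer CSV needs a 'from_class' header column")
    df = df.set_index("from_class")
    return TransferMatrix(epoch_a=epoch_a, epoch_b=epoch_b, cells=df)


def write_transfer_matrix(path, tm: TransferMatrix) -> None:
    df = tm.named().round(3)
    df.index.name = "from_class"
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path)
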