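"""Packaged reference tables for the Caohai lake-district worked example.

Small CSVs shipped with the package: per-class land-use areas (km²) for the
2000/2010/2020 epochs of the Caohai national nature reserve, and the three
inter-epoch land-use transfer matrices. They feed the worked example, the
test suite and the reproduction script; no imagery is shipped.
"""
from __future__ import annotations

from importlib.resources import files

from .io import read_area_tables, read_transfer_matrix
from .types import AreaTable, TransferMatrix

__all__ = ["caohai_area_tables", "caohai_transfer_matrix", "CAOHAI_EPOCH_PAIRS"]

CAOHAI_EPOCH_PAIRS = ((2000, 2010), (2010, 2020), (2000, 2020))

_DATA = files("rseikit.data")


def caohai_area_tables() -> dict[int, AreaTable]:
    """Per-class areas (km²) for 2000, 2010 and 2020, keyed by year."""
    tables = read_area_tables(str(_DATA / "caohai_class_areas.csv"))
    return {int(epoch): t for epoch, t in tables.items()}


def caohai_transfer_matrix(epoch_a: int, epoch_b: int) -> TransferMatrix:
    """Published transfer matrix (km²) for one of the three epoch pairs."""
    if (epoch_a, epoch_b) not in CAOHAI_EPOCH_PAIRS:
        raise KeyError(f"no packaged transfer matrix for {(epoch_a, epoch_b)}")
    return read_transfer_matrix(
        str(_DATA / f"caohai_transfer_{epoch_a}_{epoch_b}.csv"),
        epoch_a=epoch_a,
        epoch_b=epoch_b,
    )
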