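"""RSEI composition: normalization, PCA compositing, level and change maps.

The remote sensing ecological index (RSEI) is built from four indicator
rasters — greenness (NDVI), wetness (WET), dryness (NDBSI) and heat (LST) —
by min–max normalizing each to [0, 1], taking the first principal component
of the normalized 4-vector over valid cells, and rescaling PC1 back to
[0, 1]. Higher RSEI = better ecological condition.

PCA runs on the covariance matrix of the mean-centered normalized stack
(normalization already puts the indicators on a common scale). The sign of
an eigenvector is arbitrary, so PC1 is oriented to load nonnegatively on
NDVI, making "up" mean greener/wetter; the 1 − PC1 variant used by part of
the RSEI literature is available via ``pc1_transform="one_minus"``.

Water bodies dominate the wetness signal in lake districts, so a water mask
is usually applied to the whole stack before normalization and PCA.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ContractViolationError,
    DegenerateInputError,
    EmptyInputError,
)
from .types import IndexRaster, check_same_grid

__all__ = [
    "INDICATOR_ORDER",
    "LEVEL_NAMES",
    "normalize_01",
    "apply_water_mask",
    "pca_composite",
    "RSEIResult",
    "classify_levels",
    "change_classes",
    "ChangeMap",
    "level_area_stats",
]

#: Fixed stack order for the PCA.
INDICATOR_ORDER = ("NDVI", "WET", "NDBSI", "LST")

LEVEL_NAMES = {1: "very poor", 2: "poor", 3: "moderate", 4: "good", 5: "excellent"}
_LEVEL_EDGES = np.array([0.2, 0.4, 0.6, 0.8])


def normalize_01(idx: IndexRaster, clip_percentiles: tuple[float, float] | None = None) -> IndexRaster:
    """Min–max rescale an indicator to [0, 1] over its valid mask.

    ``clip_percentiles`` (e.g. ``(1, 99)``) optionally winsorizes before
    rescaling; off by default — plain min–max is the standard recipe.
    Raises DegenerateInputError for a constant raster.
    """
    vals = idx.valid_values()
    if vals.size == 0:
        raise EmptyInputError(f"{idx.name}: no valid cells to normalize")
    if clip_percentiles is not None:
        lo, hi = np.percentile(vals, clip_percentiles)
    else:
        lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        raise DegenerateInputError(f"{idx.name}: constant raster cannot be normalized")
    values = np.clip((idx.values - lo) / (hi - lo), 0.0, 1.0)
    return IndexRaster(
        name=f"n{idx.name}",
        values=values,
        mask=idx.mask,
        transform=idx.transform,
        crs=idx.crs,
    )


def apply_water_mask(
    stack: list[IndexRaster], water: np.ndarray
) -> list[IndexRaster]:
    """Remove water cells from every indicator's validity mask.

    ``water`` is a boolean grid, True on water cells. Raises EmptyInputError
    if nothing survives.
    """
    water = np.asarray(water, dtype=bool)
    out = [idx.with_mask(~water) for idx in stack]
    if not any(idx.mask.any() for idx in out):
        raise EmptyInputError("water mask removes every valid cell")
    return out


@dataclass
class RSEIResult:
    """PCA composite of the normalized indicator stack."""

    indicator_names: tuple[str, ...]
    loadings: pd.DataFrame          # indicators × PC1..PC4, unit columns
    eigenvalues: np.ndarray         # descending
    contributions: np.ndarray       # eigenvalue shares, sum to 1
    pc1_sign: int                   # orientation applied to the raw eigenvector
    rsei: IndexRaster               # in [0, 1] on the valid mask
    mean_rsei: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean_rsei = float(np.nanmean(self.rsei.values))

    def report(self) -> dict:
        """JSON-ready summary mirroring the usual loadings table layout."""
        return {
            "indicators": list(self.indicator_names),
            "loadings": {
                pc: {ind: round(float(v), 4) for ind, v in col.items()}
                for pc, col in self.loadings.items()
            },
            "eigenvalues": [round(float(v), 6) for v in self.eigenvalues],
            "contribution_pct": [round(float(100 * v), 2) for v in self.contributions],
            "pc1_sign": self.pc1_sign,
            "mean_rsei": round(self.mean_rsei, 4),
        }


def pca_composite(
    stack: list[IndexRaster],
    pc1_transform: str = "orient_ndvi",
) -> RSEIResult:
    """Composite four normalized indicators into the RSEI via PCA.

    The stack must follow ``INDICATOR_ORDER`` semantics (greenness first).
    Eigenpairs of the covariance matrix are sorted by descending eigenvalue
    (ties keep indicator order); PC1 is sign-oriented on the first
    indicator's loading unless ``pc1_transform="one_minus"``, which applies
    the 1 − PC1 convention instead. RSEI is PC1 min–max rescaled to [0, 1].
    """
    if len(stack) < 2:
        raise ValueError("need at least two indicators to composite")
    check_same_grid(*stack)
    mask = np.logical_and.reduce([idx.mask for idx in stack])
    n_valid = int(mask.sum())
    if n_valid < 2:
        raise EmptyInputError(f"only {n_valid} jointly valid cells; need >= 2")
    X = np.column_stack([idx.values[mask] for idx in stack])
    Xc = X - X.mean(axis=0)
    cov = (Xc.T @ Xc) / (n_valid - 1)
    if not np.any(cov.diagonal() > 0):
        raise DegenerateInputError("all indicators constant on the joint mask")
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]                      # descending
    evals = np.clip(evals[order], 0.0, None)             # kill tiny negatives
    evecs = evecs[:, order]

    pc1 = evecs[:, 0]
    sign = 1
    if pc1_transform == "orient_ndvi":
        if pc1[0] < 0:
            sign = -1
            evecs = evecs.copy()
            evecs[:, 0] = -pc1
    elif pc1_transform != "one_minus":
        raise ValueError(f"unknown pc1_transform {pc1_transform!r}")

    scores = Xc @ evecs[:, 0]
    if pc1_transform == "one_minus":
        scores = 1.0 - scores
    lo, hi = scores.min(), scores.max()
    if hi <= lo:
        raise DegenerateInputError("PC1 is constant; RSEI undefined")
    rsei_valid = (scores - lo) / (hi - lo)
    values = np.full(stack[0].shape, np.nan)
    values[mask] = rsei_valid

    names = tuple(idx.name.removeprefix("n") for idx in stack)
    loadings = pd.DataFrame(
        evecs,
        index=list(names),
        columns=[f"PC{i + 1}" for i in range(len(stack))],
    )
    total = evals.sum()
    return RSEIResult(
        indicator_names=names,
        loadings=loadings,
        eigenvalues=evals,
        contributions=evals / total,
        pc1_sign=sign,
        rsei=IndexRaster(
            "RSEI", values, mask, transform=stack[0].transform, crs=stack[0].crs
        ),
    )


def classify_levels(rsei: IndexRaster) -> np.ndarray:
    """Bin RSEI into five quality levels.

    Intervals are 0.2 wide, half-open with the top closed:
    [0, 0.2) very poor, [0.2, 0.4) poor, [0.4, 0.6) moderate,
    [0.6, 0.8) good, [0.8, 1.0] excellent. Returns an integer grid
    (1..5, 0 outside the mask); out-of-range values raise.
    """
    vals = rsei.valid_values()
    if vals.size and ((vals < 0).any() or (vals > 1).any()):
        raise ContractViolationError("RSEI values outside [0, 1]")
    levels = np.zeros(rsei.shape, dtype=np.int8)
    levels[rsei.mask] = np.digitize(vals, _LEVEL_EDGES) + 1
    return levels


@dataclass
class ChangeMap:
    """Interannual difference of one indicator, categorized.

    categories: +1 improvement, 0 no change, −1 degradation, on the joint
    valid mask (NaN-free ints; cells off the mask are coded −128).
    """

    name: str
    difference: IndexRaster
    categories: np.ndarray
    epsilon: float
    sign: str

    def summary(self) -> pd.DataFrame:
        """Per-category cell counts and percentage of the joint valid area."""
        mask = self.difference.mask
        total = int(mask.sum())
        rows = []
        for code, label in [(1, "improvement"), (0, "no change"), (-1, "degradation")]:
            n = int(((self.categories == code) & mask).sum())
            rows.append((label, n, round(100.0 * n / total, 2) if total else np.nan))
        return pd.DataFrame(rows, columns=["category", "cells", "percent"])


def change_classes(
    earlier: IndexRaster,
    later: IndexRaster,
    epsilon: float = 0.05,
    sign: str = "benefit",
) -> ChangeMap:
    """Categorize the change of an indicator between two epochs.

    D = later − earlier on the joint mask. For benefit indicators (NDVI,
    WET, RSEI) D > ε is improvement and D < −ε degradation; for cost
    indicators (NDBSI, LST — higher is worse) the labels are swapped.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    if sign not in ("benefit", "cost"):
        raise ValueError("sign must be 'benefit' or 'cost'")
    check_same_grid(earlier, later)
    mask = earlier.mask & later.mask
    diff = np.where(mask, later.values - earlier.values, np.nan)
    cats = np.full(earlier.shape, -128, dtype=np.int8)
    up = mask & (diff > epsilon)
    down = mask & (diff < -epsilon)
    cats[mask] = 0
    if sign == "benefit":
        cats[up], cats[down] = 1, -1
    else:
        cats[up], cats[down] = -1, 1
    return ChangeMap(
        name=earlier.name,
        difference=IndexRaster(
            f"d{earlier.name}", diff, mask,
            transform=earlier.transform, crs=earlier.crs,
        ),
        categories=cats,
        epsilon=epsilon,
        sign=sign,
    )


def level_area_stats(levels: np.ndarray, cell_area: float) -> pd.DataFrame:
    """Per-level area (km²) and percentage of the classified area.

    ``levels`` is the integer grid from :func:`classify_levels`; zeros
    (outside the mask) are excluded from the denominator.
    """
    levels = np.asarray(levels)
    valid = levels > 0
    total = int(valid.sum())
    if total == 0:
        raise EmptyInputError("level map has no classified cells")
    rows = []
    for code, label in LEVEL_NAMES.items():
        n = int((levels == code).sum())
        rows.append((label, n * cell_area, round(100.0 * n / total, 2)))
    return pd.DataFrame(rows, columns=["level", "area_km2", "percent"])
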