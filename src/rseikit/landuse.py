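"""Land-use change mathematics.

Implements the standard LUCC (land use / land cover change) toolbox for a
six-class categorical raster pair or per-class area tables:

* per-class structure change rate ``K`` (difference of class-area
  proportions between two epochs, in percentage points);
* single land-use dynamic degree ``K1`` (annualized relative area change of
  one class, %/yr) and the raw change value ``ΔU`` (km²);
* comprehensive land-use dynamics index ``K2`` (area-weighted mean of
  integer intensity grades × 100, bounded in [100, 400]) and its inter-epoch
  difference ``ΔI`` with a declining/developing phase label;
* land-use transfer matrices (area cross-tabulations) with reduce/add
  marginals and a conservation validator;
* Cohen's kappa from a confusion matrix, for interpretation-accuracy
  reporting.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigurationError, EmptyInputError
from .types import (
    ALL_CLASSES,
    CLASS_NAMES,
    DEFAULT_GRADING,
    NODATA_CODE,
    AreaTable,
    LandUseRaster,
    TransferMatrix,
    check_same_grid,
)

__all__ = [
    "class_areas",
    "structure_change_rate",
    "single_dynamics",
    "comprehensive_dynamics",
    "delta_i",
    "transfer_matrix",
    "validate_transfer_matrix",
    "cohen_kappa",
    "dynamics_report",
    "DynamicsReport",
    "ValidationReport",
]


def class_areas(lu: LandUseRaster) -> AreaTable:
    """Tabulate per-class areas (km²) of one land-use raster.

    Classes absent from the raster appear with area 0; nodata cells are
    excluded from the total.
    """
    valid = lu.valid_mask
    if not valid.any():
        raise EmptyInputError("raster contains no valid (non-nodata) cells")
    counts = np.bincount(lu.grid[valid].ravel(), minlength=max(ALL_CLASSES) + 1)
    areas = pd.Series(
        {c: counts[c] * lu.cell_area for c in ALL_CLASSES}, dtype=float
    )
    return AreaTable(epoch=lu.epoch if lu.epoch is not None else "", areas=areas)


def structure_change_rate(a: AreaTable, b: AreaTable) -> pd.Series:
    """Per-class change of land-use structure, K = Q_b − Q_a.

    Q is the class-area proportion of each epoch's own total; K is returned
    in percentage points (summaries round it to 2 decimals).
    """
    if a.total <= 0 or b.total <= 0:
        raise EmptyInputError("epoch total area is zero; proportions undefined")
    k = 100.0 * (b.proportions() - a.proportions())
    k.name = "K_pct_points"
    return k


def single_dynamics(a: AreaTable, b: AreaTable, years: float) -> pd.DataFrame:
    """Single land-use dynamic degree per class.

    Returns a frame with ``change_km2`` = U_b − U_a and ``annual_rate_pct``
    = 100 · (ΔU / U_a) / years. Classes with U_a = 0 get NaN for the rate
    (undefined); the change value is still reported.
    """
    if years <= 0:
        raise ValueError("period length in years must be positive")
    delta = b.areas - a.areas
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = 100.0 * (delta / a.areas) / years
    rate = rate.where(a.areas > 0, np.nan)
    return pd.DataFrame({"change_km2": delta, "annual_rate_pct": rate})


def comprehensive_dynamics(
    a: AreaTable, grading: dict[int, int] | None = None
) -> float:
    """Comprehensive land-use dynamics index K2 = 100 · Σ A_n C_n.

    A_n are integer intensity grades (1 = unused … 4 = construction by
    default) and C_n the class-area fractions of the epoch's own total.
    Bounded in [100, 400] whenever grades lie in {1..4}.
    """
    grading = dict(DEFAULT_GRADING if grading is None else grading)
    bad = [g for g in grading.values() if not 1 <= int(g) <= 4]
    if bad:
        raise ConfigurationError(f"grades must lie in 1..4, got {bad}")
    missing = [
        CLASS_NAMES[c]
        for c in ALL_CLASSES
        if c not in grading and a.areas[c] > 0
    ]
    if missing:
        raise ConfigurationError(f"no grade configured for classes with area: {missing}")
    props = a.proportions()
    return float(100.0 * sum(grading[c] * props[c] for c in ALL_CLASSES if c in grading))


def delta_i(k2_a: float, k2_b: float) -> tuple[float, str]:
    """Inter-epoch difference of K2 with its phase label.

    Negative ΔI marks a declining period of land-use intensity, positive a
    developing period.
    """
    if not (np.isfinite(k2_a) and np.isfinite(k2_b)):
        raise ValueError("K2 inputs must be finite")
    d = float(k2_b - k2_a)
    label = "declining" if d < 0 else "developing" if d > 0 else "stable"
    return d, label


def transfer_matrix(lu_a: LandUseRaster, lu_b: LandUseRaster) -> TransferMatrix:
    """Cross-tabulate areas by (class at epoch a, class at epoch b).

    Cells that are nodata in either raster are excluded from the matrix and
    both marginals, so area is conserved exactly between epochs.
    """
    check_same_grid(lu_a, lu_b)
    if lu_a.cell_area != lu_b.cell_area:
        raise AlignmentError("cell areas differ between epochs")
    joint_valid = lu_a.valid_mask & lu_b.valid_mask
    if not joint_valid.any():
        raise EmptyInputError("no cell is valid in both epochs")
    n = max(ALL_CLASSES) + 1
    pair_codes = lu_a.grid[joint_valid].astype(np.int64) * n + lu_b.grid[joint_valid]
    counts = np.bincount(pair_codes.ravel(), minlength=n * n).reshape(n, n)
    cells = pd.DataFrame(
        counts[1:, 1:] * lu_a.cell_area,
        index=list(ALL_CLASSES),
        columns=list(ALL_CLASSES),
        dtype=float,
    )
    return TransferMatrix(epoch_a=lu_a.epoch, epoch_b=lu_b.epoch, cells=cells)


@dataclass
class CheckResult:
    name: str
    passed: bool
    max_residual: float


@dataclass
class ValidationReport:
    """Outcome of the transfer-matrix conservation checks."""

    checks: list[CheckResult] = field(default_factory=list)
    tol: float = 1e-9

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.name, c.passed, c.max_residual) for c in self.checks],
            columns=["check", "passed", "max_residual"],
        )


def validate_transfer_matrix(
    tm: TransferMatrix, a: AreaTable, b: AreaTable, tol: float = 1e-9
) -> ValidationReport:
    """Check a transfer matrix against the two epoch area tables.

    Verifies: row sums reproduce epoch-a areas, column sums epoch-b areas,
    grand-total conservation, and reduce/add marginals equal off-diagonal
    sums. Failures are reported with residuals, never raised — printed
    tables carry rounding, so callers choose the tolerance.
    """
    report = ValidationReport(tol=tol)

    def check(name: str, residuals) -> None:
        worst = float(np.max(np.abs(np.asarray(residuals, dtype=float))))
        report.checks.append(CheckResult(name, worst <= tol, worst))

    check("row_sums_vs_epoch_a", tm.row_totals - a.areas)
    check("col_sums_vs_epoch_b", tm.col_totals - b.areas)
    check("grand_total_vs_epoch_a", [tm.grand_total - a.total])
    check("grand_total_vs_epoch_b", [tm.grand_total - b.total])
    diag = np.diag(tm.cells.values)
    check("reduce_is_offdiag_row_sum", tm.reduce_area - (tm.row_totals - diag))
    check("add_is_offdiag_col_sum", tm.add_area - (tm.col_totals - diag))
    check(
        "net_change_consistency",
        (tm.add_area - tm.reduce_area) - (b.areas - a.areas),
    )
    return report


def cohen_kappa(confusion: np.ndarray) -> float:
    """Cohen's kappa from a square confusion-count matrix.

    κ = (p_o − p_e)/(1 − p_e) with observed agreement p_o (diagonal share)
    and chance agreement p_e from the row/column marginals. Returns NaN when
    p_e = 1 (a single category on both axes — agreement is undefined).
    """
    m = np.asarray(confusion, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (m < 0).any():
        raise ValueError("confusion counts must be nonnegative")
    total = m.sum()
    if total <= 0:
        raise EmptyInputError("confusion matrix is empty")
    p_o = np.trace(m) / total
    p_e = float((m.sum(axis=1) / total) @ (m.sum(axis=0) / total))
    if np.isclose(p_e, 1.0):
        return float("nan")
    return float((p_o - p_e) / (1.0 - p_e))


@dataclass
class DynamicsReport:
    """Bundle of all change statistics for one epoch pair."""

    epoch_a: int | str
    epoch_b: int | str
    years: float
    structure_change: pd.Series        # K, percentage points
    single: pd.DataFrame               # change_km2 + annual_rate_pct
    k2_a: float
    k2_b: float
    delta_i: float
    phase: str
    grading: dict[int, int]

    def to_dict(self) -> dict:
        """JSON-ready summary, rounded to the reporting precision
        (3 decimals for km², 2 for percentages); raw values retained."""
        named = lambda s: {CLASS_NAMES[c]: v for c, v in s.items()}
        return {
            "epoch_a": self.epoch_a,
            "epoch_b": self.epoch_b,
            "years": self.years,
            "structure_change_pct_points": named(self.structure_change.round(2)),
            "change_km2": named(self.single["change_km2"].round(3)),
            "annual_rate_pct": {
                k: (None if not np.isfinite(v) else v)
                for k, v in named(self.single["annual_rate_pct"].round(2)).items()
            },
            "k2": {str(self.epoch_a): round(self.k2_a, 2), str(self.epoch_b): round(self.k2_b, 2)},
            "delta_i": round(self.delta_i, 2),
            "phase": self.phase,
            "grading": {CLASS_NAMES[c]: g for c, g in self.grading.items()},
            "raw": {
                "structure_change_pct_points": named(self.structure_change),
                "change_km2": named(self.single["change_km2"]),
                "annual_rate_pct": {
                    k: (None if not np.isfinite(v) else v)
                    for k, v in named(self.single["annual_rate_pct"]).items()
                },
                "k2_a": self.k2_a,
                "k2_b": self.k2_b,
                "delta_i": self.delta_i,
            },
        }


def dynamics_report(
    a: AreaTable,
    b: AreaTable,
    years: float,
    grading: dict[int, int] | None = None,
) -> DynamicsReport:
    """Compute every change statistic for one epoch pair in one call."""
    grading = dict(DEFAULT_GRADING if grading is None else grading)
    k2_a = comprehensive_dynamics(a, grading)
    k2_b = comprehensive_dynamics(b, grading)
    d, phase = delta_i(k2_a, k2_b)
    return DynamicsReport(
        epoch_a=a.epoch,
        epoch_b=b.epoch,
        years=years,
        structure_change=structure_change_rate(a, b),
        single=single_dynamics(a, b, years),
        k2_a=k2_a,
        k2_b=k2_b,
        delta_i=d,
        phase=phase,
        grading=grading,
    )
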