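"""Synthetic scenes with known ground truth.

Two generators drive validation of the whole pipeline:

* land-use raster pairs with *planted* inter-epoch transition counts —
  counts, not probabilities, so transfer-matrix recovery is an exact
  equality check;
* multispectral/thermal scenes in which a latent per-cell ecological
  gradient g ∈ [0, 1] pushes greenness and wetness up and dryness and
  temperature down, on top of class-dependent spectral signatures and
  additive Gaussian noise.

Everything is a pure function of (spec, seed): the same seed reproduces the
same arrays bit for bit.

The default spec mimics a Caohai-like mosaic — a lake district dominated by
water (~22%) and grassland (~46%) — at 200×200 cells of 30 m (cell area
0.0009 km²), small enough for sub-second tests.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import SpecificationError
from .types import (
    ALL_CLASSES,
    CONSTRUCTION,
    CULTIVATED,
    FOREST,
    GRASSLAND,
    UNUSED,
    WATER,
    IndexRaster,
    LandUseRaster,
    SpectralScene,
    REFLECTIVE_BANDS,
)

__all__ = [
    "SceneSpec",
    "default_scene_spec",
    "uniform_landuse",
    "generate_landuse_pair",
    "generate_scene",
    "generate_epoch_series",
    "two_factor_indicator_stack",
]

#: Per-class mean surface reflectance (blue, green, red, NIR, SWIR1, SWIR2)
#: and thermal digital-number level. Rough Landsat-like signatures.
DEFAULT_SIGNATURES: dict[int, tuple[float, ...]] = {
    WATER: (0.06, 0.05, 0.04, 0.02, 0.01, 0.01),
    CONSTRUCTION: (0.18, 0.20, 0.22, 0.24, 0.30, 0.28),
    GRASSLAND: (0.04, 0.07, 0.06, 0.35, 0.18, 0.10),
    CULTIVATED: (0.06, 0.09, 0.10, 0.28, 0.22, 0.14),
    FOREST: (0.03, 0.05, 0.04, 0.40, 0.15, 0.08),
    UNUSED: (0.12, 0.14, 0.16, 0.20, 0.26, 0.24),
}
DEFAULT_THERMAL_DN: dict[int, float] = {
    WATER: 110.0,
    CONSTRUCTION: 160.0,
    GRASSLAND: 130.0,
    CULTIVATED: 140.0,
    FOREST: 120.0,
    UNUSED: 150.0,
}
#: Reflectance slope per band on (g − 1/2): chosen so NDVI and tasseled-cap
#: wetness rise with g while the soil/built-up indices fall.
DEFAULT_COUPLINGS: tuple[float, ...] = (-0.01, 0.02, -0.06, 0.20, -0.12, -0.10)


@dataclass
class SceneSpec:
    """Everything the generators need, in one reproducible record."""

    shape: tuple[int, int] = (200, 200)
    cell_area: float = 0.0009
    #: epoch-a cell counts per class code; must sum to rows×cols.
    class_counts: dict[int, int] = field(default_factory=dict)
    #: planted (from, to) → cell counts; diagonal may be left implicit.
    transitions: dict[tuple[int, int], int] = field(default_factory=dict)
    signatures: dict[int, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_SIGNATURES)
    )
    thermal_levels: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_THERMAL_DN)
    )
    couplings: tuple[float, ...] = DEFAULT_COUPLINGS
    thermal_coupling: float = -60.0     # DN per unit gradient; negative = cooler
    gradient: str = "ramp"              # "ramp" | "smooth" | "constant"
    smooth_sigma: float = 8.0
    noise_sd: float = 0.01              # reflectance noise
    thermal_noise_sd: float = 1.0       # DN noise

    @property
    def n_cells(self) -> int:
        return int(self.shape[0] * self.shape[1])


def default_scene_spec(shape: tuple[int, int] = (200, 200)) -> SceneSpec:
    """Caohai-like class proportions with a plausible transition plan."""
    n = shape[0] * shape[1]
    fractions = {
        WATER: 0.22,
        CONSTRUCTION: 0.03,
        GRASSLAND: 0.46,
        CULTIVATED: 0.13,
        FOREST: 0.12,
        UNUSED: 0.04,
    }
    counts = {c: int(round(f * n)) for c, f in fractions.items()}
    counts[GRASSLAND] += n - sum(counts.values())  # absorb rounding
    per_mille = max(1, n // 1000)
    transitions = {
        (GRASSLAND, CULTIVATED): 8 * per_mille,
        (GRASSLAND, CONSTRUCTION): 3 * per_mille,
        (CULTIVATED, GRASSLAND): 6 * per_mille,
        (CULTIVATED, CONSTRUCTION): 2 * per_mille,
        (FOREST, GRASSLAND): 2 * per_mille,
        (UNUSED, GRASSLAND): 2 * per_mille,
        (WATER, GRASSLAND): 1 * per_mille,
    }
    return SceneSpec(shape=shape, class_counts=counts, transitions=transitions)


def uniform_landuse(
    code: int, shape: tuple[int, int] = (200, 200), cell_area: float = 0.0009,
    epoch=None,
) -> LandUseRaster:
    """Single-class raster, handy for gradient-only experiments."""
    return LandUseRaster(
        grid=np.full(shape, code, dtype=np.int16), cell_area=cell_area, epoch=epoch
    )


def _realize_grid(counts: dict[int, int], shape, rng: np.random.Generator) -> np.ndarray:
    n = shape[0] * shape[1]
    if sum(counts.values()) != n:
        raise SpecificationError(
            f"class counts sum to {sum(counts.values())}, grid has {n} cells"
        )
    flat = np.repeat(
        np.fromiter(counts.keys(), dtype=np.int16),
        np.fromiter(counts.values(), dtype=np.int64),
    )
    rng.shuffle(flat)
    return flat.reshape(shape)


def _full_transition_counts(
    counts_a: dict[int, int], transitions: dict[tuple[int, int], int]
) -> np.ndarray:
    """6×6 count matrix with the diagonal filled in from the residuals."""
    m = np.zeros((len(ALL_CLASSES) + 1, len(ALL_CLASSES) + 1), dtype=np.int64)
    for (i, j), cnt in transitions.items():
        if cnt < 0:
            raise SpecificationError("transition counts must be nonnegative")
        m[i, j] += cnt
    for c in ALL_CLASSES:
        have = counts_a.get(c, 0)
        off = m[c, :].sum() - m[c, c]
        if m[c, c] == 0:
            m[c, c] = have - off
        if m[c, :].sum() != have or m[c, c] < 0:
            raise SpecificationError(
                f"transitions out of class {c} need {m[c, :].sum() - m[c, c]} "
                f"cells but the class has {have}"
            )
    return m


def _apply_transitions(
    grid: np.ndarray, counts_matrix: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    out = grid.copy()
    for c in ALL_CLASSES:
        idx = np.flatnonzero(grid.ravel() == c)
        rng.shuffle(idx)
        pos = 0
        for to in ALL_CLASSES:
            cnt = int(counts_matrix[c, to])
            if cnt:
                out.ravel()[idx[pos:pos + cnt]] = to
                pos += cnt
    return out


def generate_landuse_pair(spec: SceneSpec, seed: int = 0):
    """Realize an epoch pair with cell-exact planted transitions.

    Returns (raster_a, raster_b, planted TransferMatrix). The analyzer's
    transfer matrix on the pair equals the planted counts × cell_area
    exactly.
    """
    from .types import TransferMatrix
    import pandas as pd

    rng = np.random.default_rng(seed)
    counts_m = _full_transition_counts(spec.class_counts, spec.transitions)
    grid_a = _realize_grid(spec.class_counts, spec.shape, rng)
    grid_b = _apply_transitions(grid_a, counts_m, rng)
    lu_a = LandUseRaster(grid_a, spec.cell_area, epoch="a")
    lu_b = LandUseRaster(grid_b, spec.cell_area, epoch="b")
    planted = TransferMatrix(
        epoch_a="a",
        epoch_b="b",
        cells=pd.DataFrame(
            counts_m[1:, 1:] * spec.cell_area,
            index=list(ALL_CLASSES),
            columns=list(ALL_CLASSES),
        ),
    )
    return lu_a, lu_b, planted


def _gradient(spec: SceneSpec, shape, rng: np.random.Generator) -> np.ndarray:
    rows, cols = shape
    if spec.gradient == "constant":
        return np.full(shape, 0.5)
    if spec.gradient == "ramp":
        return np.tile(np.linspace(0.0, 1.0, cols), (rows, 1))
    if spec.gradient == "smooth":
        g = ndimage.gaussian_filter(rng.standard_normal(shape), spec.smooth_sigma)
        lo, hi = g.min(), g.max()
        return (g - lo) / (hi - lo) if hi > lo else np.full(shape, 0.5)
    raise SpecificationError(f"unknown gradient model {spec.gradient!r}")


def generate_scene(
    lu: LandUseRaster, spec: SceneSpec, seed: int = 0, sensor: str = "TM"
):
    """Reflectance + thermal scene over a land-use mosaic.

    Each band is class signature + coupling·(g − 1/2) + N(0, noise_sd),
    clipped into (0, 1); the thermal DN decreases in g so the full LST chain
    under an identity atmosphere yields cooler temperatures where ecology is
    better. Returns (scene, gradient grid).
    """
    rng = np.random.default_rng(seed)
    g = _gradient(spec, lu.shape, rng)
    present = np.unique(lu.grid[lu.valid_mask])
    missing = [c for c in present if c not in spec.signatures]
    if missing:
        raise SpecificationError(f"no spectral signature for classes {missing}")

    bands: dict[str, np.ndarray] = {}
    for bi, band in enumerate(REFLECTIVE_BANDS):
        base = np.zeros(lu.shape, dtype=float)
        for c in present:
            base[lu.grid == c] = spec.signatures[c][bi]
        noise = rng.normal(0.0, spec.noise_sd, lu.shape) if spec.noise_sd > 0 else 0.0
        bands[band] = np.clip(
            base + spec.couplings[bi] * (g - 0.5) + noise, 1e-4, 1.0 - 1e-4
        )

    dn = np.zeros(lu.shape, dtype=float)
    for c in present:
        dn[lu.grid == c] = spec.thermal_levels[c]
    if spec.thermal_noise_sd > 0:
        dn = dn + rng.normal(0.0, spec.thermal_noise_sd, lu.shape)
    dn = np.clip(dn + spec.thermal_coupling * (g - 0.5), 1.0, None)

    scene = SpectralScene(
        bands=bands,
        thermal_dn=dn,
        sensor=sensor,
        mask=lu.valid_mask.copy(),
        epoch=lu.epoch,
        transform=lu.transform,
        crs=lu.crs,
    )
    return scene, g


def generate_epoch_series(
    spec: SceneSpec,
    transition_plans: list[dict[tuple[int, int], int]],
    seed: int = 0,
    epochs: list | None = None,
    sensor: str = "TM",
):
    """Chain of epochs with planted transitions between consecutive pairs.

    ``transition_plans[k]`` moves epoch k to epoch k+1. Returns a list of
    (LandUseRaster, SpectralScene, gradient) triples; the analyzer's
    transfer matrix of each consecutive pair equals its plan exactly.
    """
    rng = np.random.default_rng(seed)
    n_epochs = len(transition_plans) + 1
    epochs = epochs or list(range(n_epochs))
    grid = _realize_grid(spec.class_counts, spec.shape, rng)
    out = []
    for k in range(n_epochs):
        lu = LandUseRaster(grid, spec.cell_area, epoch=epochs[k])
        scene, g = generate_scene(
            lu, spec, seed=int(rng.integers(2**31)), sensor=sensor
        )
        out.append((lu, scene, g))
        if k < len(transition_plans):
            counts_now = {
                c: int((grid == c).sum()) for c in ALL_CLASSES
            }
            m = _full_transition_counts(counts_now, transition_plans[k])
            grid = _apply_transitions(grid, m, rng)
    return out


def two_factor_indicator_stack(
    shape: tuple[int, int] = (200, 200),
    variance_ratio: float = 10.0,
    noise_sd: float = 0.01,
    seed: int = 0,
):
    """Indicator stack driven by an ecology factor plus a nuisance factor.

    Four indicators share one latent ecology factor G (loadings +, +, −, −
    for NDVI, WET, NDBSI, LST) and an orthogonal nuisance factor H with
    ``variance_ratio`` times less variance, plus iid noise. All four have
    identical marginal variance, so min–max normalization rescales them
    uniformly and the PC1 variance share of the stack has the closed form
    planted_share = 1 / (1 + 1/ratio + (σ_ε/a)²), which is returned as the
    ground truth to recover.
    """
    rng = np.random.default_rng(seed)
    a = 0.12
    b = a / np.sqrt(variance_ratio)
    G = rng.standard_normal(shape)
    H = rng.standard_normal(shape)
    u = np.array([1.0, 1.0, -1.0, -1.0])
    v = np.array([1.0, -1.0, 1.0, -1.0])
    names = ("NDVI", "WET", "NDBSI", "LST")
    stack = []
    for i, name in enumerate(names):
        vals = 0.5 + a * u[i] * G + b * v[i] * H + rng.normal(0, noise_sd, shape)
        stack.append(IndexRaster(name, vals))
    planted_share = a**2 / (a**2 + b**2 + noise_sd**2)
    return stack, float(planted_share)
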