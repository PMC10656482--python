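"""Greenness, wetness and dryness indicator rasters.

NDVI = (NIR − R)/(NIR + R) is the greenness proxy. Wetness is the
tasseled-cap wetness component, a fixed linear combination of the six
reflective bands with sensor-specific coefficients. Dryness (NDBSI) is the
mean of a soil index SI and a built-up index IBI; both are normalized
ratios bounded in [−1, 1].

Cells whose denominators vanish are masked invalid rather than clamped, so
index ranges stay honest and a single validity concept propagates.
"""
from __future__ import annotations

import numpy as np

from .errors import AlignmentError, ConfigurationError
from .types import IndexRaster, SpectralScene, check_same_grid

__all__ = [
    "WETNESS_COEFFICIENTS",
    "compute_ndvi",
    "compute_wet",
    "compute_si",
    "compute_ibi",
    "compute_ndbsi",
]

#: Tasseled-cap wetness coefficients per sensor, in band order
#: blue, green, red, NIR, SWIR1, SWIR2. Additional variants can be
#: registered without touching the computation.
WETNESS_COEFFICIENTS: dict[str, dict[str, float]] = {
    "TM": {
        "blue": 0.0315,
        "green": 0.2021,
        "red": 0.3102,
        "nir": 0.1594,
        "swir1": -0.6806,
        "swir2": -0.6109,
    },
    "OLI_TIRS": {
        "blue": 0.1511,
        "green": 0.1973,
        "red": 0.3283,
        "nir": 0.3407,
        "swir1": -0.7171,
        "swir2": -0.4559,
    },
}

_SENSOR_ALIASES = {
    "TM": "TM",
    "LANDSAT5": "TM",
    "OLI": "OLI_TIRS",
    "OLI/TIRS": "OLI_TIRS",
    "OLI_TIRS": "OLI_TIRS",
    "LANDSAT8": "OLI_TIRS",
}


def resolve_sensor(tag: str) -> str:
    try:
        return _SENSOR_ALIASES[str(tag).upper().replace("-", "_")]
    except KeyError:
        raise ConfigurationError(
            f"unknown sensor tag {tag!r}; known: {sorted(set(_SENSOR_ALIASES))}"
        ) from None


def _ratio(num: np.ndarray, den: np.ndarray, base_mask: np.ndarray):
    """Elementwise num/den with zero denominators masked out."""
    ok = base_mask & (den != 0) & np.isfinite(num) & np.isfinite(den)
    out = np.full(num.shape, np.nan)
    np.divide(num, den, out=out, where=ok)
    return out, ok


def compute_ndvi(scene: SpectralScene) -> IndexRaster:
    """Normalized difference vegetation index, (NIR − R)/(NIR + R)."""
    nir, red = scene.band("nir"), scene.band("red")
    values, mask = _ratio(nir - red, nir + red, scene.mask)
    return IndexRaster("NDVI", values, mask, transform=scene.transform, crs=scene.crs)


def compute_wet(scene: SpectralScene) -> IndexRaster:
    """Tasseled-cap wetness from the six reflective bands.

    The coefficient set is selected by the scene's sensor tag; an unknown
    tag raises ConfigurationError.
    """
    coeffs = WETNESS_COEFFICIENTS[resolve_sensor(scene.sensor)]
    values = np.zeros(scene.shape, dtype=float)
    for band, c in coeffs.items():
        values = values + c * scene.band(band)
    mask = scene.mask & np.isfinite(values)
    return IndexRaster("WET", values, mask, transform=scene.transform, crs=scene.crs)


def compute_si(scene: SpectralScene) -> IndexRaster:
    """Soil index: [(SWIR1+R) − (NIR+B)] / [(SWIR1+R) + (NIR+B)]."""
    hi = scene.band("swir1") + scene.band("red")
    lo = scene.band("nir") + scene.band("blue")
    values, mask = _ratio(hi - lo, hi + lo, scene.mask)
    return IndexRaster("SI", values, mask, transform=scene.transform, crs=scene.crs)


def compute_ibi(scene: SpectralScene) -> IndexRaster:
    """Index-based built-up index.

    IBI = (u − v) / (u + v) with u = 2·SWIR1/(SWIR1+NIR) and
    v = NIR/(NIR+R) + G/(G+SWIR1). Cells where any component fraction has a
    zero denominator are masked.
    """
    swir1, nir = scene.band("swir1"), scene.band("nir")
    red, green = scene.band("red"), scene.band("green")
    d1, d2, d3 = swir1 + nir, nir + red, green + swir1
    comp_ok = scene.mask & (d1 != 0) & (d2 != 0) & (d3 != 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = 2.0 * swir1 / d1
        v = nir / d2 + green / d3
    values, mask = _ratio(u - v, u + v, comp_ok)
    return IndexRaster("IBI", values, mask, transform=scene.transform, crs=scene.crs)


def compute_ndbsi(si: IndexRaster, ibi: IndexRaster) -> IndexRaster:
    """Dryness indicator: cellwise mean of SI and IBI.

    The output mask is the intersection of the input masks; grids must be
    co-registered.
    """
    check_same_grid(si, ibi)
    mask = si.mask & ibi.mask
    values = np.where(mask, (si.values + ibi.values) / 2.0, np.nan)
    return IndexRaster("NDBSI", values, mask, transform=si.transform, crs=si.crs)
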