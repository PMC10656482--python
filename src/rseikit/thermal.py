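"""Single-channel land surface temperature (LST) inversion.

The thermal chain is: digital number → at-sensor radiance via the linear
calibration L = gain·DN + bias; atmospheric correction to surface-leaving
blackbody radiance B = [L − L_up − τ(1−ε)L_down]/(τ·ε); and Planck-type
inversion LST = K2/ln(K1/B + 1) − 273 (°C).

Calibration constants and atmospheric parameters are configuration inputs.
Defaults for Landsat 5 TM band 6 and Landsat 8 TIRS band 10 follow the
sensor handbooks; the upward/downward radiances and transmittance are
scene-specific and normally come from an atmospheric-correction query
service. Emissivity may be a scalar or a per-pixel grid; an NDVI-threshold
estimator is provided for when no emissivity map is available.

The −273 offset (rather than −273.15) matches the conventional printed form
of the inversion; pass ``kelvin_offset=273.15`` for the physical value.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .types import IndexRaster, SpectralScene

__all__ = [
    "ThermalCalibration",
    "AtmosphericParams",
    "TM_BAND6",
    "TIRS_BAND10",
    "IDENTITY_ATMOSPHERE",
    "dn_to_radiance",
    "blackbody_radiance",
    "radiance_to_lst",
    "lst_pipeline",
    "emissivity_from_ndvi",
]


@dataclass(frozen=True)
class ThermalCalibration:
    """Sensor calibration for one thermal band.

    gain/bias convert digital numbers to at-sensor spectral radiance
    (W·m⁻²·sr⁻¹·µm⁻¹); K1 (same units) and K2 (kelvin) are the Planck
    calibration constants.
    """

    gain: float
    bias: float
    k1: float
    k2: float

    def __post_init__(self) -> None:
        if self.gain <= 0 or self.k1 <= 0 or self.k2 <= 0:
            raise ConfigurationError("thermal calibration requires gain, K1, K2 > 0")


#: Landsat 5 TM band 6 defaults.
TM_BAND6 = ThermalCalibration(gain=0.055376, bias=1.18243, k1=607.76, k2=1260.56)
#: Landsat 8 TIRS band 10 defaults.
TIRS_BAND10 = ThermalCalibration(gain=3.342e-4, bias=0.1, k1=774.8853, k2=1321.0789)

CALIBRATION_PRESETS = {"TM": TM_BAND6, "OLI_TIRS": TIRS_BAND10}


@dataclass
class AtmosphericParams:
    """Atmospheric correction terms for the thermal band.

    l_up / l_down: upward and downward path radiance; tau: transmittance in
    (0, 1]; emissivity: surface emissivity in (0, 1], scalar or grid.
    """

    l_up: float = 0.0
    l_down: float = 0.0
    tau: float = 1.0
    emissivity: float | np.ndarray = 1.0

    def __post_init__(self) -> None:
        eps = np.asarray(self.emissivity, dtype=float)
        if self.tau <= 0 or self.tau > 1:
            raise ConfigurationError("transmittance tau must lie in (0, 1]")
        if (eps <= 0).any() or (eps > 1).any():
            raise ConfigurationError("emissivity must lie in (0, 1]")


IDENTITY_ATMOSPHERE = AtmosphericParams()


def dn_to_radiance(thermal_dn: np.ndarray, cal: ThermalCalibration) -> np.ndarray:
    """At-sensor radiance from raw digital numbers: L = gain·DN + bias."""
    return cal.gain * np.asarray(thermal_dn, dtype=float) + cal.bias


def blackbody_radiance(
    radiance: np.ndarray, atm: AtmosphericParams
) -> tuple[np.ndarray, np.ndarray]:
    """Atmospherically corrected surface blackbody radiance.

    B = [L − L_up − τ(1−ε)L_down] / (τ·ε). Returns (B, valid_mask); cells
    with nonpositive B cannot be inverted to a temperature and are flagged
    invalid.
    """
    L = np.asarray(radiance, dtype=float)
    eps = np.asarray(atm.emissivity, dtype=float)
    b = (L - atm.l_up - atm.tau * (1.0 - eps) * atm.l_down) / (atm.tau * eps)
    return b, np.isfinite(b) & (b > 0)


def radiance_to_lst(
    b_lst: np.ndarray,
    cal: ThermalCalibration,
    mask: np.ndarray | None = None,
    kelvin_offset: float = 273.0,
) -> IndexRaster:
    """Planck inversion of blackbody radiance: LST = K2/ln(K1/B + 1) − offset."""
    b = np.asarray(b_lst, dtype=float)
    ok = np.isfinite(b) & (b > 0)
    if mask is not None:
        ok &= np.asarray(mask, dtype=bool)
    values = np.full(b.shape, np.nan)
    np.divide(cal.k1, b, out=values, where=ok)
    values = np.where(ok, cal.k2 / np.log1p(values) - kelvin_offset, np.nan)
    return IndexRaster("LST", values, ok, units="degC")


def lst_pipeline(
    scene: SpectralScene,
    cal: ThermalCalibration,
    atm: AtmosphericParams = IDENTITY_ATMOSPHERE,
    kelvin_offset: float = 273.0,
) -> IndexRaster:
    """Full thermal chain on a scene's DN band; validity mask propagated."""
    if scene.thermal_dn is None:
        raise ConfigurationError("scene has no thermal band")
    radiance = dn_to_radiance(scene.thermal_dn, cal)
    b, ok = blackbody_radiance(radiance, atm)
    out = radiance_to_lst(b, cal, mask=ok & scene.mask, kelvin_offset=kelvin_offset)
    out.transform, out.crs = scene.transform, scene.crs
    return out


def emissivity_from_ndvi(
    ndvi: IndexRaster,
    ndvi_soil: float = 0.2,
    ndvi_veg: float = 0.5,
    eps_soil: float = 0.966,
    eps_veg: float = 0.986,
) -> np.ndarray:
    """NDVI-threshold emissivity: soil and vegetation endmember mixing.

    Cells below ``ndvi_soil`` take the bare-soil emissivity, above
    ``ndvi_veg`` the full-vegetation value; in between, the fractional
    vegetation cover Pv = [(NDVI − NDVI_s)/(NDVI_v − NDVI_s)]² interpolates
    linearly between the endmembers. Invalid NDVI cells fall back to the
    soil value.
    """
    v = np.asarray(ndvi.values, dtype=float)
    pv = np.clip((v - ndvi_soil) / (ndvi_veg - ndvi_soil), 0.0, 1.0) ** 2
    eps = eps_soil + (eps_veg - eps_soil) * pv
    return np.where(np.isfinite(v), eps, eps_soil)
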