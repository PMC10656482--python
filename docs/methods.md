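# Methods

## Scope and data model

The package analyzes two kinds of input. First, categorical land-use
rasters (or per-class area tables) for a small set of epochs, with six
fixed classes coded 1..6 — water, construction, grassland, cultivated,
forest, unused — and 0 for nodata. Second, co-registered surface
reflectance scenes (blue, green, red, NIR, SWIR1, SWIR2, nominally 0–1)
plus a raw thermal digital-number band. All grids are row-major,
top-left-origin, pixel-is-area; geotransform/CRS metadata is carried
opaquely and never reprojected — inputs must already be aligned, as
preprocessed Landsat stacks are. Reflectances are assumed to be
atmospherically corrected already; no TOA→surface step is implemented.

## Land-use change statistics

Let `U_{t,c}` be the area of class `c` at epoch `t` and `Q_{t,c}` its
share of that epoch's own total (each epoch uses its own total, not a
shared constant).

- Structure change rate: `K_c = 100·(Q_{b,c} − Q_{a,c})` percentage
  points; the column always sums to zero.
- Single dynamic degree: `ΔU_c = U_{b,c} − U_{a,c}` and
  `K₁ = 100·(ΔU_c/U_{a,c})/(b − a)` %/yr, implemented literally; a class
  with zero initial area reports ΔU but an undefined (NaN) rate.
- Comprehensive index: `K₂ = 100·Σₙ Aₙ·Cₙ` with integer grades `Aₙ` and
  area fractions `Cₙ`. Default grading: unused 1; water, forest,
  grassland 2; cultivated 3; construction 4. Grassland's grade follows the
  standard Chinese land-use intensity convention (natural vegetation = 2);
  the grading map is user-overridable. `K₂ ∈ [100, 400]` and strictly
  increases when area moves to a higher-graded class.
- `ΔI = K₂(b) − K₂(a)`, labeled declining/stable/developing by sign.

Transfer matrices cross-tabulate cell counts × cell area by (class at a,
class at b). Cells that are nodata in **either** epoch are excluded from
the matrix and both marginals, which keeps conservation exact: row sums
equal epoch-a class areas and column sums epoch-b class areas with no
tolerance. The validator reports residuals for row/column sums, grand
total, the reduce/add = off-diagonal-sum identities, and net-change
consistency; it never raises, because published tables printed at 3
decimals legitimately carry ~0.002 km² of rounding slack (use `tol=0.005`
for such tables, the default `1e-9` for computed ones).

Cohen's kappa is computed directly from a confusion-count matrix,
`κ = (p_o − p_e)/(1 − p_e)`; a degenerate single-category matrix returns
NaN rather than a value.

Reported tables round to 3 decimals for km² and 2 for percentages; all
internal arithmetic is full precision, and report JSON carries both.

## Indicator rasters

NDVI, SI and IBI are normalized ratios bounded in [−1, 1]; wetness is the
tasseled-cap wetness component with coefficient sets per sensor (TM:
0.0315, 0.2021, 0.3102, 0.1594, −0.6806, −0.6109; OLI/TIRS: 0.1511,
0.1973, 0.3283, 0.3407, −0.7171, −0.4559, band order blue→SWIR2), stored
in a registry so further variants can be added without code change.
NDBSI is the cellwise mean of SI and IBI. Cells whose denominators vanish
are **masked invalid, not clamped**: masks only shrink through the
pipeline (every downstream operation intersects masks), so a single
validity concept propagates and index ranges stay honest.

## Thermal chain

`L = gain·DN + bias` → `B = [L − L↑ − τ(1−ε)L↓]/(τ·ε)` →
`LST = K₂/ln(K₁/B + 1) − 273` in °C. Calibration defaults are the sensor
handbook values for Landsat 5 TM band 6 (gain 0.055376, bias 1.18243,
K₁ 607.76, K₂ 1260.56) and Landsat 8 TIRS band 10 (gain 3.342e-4,
bias 0.1, K₁ 774.8853, K₂ 1321.0789); upward/downward radiance and
transmittance are per-scene configuration (they come from an atmospheric
correction service in practice) and default to the identity atmosphere.
Emissivity is a scalar or per-pixel grid; an NDVI-threshold estimator
(soil/vegetation endmembers 0.966/0.986, fractional cover
`Pv = [(NDVI − 0.2)/0.3]²`) is available when no map exists. The −273
offset is the conventional printed form of the inversion;
`kelvin_offset=273.15` switches to the physical value. Nonpositive
corrected radiance cannot be inverted and is masked. LST is strictly
increasing in DN and decreasing in emissivity whenever the signal exceeds
the path radiance; both properties are pinned by tests, as is the exact
algebraic round trip of the forward radiative model.

## RSEI composition

Each indicator is min–max normalized to [0, 1] over its valid mask
(constant rasters are an error; optional percentile clipping exists but
is off by default — plain min–max is the standard recipe). PCA runs on
the **covariance** matrix of the mean-centered normalized stack in the
fixed order NDVI, WET, NDBSI, LST: normalization already equalizes scales,
and mean-centering is required by PCA itself. Eigenpairs are sorted by
descending eigenvalue with deterministic tie handling; loadings columns
are unit-norm and contributions are eigenvalue shares summing to one.

Eigenvector sign is arbitrary, so PC1 is oriented to load nonnegatively
on NDVI — higher RSEI then means greener/wetter, and dryness/heat load
negatively, matching the expected loadings structure. The `1 − PC1`
convention used by part of the RSEI literature is available via
`pc1_transform="one_minus"`. RSEI is PC1 rescaled to [0, 1], so its
minimum is exactly 0 and maximum exactly 1 on the valid mask by
construction, and it is invariant to any positive affine transform of a
single raw indicator (the normalization absorbs it).

In lake districts open water dominates the wetness signal, so
`apply_water_mask` removes water cells (e.g. the water class of the
land-use raster) from the whole stack before normalization and PCA; the
full pipeline does this by default when a land-use raster is supplied.

Quality levels are 0.2-wide bins — very poor, poor, moderate, good,
excellent — half-open with the top interval closed, resolving the tie at
each printed boundary deterministically. Change maps threshold the
difference of two epochs at ε (default 0.05, configurable; no published
convention exists): for benefit indicators (NDVI, WET, RSEI) a rise
beyond ε is improvement; for cost indicators (NDBSI, LST) the labels are
swapped.

## Synthetic scenes

The generator is the ground-truth source for validation. Land-use pairs
are realized from **exact planted cell counts**: epoch-a class counts and
(from, to) transition counts are laid out by a seeded shuffle, so the
analyzer's transfer matrix equals the planted matrix with no tolerance.
(Probabilistic stress-testing can be had by drawing the counts upstream.)
Spectral scenes add, per band, a class signature + coupling·(g − ½) +
clipped Gaussian noise, where g ∈ [0, 1] is a latent per-cell ecological
gradient (column ramp, smoothed noise, or constant). Couplings are signed
so greenness and wetness rise with g while dryness and temperature fall;
the thermal DN slope is −60 DN per unit g. Defaults: 200×200 cells at
30 m (0.0009 km²/cell), class shares ≈ 22% water / 46% grassland / 13%
cultivated / 12% forest / 3% construction / 4% unused — a lake-wetland
mosaic — and reflectance noise σ = 0.01. All outputs are pure functions
of (spec, seed).

A separate two-factor generator emits indicator stacks directly:
indicator_i = ½ + a·u_i·G + b·v_i·H + ε with orthogonal sign patterns
u = (+,+,−,−), v = (+,−,+,−), a = 0.12, b = a/√ratio (ratio 10 by
default), ε ~ N(0, 0.01). All four indicators share one marginal
distribution, so min–max normalization rescales them uniformly and the
planted PC1 variance share has the closed form 1/(1 + 1/ratio + (σ/a)²),
which the pipeline recovers within a fraction of a percentage point.

What the synthetic scenes do **not** emulate: sensor PSF and registration
artifacts, physically based radiative transfer, spatial autocorrelation
of noise, mixed pixels, seasonality. Passing the synthetic suite
demonstrates the correctness of the arithmetic, masking, conservation and
eigen-structure recovery — not that any particular real landscape will
show a 97% PC1 share.

## Problem sizes and numerical choices

Tests run on grids from 2×2 to 200×200 (sub-second each; the whole suite
is a few seconds). PCA uses a symmetric eigen-solver on the 4×4
covariance; eigenvalues are clipped at zero to absorb −1e−17-style noise,
and rank-deficient stacks are legal (null components contribute 0).
Degenerate inputs (all-nodata rasters, constant indicators, empty joint
masks, zero-area epochs) raise typed errors early rather than producing
NaN results. Transfer-matrix tallies use a single bincount over joint
codes and are compared against an exhaustive per-cell tally in tests.

## Known limitations

- Published annualized single-dynamic rates in the motivating tables do
  not follow the printed formula for all classes; the package implements
  the formula literally and asserts only the area-difference change
  values. Similarly, two cells of the printed 2000–2020 structure-change
  column are internally inconsistent at the second decimal; the computed
  values are the self-consistent ones.
- No reprojection, resampling, or vector zoning; inputs must share a grid.
- The RSEI level-percentage denominators of any particular published
  study (full area vs water-masked area) may differ from this package's
  convention (the classified mask).
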