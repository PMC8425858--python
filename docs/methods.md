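# Methods

This note records the models, numerical choices and limitations behind
`ybrachy`, in the order the pipeline runs them.

## Source model

The source is modeled as nested cylinders on a common axis, all dimensions
configurable with defaults taken from the published description of the
prototype: a Yb₂O₃ ceramic core (density 6.2 g/cm³, length 2.6 mm) inside a
0.06 mm titanium tube inside a 0.15 mm SS 316L tube, external diameter
0.90 mm, total length 4.73 mm, with a hemispherical distal tip and a 0.9 mm
SS 304L drive cable (default length 2 cm). θ = 0° points through the tip,
180° toward the cable; the origin is the center of the active core.

Two published dimensions cannot all hold at once: a 0.60 mm core plus
2×(0.06 + 0.15) mm of walls exceeds the 0.90 mm external diameter. The
default resolves this outside-in — the external diameter and wall
thicknesses are honored and the core fills the remaining interior
(0.48 mm diameter). The axial layout is not fully specified either; the
core is centered in the capsule, which leaves ≈1 mm of solid steel at the
tip and ≈0.9 mm at the weld. This choice reproduces the fore–aft symmetry
of the published anisotropy table; anchoring the tip minimally instead
overshoots F near θ = 0 by up to 20%. Inner-capsule end caps default to
their layer's radial wall thickness (not stated in the source description).

Emission is isotropic from points uniform in the core volume; decay photons
are sampled independently from the 13-line spectrum (49.77–307.74 keV,
total intensity 332.2%, I_γ = 3.322 photons/decay). No decay-scheme
correlations, internal conversion or fluorescence regeneration are modeled.

## Interaction coefficients

No tabulated cross-section library is bundled as a dependency; instead
`scripts/generate_xs_tables.py` builds per-material CSV tables (10–350 keV,
log-log interpolated at run time, exact at grid nodes) from an analytic
model: exact Klein–Nishina incoherent scattering with a small empirical
binding damping, an empirical Z^2.5/E^1.9 coherent fit, and photoelectric
terms anchored to widely published elemental attenuation coefficients
(with explicit K-edge breaks for Mo and Yb; the Yb anchors above its
61.3 keV edge are scaled from tungsten, the closest well-known element).
For the two kerma-scoring media — water and air at 40% humidity — the
published compound (μ/ρ, μ_en/ρ) pairs are used directly and the
photoelectric/incoherent split is derived from them via the Klein–Nishina
energy-transfer fraction, which makes absorption sampling and
energy-absorption scoring mutually consistent. Composition data follow the
published materials table (mass fractions normalized on load; the SS 316L
row sums to 100.05%). The resulting water and air totals match standard
compilations at the anchor energies by construction; the metal tables are
estimated to a few percent, which matters mainly for capsule
self-absorption (see Limitations).

## Transport engine

Photon-only Monte Carlo under the kerma approximation: at ≤308 keV the
secondary-electron ranges in water (≲0.1 mm) are far below the voxel size,
so collision kerma stands in for absorbed dose and photoelectric absorption
ends a history on the spot. Photons below δ = 10 keV are terminated — the
same cutoff that defines the air-kerma strength tallies.

* Capsule/cable transport uses Woodcock (delta) tracking under a majorant
  cross section, confined to the convex bounding cylinder of the source;
  the homogeneous phantom outside uses direct exponential flight sampling.
  Flights that would cross back into the envelope are handed to the
  Woodcock tracker, so the cable shadow is exact for scattered photons too.
* Incoherent scattering samples the Klein–Nishina distribution
  (free-electron) by composite rejection.
* Coherent scattering deflects via a screened form-factor model (momentum
  transfer drawn from a (1+(x/x_c)²)⁻³ density with x_c = 0.17·Z^⅓ Å⁻¹,
  accepted against the Thomson factor). A form-factor-free Thomson option
  and an off switch are toggles: at these energies true Rayleigh scattering
  is strongly forward-peaked, and the Thomson model measurably inflates
  water build-up (it pushes the g_L maximum up by ≈0.02).
* Scoring is a track-length estimator on the spherical (r, θ) mesh
  (analytic segment/shell/cone intersections, fully vectorized); a history
  is carried with implicit capture and Russian roulette below weight 0.1.
  Relative statistical errors come from the spread of 20 independent
  batches; identical seed and configuration reproduce tables bit-exactly.
* Air-kerma strength tallies follow the vacuum design: air-filled shells
  [d−2.5, d+2.5] cm at d = 50…150 cm cut by the 88–92° cone band, vacuum
  elsewhere, so no air attenuation or build-up correction is needed. The
  shell average of 1/r² is removed with the radial line average 1/(ab)
  (0.25% at 50 cm, 0.026% at 150 cm); a volume-average option
  3/(a²+ab+b²) exists and differs by 0.33% at 50 cm.

Default mesh: radial bins of ±1 mm centered on 0.5, 1.0, …, 10.0 cm
(contiguous edge list, byproduct gap bins kept), angular bins of 10°
centered on 10°…170° plus narrow polar bins, the voxel position being the
bin center. Voxels whose centers fall inside the source or cable are
flagged invalid and surface as missing anisotropy entries.

## TG-43 extraction and uncertainties

G_L uses β computed as a sum of two arctangents (stable at all angles) and
the closed form 1/(r²−L²/4) on the axis; the two branches agree to 10⁻⁶
at θ = 0.01°. The raw tally (MeV g⁻¹ photon⁻¹) converts to cGy·mCi⁻¹·h⁻¹
through the constant 2.134×10³, computed from 3.7×10⁷ Bq/mCi, 3600 s/h and
the CODATA MeV→J factor and asserted against its rounded value at import.
g_L and F are ratio extractions against the (1 cm, 90°) voxel and are
exactly 1 at their references; g_L(r) is fitted with an unweighted
fifth-order polynomial whose maximum relative residual must stay within 2%
(the treatment-planning criterion; the published fit statement is ambiguous
between residual and coefficient uncertainty, and residual is implemented).
S_k averages the per-distance estimates without weighting.

All uncertainties are relative standard uncertainties combined in
quadrature from independent components: per-voxel Monte Carlo statistics
(type A), a fixed 2% interaction-database term (type B, configurable), and
the 1.5% photon-yield term where absolute dose rates are involved. Ratio
quantities (g, F, Λ) carry the database term twice and are exactly zero at
their reference points. Display rounding follows the one-significant-figure
convention (1.2136 ± 0.0292 → 1.21 ± 0.03).

## Film chain

netOD = log₁₀[(PV_before−PV_bckg)/(PV_after−PV_bckg)] from mean ROI pixel
values with 3-MAD outlier rejection (dust/scratches); the red channel is
the default for the 0.25–6 Gy range. The dose response D = a·netOD +
b·netODⁿ is fitted by nonlinear least squares with a, b ≥ 0 and n > 1
(monotone by construction); parameter errors and the full covariance come
from the fit. Dose uncertainty propagates the covariance plus an
independent netOD variance to first order — the published uncertainty
formula for this conversion is typographically corrupted (it mixes symbols
absent from the response model), so standard first-order propagation is
implemented and labeled as such. At film-like noise levels the (a, b, n)
triple is strongly correlated and individually unidentifiable; the fitted
response curve is the meaningful recovered object and is what the tests
check. Dose maps optionally smooth the netOD image with a small box filter
(≈0.5 mm) before conversion — the usual scanner-noise suppression, without
which per-pixel dose noise at low doses is several percent. PDD profiles
normalize to their maximum sample; isodose contours use bilinear marching
squares; the film anisotropy removes G_L and renormalizes at 90°.
Acquisition protocol (2-day post-exposure stabilization, scanner warm-up,
lateral response) is out of computational scope.

## Synthetic generators

Every generator inverts its analysis exactly: dose tables from
(S_k*, Λ*, g*, F*) through the TG-43 equation with per-voxel Gaussian
relative noise (default σ(r) = 0.002·√r, mimicking tally statistics; the
cable shadow marks θ > 174/176/178° at r ≤ 0.5/1/2 cm invalid); air-kerma
tallies from S_k* through the shell-average factor; film scans through the
numerical inverse of the calibration curve with relative pixel noise.
Defaults reproduce the published parameter values of this source, so
synthetic data resemble the real characterization. Noise is independent
per voxel/pixel — no attempt is made to emulate the correlation structure
of a real transport code's tallies, and film synthesis has uniform response
(no lateral scanner effects). Passing round-trip tests therefore
demonstrates correctness of the inversion chain, not robustness to
correlated artifacts of real data.

## Problem sizes

The test suite simulates 2×10⁶ water histories (per-voxel statistics
≈0.3–0.5%) and the acceptance script 5×10⁶ (+10⁶ for air kerma), sizes
chosen so statistical error is well below the published uncertainties while
a run stays in the minutes range on one core. Published reference
characterizations of such sources use ~9×10⁷ histories with coupled
electron transport; estimator efficiency differs, so statistical targets
are treated as properties rather than matched values.

## Known limitations

* Kerma approximation: exact charged-particle equilibrium is assumed
  everywhere, including millimeters from the capsule.
* Analytic interaction tables: metal coefficients are anchored estimates
  (few-percent level). S_k absorbs capsule/core self-absorption directly
  and comes out ≈1.13 U/mCi against the published 1.03 ± 0.03 U; Λ, being
  a water/air ratio with common capsule filtering, lands within ≈0.03 of
  the published 1.21.
* The capsule interior layout (core diameter vs. wall overlap, axial
  placement, end-cap thicknesses) is partly inferred; all of it is
  configurable, and the anisotropy function near the poles is the quantity
  most sensitive to it (residual differences of up to ≈+5% against the
  published table at θ ≤ 30°, which itself carries ±0.03 per cell and is
  non-monotonic in r at two columns).
* No electron transport, bremsstrahlung, fluorescence regeneration, or
  variance reduction beyond track-length estimation and implicit capture.
* Activity normalization is per mCi of apparent activity; contained-activity
  calibration is out of scope.
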