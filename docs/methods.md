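# Methods

This note documents the models, parameter choices and numerical
conventions behind `meromix`, and what the synthetic-data tests do and
do not establish about field data.

## Density equation of state

Density is the sum of a freshwater cubic in temperature and a linear
haline term driven by κ20, conductivity normalized to 20 °C:

    ρ_w(T, S) = ρ'_w(T) + β S,     S = α κ20
    ρ'_w(T) = 999.84 + 6.55e-2 T − 8.56e-3 T² + 5.94e-5 T³   [kg m⁻³]

The cubic peaks at 3.99 °C, the familiar freshwater density maximum.
α = 0.72e-3 kg m⁻³ (µS cm⁻¹)⁻¹ converts ion content to salinity for
this lake's ionic composition (calcium-sulfate dominated groundwater
inflows).

**Unit resolution of β.** The haline contraction coefficient is
published as β = 0.96e-3 kg g⁻¹, i.e. per gram of dissolved salt.
With salinity expressed in kg m⁻³ (as α κ20 yields), the consistent
dimensionless multiplier is 0.96 = 0.96e-3 kg g⁻¹ × 10³ g kg⁻¹. The
default `DensityParams.beta = 0.96` adopts this reading: it gives a
chemocline density step of ~0.17 kg m⁻³ for a 250 µS cm⁻¹ κ20
contrast, which is what sustains meromixis once the thermal gradient
vanishes in winter. Taking the printed 0.96e-3 literally would make
the haline term ~10⁻⁴ kg m⁻³ — physically negligible and inconsistent
with a permanently stratified lake. Both readings are available via
`DensityParams(beta=...)`.

## κ20 normalization

The probe firmware's normalization formula is not public, so the
package uses the linear temperature-compensation model standard in
freshwater work, κ20 = κ_T / (1 + a_t (T − 20)) with a_t = 0.020 °C⁻¹
(2 %/°C), configurable. The synthetic generator embeds the same model,
so round-trip tests are exact; against real probe output a different
firmware coefficient would bias κ20 by a few percent at cold
temperatures — recalibrate `alpha_t` against a known-κ20 standard if
that matters.

## Schmidt stability

    Sc = (1/A_o) ∫₀^z_bot g ρ_w(z) (z − z_v) A(z) dz

- **Quadrature**: composite trapezoid on a uniform 0.1 m grid
  (configurable). Transparent against closed forms and O(h²):
  grid-halving tests verify the error drops ≥ 3×. No higher-order
  scheme — the 0.1 m default already puts quadrature error orders of
  magnitude below sensor noise.
- **Modes**: `as_printed` uses a fixed z_v (default 5.3 m, the
  published center-of-volume depth for this basin). When the fixed z_v
  is not the exact discrete center of volume of A(z), the integral
  retains a contribution from the absolute density level; this is the
  published convention and is reproduced faithfully. `anomaly` mode
  recomputes z_v from A(z) on the same integration grid, making Sc
  exactly invariant to ρ → ρ + c and zero for uniform density; use it
  for physically interpretable comparisons across lakes.
- **Boundary handling**: casts rarely reach exactly 0 or z_bot m; end
  values are extended as constants to the integration limits and the
  result carries an `extrapolated` flag.
- **Hypsometry**: tabulated A(z) can be supplied as CSV; the built-in
  power-law family A(z) = A_o (1 − z/z_bot)^q has center of volume
  z_bot/(q+2), so q = 1.96 with z_bot = 21 m reproduces the published
  z_v = 5.3 m. A_o defaults to 0.23 km²; the alternative surface
  area of 0.261 km² sometimes quoted for this basin is available
  through configuration. z_bot defaults to 21 m (a 21.5 m figure also
  circulates; the difference only moves the deepest grid cells).
- The published headline Sc of ~175 kJ m⁻² for the real lake is tied
  to the deposited field casts and the reference hypsometric curve and
  its z_v convention; it is roughly 100× the two-layer closed-form
  scale, which is what the `as_printed` convention's full-density term
  produces when z_v differs from the discrete center of volume.
  Nothing in this package is tuned to that number: the desk-scale
  checks here validate the integral against closed forms instead.

## Bacterial-layer detection

Turbidity > 10 FTU (strict) marks the layer. The detector finds
maximal contiguous super-threshold runs, screens them against a
minimum raw-sample span of 0.1 m (so a single-sample spike that
survived despiking cannot register as a layer), refines the surviving
boundaries by linear interpolation of the threshold crossing between
the neighbouring samples, and returns the interval containing the
global turbidity maximum ("the" consistent peak; `select="deepest"`
is available for casts with a secondary shallow peak). Interpolated
crossings make thickness grid-step-insensitive: on a Gaussian peak of
amplitude 24 FTU over a 1 FTU baseline (σ = 0.5 m) the analytic
crossings at ±0.700 m are recovered within one 0.1 m grid step.

The five-depth sampling plan (top − 1 m, top, top + 0.5 m, bottom,
bottom + 1 m) is clipped to [0, z_bot] with clipped names flagged.
Isotherm and oxycline depths use the same first-crossing linear
interpolation; the oxycline threshold of 0.5 mg l⁻¹ is a package
choice (no standard value exists) and is configurable.

## Flow cytometry

Acquisition thresholds FSC-H > 2000 and FL3-A > 1100 (strict, matching
the instrument configuration's phrasing) remove abiotic particles and
non-autofluorescent cells. Phenotype gating is one-dimensional on
log10(FSC-A) with cuts at 4.5 and 5.5 by default, separating the three
size classes (GSB < small PSB < large PSB); the exact gate geometry
used on the real instrument is not published, so the cuts are
config-exposed and the synthetic clusters (log10 means 4.0 / 5.0 / 6.0,
sd 0.1) are calibrated to sit 5σ from them — classification error on
synthetic mixtures is therefore ≤ 1 event in 3,000, and the 2 %
fraction-recovery bound in the tests is dominated by multinomial
sampling, not gating. Events with FSC-A = 0 cannot be placed on the
log scale and are tallied as unclassifiable rather than silently
dropped. Sample standard deviations use the n − 1 denominator.
Acquired volume is a required input — event counts alone cannot give
concentrations.

Input is delimited text with named channel columns (aliases
configurable). Binary FCS containers are not parsed; export the event
table as CSV from the acquisition software.

## Seasonal aggregation

Monthly summaries operate on native-cadence records: radiation is
integrated as Σ(W m⁻² × interval seconds); months with < 50 % of their
expected records are flagged (`low_coverage`) but kept, mirroring how
a broken pyranometer year should appear as present-but-flagged rather
than vanish. The interannual trend is plain OLS on annual means — a
descriptive rate, not a climate attribution. Surface/bottom extraction
windows for the historical table (0.5 m / 1 m) are robustness choices
against variable sensor start depths, configurable. Bottom sulfide is
averaged over observations between 18 and 20 m, the convention for
"lake bottom" in the historical series.

## Synthetic generators

The generators emulate structure, not the lake: logistic transitions
for T, κ20 and dissolved oxygen across the chemocline (smooth
transition, no functional form is claimed by the field data), a
Gaussian turbidity peak for the bacterial layer, log-normal cytometer
clusters with debris drawn strictly below both acquisition thresholds
(so retention has the analytic expectation 1 − debris fraction), and
weather as seasonal sinusoid + linear trend + AR(1) noise with Poisson
storm arrivals carrying gamma-distributed rainfall. Scenario defaults
(15 °C surface, 4 °C bottom, κ20 150 → 400 µS cm⁻¹, chemocline at
11 m, layer at 13 m with 24 FTU, trend 0.0325 °C yr⁻¹) describe a
typical mid-July situation for this kind of basin and are scenario
conventions, not lake facts. All generators are bit-reproducible per
seed and return their ground truth.

What passing tests show: the pipeline recovers known structure through
its own QC chain at realistic noise levels. What they do not show:
robustness to sensor drift, thermal-lag artifacts, up/downcast
hysteresis beyond simple leading-segment selection, cytometer spectral
spillover, or weather regimes outside the generator family.

## Problem sizes

The default test and acceptance runs use 0.1 m profile grids
(211 samples per cast), 10-cast noisy ensembles, 10,000-event
cytometry tables, and a 200-seed × 35-year trend Monte Carlo at annual
resolution (daily cadence for the single full weather-generator pass,
with partial first/last calendar years dropped before the trend fit —
their incomplete seasonal coverage would bias the annual means). These
sizes put Monte-Carlo standard errors well inside the asserted
tolerances.

## Known limitations

- No TEOS-10 / seawater physics; the cubic + linear EOS is only valid
  for dilute lake water.
- No sensor drift, lag or thermal-mass corrections.
- The κ20 model and β unit resolution are documented conventions, not
  instrument ground truth.
- `as_printed` Schmidt values depend on the supplied A(z) and z_v;
  comparisons across hypsometry sources must use `anomaly` mode.
- FCS binary ingestion is out of scope; delimited exports only.
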