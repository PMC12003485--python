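# meromix

Analysis pipeline for monitoring a small, permanently stratified
(meromictic) alpine lake: the kind of system where a warm, oxygenated
mixolimnion floats year-round on a cold, ion-rich, anoxic
monimolimnion, and a dense layer of anoxygenic phototrophic sulfur
bacteria (the "bacterial layer", BL) sits in the lower chemocline at
roughly 10–14 m. The package is written for limnologists and microbial
ecologists who run seasonal CTD + flow-cytometry + weather-station
campaigns on such lakes and want the whole chain — raw casts to
seasonal tables — scripted and tested.

## What it computes

**Density.** A lake-specific equation of state

```
ρ_w(T, S) = ρ'_w(T) + β S,        S = α κ20
ρ'_w(T)  = 999.84 + 6.55·10⁻² T − 8.56·10⁻³ T² + 5.94·10⁻⁵ T³   [kg m⁻³]
```

with κ20 the conductivity normalized to 20 °C (µS cm⁻¹),
α = 0.72·10⁻³ kg m⁻³ (µS cm⁻¹)⁻¹ the ion-specific
conductivity-to-salinity factor, and β the haline contraction
coefficient (see `docs/methods.md` for the unit resolution of β).

**Schmidt stability.** The mechanical work per unit surface area needed
to fully mix the water column,

```
Sc = (1/A_o) ∫₀^z_bot  g ρ_w(z) (z − z_v) A(z) dz      [J m⁻²]
```

over the hypsometric curve A(z), with either a fixed published
center-of-volume depth z_v (`as_printed` mode, default z_v = 5.3 m) or
z_v recomputed from A(z) (`anomaly` mode, offset-invariant).

**Bacterial layer.** Detection of the BL as the contiguous turbidity
interval above 10 FTU containing the global turbidity maximum, with
boundary depths refined by linear interpolation of the threshold
crossing, plus the five-depth field sampling plan (1 m above the top,
at the top, 50 cm within, at the bottom, 1 m below the bottom),
isotherm depths and the oxycline.

**Flow cytometry.** The fixed gating chain used for phototroph
enumeration — acquisition thresholds FSC-H > 2000 and FL3-A > 1100,
then size classes on log10(FSC-A) separating green sulfur bacteria,
small-celled and large-celled purple sulfur bacteria — with
concentrations (cells ml⁻¹) and the in-layer mean ± sd summary.

**Seasons.** Monthly weather summaries (mean ± sd temperature,
time-integrated net radiation in J m⁻², rainfall totals), OLS
interannual temperature trends, and historical surface/bottom tables
from profile stacks.

**Synthetic data.** Seeded generators (`meromix.synthgen`) produce CTD
casts, BL seasons, cytometer event clouds and mountain weather with
known ground truth, so the entire pipeline is testable offline.

## Worked example

```python
import meromix as mx

# a noise-free synthetic cast: 15 °C over 4 °C, chemocline at 11 m,
# 24-FTU turbidity peak at 13 m (sigma 0.5 m)
cast = mx.gen_ctd_profile(mx.LakeScenario(noise_sd={}))
cast = mx.with_k20(cast)                      # kappa-20 normalization

bl = mx.detect_bacterial_layer(cast, threshold=10.0)
print(f"BL {bl.top:.2f}-{bl.bottom:.2f} m, thickness {bl.thickness:.2f} m")
# BL 12.30-13.70 m, thickness 1.40 m

plan = mx.plan_sampling_depths(bl)
print({k: round(v, 1) for k, v in plan.depths().items()})
# {'above_1m': 11.3, 'bl_top': 12.3, 'bl_mid_50cm': 12.8,
#  'bl_bottom': 13.7, 'below_1m': 14.7}

hyps = mx.parametric_hypsometry(A_o=0.23e6, z_bot=21.0, q=1.96)
print(f"center of volume {mx.center_of_volume(hyps):.2f} m")
# center of volume 5.30 m

dens = mx.density_profile_from_ctd(cast)
sc = mx.schmidt_stability(dens, hyps, mode="anomaly")
print(f"Sc = {sc.sc_J_m2:.1f} J m^-2")
# Sc = 74.9 J m^-2
```

The detected layer boundaries are the analytic depths where the
Gaussian turbidity peak crosses 10 FTU (13 ± 0.70 m); the center of
volume of the power-law basin with shape exponent q = 1.96 lands at
5.30 m; and the Schmidt stability of this two-layer density structure
(Δρ ≈ 1.0 kg m⁻³ across the chemocline, thermal plus κ20 gradients) is
of order 10²  J m⁻² — the work per square metre of lake surface needed
to homogenize the column, small in absolute terms because most of the
basin's volume sits above the chemocline.

The same chain is available from a shell:

```
meromix simulate profile --seed 3 --out cast.csv
meromix stability --profile cast.csv --parametric-q 1.96 --out sc.csv
meromix bl --profiles casts/ --threshold 10 --out bl.csv
```

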