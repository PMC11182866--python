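# corestrat

Multiproxy analysis of short lake-sediment cores: reconstructing the
onset of eutrophication and the accompanying food-web change from
depth-indexed proxy records, with every stage testable against a
seeded synthetic-core generator that plants known effects.

The package is aimed at paleolimnologists working with recent
(~century-scale) gravity cores who need a reproducible, scriptable
version of the standard analysis chain:

1. **²¹⁰Pb geochronology** — supported-activity estimation from the
   profile tail, CFCS (Constant Flux Constant Sedimentation) and CRS
   (Constant Rate of Supply) age-depth models with Monte-Carlo
   uncertainty, and tie-point transfer of a chronology to an undated
   twin core.
2. **Hyperspectral chloropigments** — the relative absorption band
   depth index RABD₆₅₅₋₆₈₀ from reflectance spectra, with moving-average
   smoothing and depth binning.
3. **Pigments, geochemistry, subfossils** — organic-carbon
   normalisation, the chlorophyll preservation index
   CPI = Chl *a* / (Chl *a* + pheophytin *a* + pheophorbide *a*),
   pigment influx, atomic TC:TN ratios, Suess-corrected δ¹³C, and
   marker-spore-based concentrations and influxes of cladoceran and
   *Chaoborus* subfossils from body-part counts (multiplicity-adjusted
   minimum number of individuals).
4. **Zonation** — CONISS, stratigraphically constrained incremental
   sum-of-squares clustering, with broken-stick selection of the number
   of significant zones.
5. **Intervention analysis** — a within-core randomized intervention
   analysis (RIA): the pre/post mean difference at a dated intervention
   depth against a seeded permutation null,
   p = P(|Δ\*| ≥ |Δ|), two-sided, with an exact exhaustive mode for
   short series.

## The core statistics

**CFCS**: least squares of ln C<sub>u</sub> on cumulative dry mass *m*
gives slope −λ/r, hence a single mass accumulation rate
r (g cm⁻² yr⁻¹) and age(m) = t₀ − m/r, with λ = ln 2 / 22.3 yr⁻¹.

**CRS**: the unsupported inventory below depth z,
A(z) = ∫<sub>z</sub> C<sub>u</sub> dm, decays purely radioactively, so
t(z) = λ⁻¹ ln[A(0)/A(z)] and the local mass accumulation rate is
λA(z)/C<sub>u</sub>(z).

**RABD₆₅₅₋₆₈₀**: with shoulder reflectances at 590 and 730 nm and the
trough minimum R<sub>min</sub> inside 655–680 nm, the index is the
continuum (band-count-weighted shoulder interpolation at the minimum)
divided by R<sub>min</sub>; a flat spectrum scores exactly 1.

**CONISS**: only stratigraphically adjacent clusters may merge; each
step fuses the pair minimising the within-cluster sum-of-squares
increase n<sub>a</sub>n<sub>b</sub>/(n<sub>a</sub>+n<sub>b</sub>)
‖c̄<sub>a</sub>−c̄<sub>b</sub>‖². Splits are accepted while their
proportional dispersion reduction exceeds the broken-stick expectation
e<sub>k</sub> = (1/n) Σ<sub>j=k..n</sub> 1/j.

**RIA**: Δ = mean(post) − mean(pre); the series values are permuted
(1000 draws by default, seeded), Δ\* recomputed at the same split, and
p is the proportion of |Δ\*| ≥ |Δ| (reported both raw and with the
conservative +1 correction).

## Worked example

Run the full pipeline on a synthetic core (37 cm, surface year 2018,
eutrophication onset planted at 1920 with a 5× pigment increase, a 75%
cladoceran collapse planted at 1957):

```sh
corestrat -v run --seed 1 --out demo_run
```

The manifest (`demo_run/manifest.json`) reports the dated intervention
depth and the zonation:

```
intervention: {'intervention_depth_cm': 20.02, 'changepoint_depth_cm': 12.45}
              95% depth band [19.52, 20.50] cm
zones: pigments  {'n_zones': 2, 'boundaries_cm': [20.0]}
       cladocera {'n_zones': 2, 'boundaries_cm': [13.0]}
```

The truth for this seed places the 1920 CE layer at 20.58 cm and the
1957 collapse at 12.81 cm: the chronology recovers both within half a
sample, and CONISS puts the significant zone boundaries at the planted
transitions. `demo_run/ria.csv` holds the per-variable intervention
tests (first rows):

```
      variable  mean_pre  mean_post  fold_change  p_add_one
   bb_carotene    29.847    143.248        4.799      0.001
 chlorophyll_a    11.748     56.960        4.849      0.001
  pheophytin_a    61.623    285.596        4.635      0.001
pheophorbide_a    43.724    213.766        4.889      0.001
```

Every pigment is significant at p ≤ 0.05 with fold changes clustering
around the planted 5× (slightly below, because the post-onset window
includes the rising ramp). `demo_run/ria_changepoint.csv` splits the
cladoceran series at the 1957 changepoint instead and recovers the
planted 75% collapse, while the deliberately rare *Chaoborus* series
stays non-significant:

```
 variable  pct_change  p_add_one
    Alona     -69.439      0.001
  Bosmina     -65.710      0.001
Chaoborus     -19.685      0.440
 Chydorus     -71.868      0.001
```

The same stages are available individually (`corestrat simulate`,
`date`, `tchl`, `subfossils`, `zones`, `ria`, `validate`) and as plain
library calls (`corestrat.fit_crs`, `corestrat.rabd_index`,
`corestrat.coniss`, `corestrat.ria_test`, ...).

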