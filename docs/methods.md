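# Methods

This note documents the models implemented in `corestrat`, the
assumptions behind them, the choices made where the design was open,
and what the synthetic-core tests do and do not demonstrate.

## ²¹⁰Pb geochronology

Sediment ages over the last ~150 years are derived from the decay of
atmospherically delivered ("unsupported") ²¹⁰Pb over the background
("supported") activity in equilibrium with in-situ ²²⁶Ra. The decay
constant is fixed at λ = ln 2 / 22.3 yr⁻¹ (the standard ²¹⁰Pb
half-life). Depths follow the half-open convention [top, bottom) in cm,
zero at the sediment–water interface; regressions use sample
mid-depths, and cumulative dry mass (g cm⁻²) is the independent
coordinate so compaction does not bias the models.

**Supported activity.** The default estimator is the mean of the
lowermost `tail_n` total activities, with a 1σ from the reported
measurement errors combined in quadrature. This is unbiased only when
the tail has genuinely reached background; the estimator emits a
warning when the tail still declines. For profiles whose tail retains
residual excess (slow accumulation, short core), the
`decay_corrected` method alternates between a log-linear fit of the
unsupported profile and re-averaging the tail after subtracting the
fit's extrapolated residual excess — a few Bq/kg of leftover excess
otherwise propagates into a rate bias of tens of percent. The pipeline
uses `decay_corrected` by default; both agree when the tail is at
background.

**CFCS** fits ln C<sub>u</sub> against cumulative mass; the rate is
r = −λ/slope and ages are linear in mass. Samples with unsupported
activity below 10% of the profile maximum are excluded from the
regression (configurable via `min_unsupported_frac`): so close to
background, their log-activity is dominated by baseline uncertainty
and they lever the slope disproportionately. The 95% age band
propagates the slope standard error. Two-point fits are allowed with a
warning; a non-negative slope aborts with a "no decay trend"
diagnostic. Negative unsupported values are excluded from fits and
counted in the model flags rather than modelled (turbation is flagged,
not deconvolved).

**CRS** integrates the unsupported inventory over cumulative mass.
Segments between samples are integrated with the log-mean rule
(∫ = (C₁−C₂)Δm / ln(C₁/C₂)), which is exact when activity decays
exponentially between samples — the model's own law — with a
trapezoid fallback for flat segments; the surface value is
extrapolated exponentially from the first segment. The inventory below
the deepest sample is closed with an exponential tail whose e-folding
comes from the CFCS slope (standard practice; a warning flags tails
exceeding 20% of the total inventory, since ages then lean heavily on
the extrapolation). Ages follow t(z) = λ⁻¹ ln[A(0)/A(z)]; the 95% band
re-dates `mc_draws` profiles perturbed with the reported 1σ errors
(seeded and reproducible). On noise-free constant-flux
constant-sedimentation cores, CRS and CFCS ages agree to ~10⁻¹³
relative; with a plain trapezoid the disagreement at the core top
reaches ~4% of elapsed time, which is why the log-mean rule is used.

**Tie-point transfer** maps an undated core onto a dated chronology by
piecewise-linear interpolation between stratigraphic correlation
points (e.g. matched total-chloropigment features); mappings beyond
the outer tie points are linearly extrapolated and flagged. A
`method` label field allows externally produced chronologies (e.g.
Bayesian age models) to be read from CSV and used interchangeably.

## RABD₆₅₅₋₆₈₀ chloropigment index

For each spectrum the trough minimum is the gridpoint of minimum
reflectance within 655–680 nm (no sub-band interpolation: on ~1-nm
grids the refinement is negligible). With X bands between the minimum
and the right shoulder and Y bands between the left shoulder and the
minimum, the continuum is (X·R<sub>left</sub> + Y·R<sub>right</sub>)/(X+Y)
— on uniform grids exactly the linear interpolation of the shoulders —
and the index is continuum/R<sub>min</sub>. A flat spectrum scores
exactly 1; the index is invariant to uniform scaling of the spectrum,
so calibration of absolute reflectance does not matter. Shoulder
wavelengths default to 590/730 nm and are configurable. Smoothing uses
a centred k = 13 moving average whose end windows are clipped to the
series; depth binning averages values whose mid-depths fall in
half-open [i·bin, (i+1)·bin) bins, keeping empty bins as missing.

## Pigments, geochemistry, subfossils

Pigment concentrations are normalised to organic carbon by dividing by
TC/100, and influx is concentration × dry bulk density × sedimentation
rate. The preservation index CPI = Chl a / (Chl a + pheophytin a +
pheophorbide a) uses the two chlorophyll-a derivatives in the
analysed pigment set; an all-zero input leaves CPI undefined (NaN)
rather than zero. The atomic TC:TN ratio is
(TC/12.011)/(TN/14.007).

δ¹³C values are corrected for the Suess effect by subtracting the
change of the atmospheric CO₂ δ¹³C curve relative to a reference year
(default 1900, configurable). The curve is a pluggable tabulated input
evaluated by linear interpolation; the packaged default is a
**synthetic** stand-in reproducing the accepted industrial-era shape
(~ −6.4‰ preindustrial falling to ~ −8.6‰ by the late 2010s) and
should be replaced with a measured compilation for real-data work.

Subfossil abundances follow the minimum-number-of-individuals rule
with a multiplicity adjustment: each body part count is divided by its
per-individual multiplicity (headshield 1, carapace 2 valves,
postabdomen 1, *Chaoborus* mandible 2; user-overridable) and rounded
up before taking the maximum over parts — raw maxima would
double-count paired parts. The screened volume is the subsample volume
times the fraction of added *Lycopodium clavatum* marker spores
recovered; concentration is MNI per screened cm³, and influx divides
by the local years-per-cm, i.e. multiplies by the age model's
sedimentation rate at the sample depth. Zero recovered spores leave
concentration undefined with a warning.

## CONISS and broken-stick zonation

Variables are prepared by natural-log transform (optional, with a
configurable pseudo-offset for zeros) and per-variable centring; unit
variance scaling is provided as a flag because centring alone and full
standardisation are both defensible readings of common practice.
Clustering is agglomerative with the adjacency constraint: only
stratigraphically neighbouring clusters may fuse, and each step takes
the fusion with the minimal within-cluster sum-of-squares increase,
computed incrementally from cluster sizes and centroids. Ties go to
the uppermost pair, making output deterministic. The increments sum to
the total sum of squares about the grand mean (asserted to 1e-9
relative), and for small n the merge sequence is verified against a
brute-force oracle that recomputes every candidate cost from raw
samples.

Zone counts are read from the merge tree in reverse: the split into k
zones is accepted while its proportional dispersion reduction exceeds
the broken-stick expectation e<sub>k</sub> = (1/n)Σ<sub>j=k..n</sub>1/j,
stopping at the first failure (sequential stopping yields a contiguous
zone hierarchy; accepting any later split that clears the bar would
not). Zero total dispersion yields one zone. On 37-sample, 15-variable
iid noise matrices the procedure returns a single zone in ≈100% of
seeds; matrices with fewer variables are more permissive (a 30×3 noise
matrix yields a spurious second zone in ~20% of seeds), so zone counts
from variable-poor records deserve caution.

## Randomized intervention analysis

The observed effect is Δ = mean(post) − mean(pre) at a fixed split
(the core depth dated to the intervention year; a sample exactly at
the boundary goes to the post side by default, configurable). The
null permutes the series values uniformly (full exchangeability),
splits at the same index and recomputes Δ\*; the two-sided p is the
proportion of |Δ\*| ≥ |Δ|. Sampled mode (default 1000 permutations)
reports both the raw proportion and the conservative +1-corrected
(1+count)/(n_perm+1), flagged `p_add_one`, which can never be zero;
exhaustive mode enumerates all C(n, n_pre) assignments for short
series and reports the exact proportion. The batch runner gives every
variable an independent spawned substream, and adds a
Benjamini–Hochberg column as a clearly-labelled extension — the
per-variable p-values are the primary result. The test is exact under
exchangeability; serial autocorrelation violates exchangeability and
inflates the type-I error, which the generator's AR(1) noise option
(`pigment_ar1`) exists to demonstrate. Block permutation is not
implemented.

**Interpreting percent changes when the response lags the
intervention.** With the split at the intervention year t₀ and an
abrupt change at a later year t₁, the post-window mean mixes
pre-change and post-change values, so a step decline of fraction f
appears as f·(t_surface − t₁)/(t_surface − t₀). Under the default
synthetic conditions (t₀ = 1920, t₁ = 1957, surface 2018) a planted
75% cladoceran collapse is expected to register as ≈ −47% in the
1920-split RIA. The pipeline therefore runs a second, changepoint-split
RIA for the zooplankton series (default 1957) whose percent change is
the undiluted recovery of the planted collapse; both outputs are
written (`ria.csv`, `ria_changepoint.csv`).

## Synthetic cores: what they emulate and what they do not

The generator plants the full effect structure the pipeline is meant
to detect in a ~37 cm, 1-cm-sampled core with surface year 2018,
constant sedimentation 0.21 cm/yr (so ~25 cm dates to ~1900) and
constant dry bulk density 0.5 g/cm³:

* total ²¹⁰Pb = 30 + 500·exp(−λt) Bq/kg with multiplicative N(0, cv)
  noise on the unsupported term (cv = 0.10 by default) and 1σ error
  columns; a weak ¹³⁷Cs bump near 1963 is included but never used for
  dating;
* fifteen pigments with fixed baselines, multiplied by
  `pigment_fold_change` (default 5, within the plausible 2–10× range)
  after the 1920 onset — a linear ramp three samples wide by default,
  or a step — under mean-preserving lognormal noise (σ = 0.15 of the
  log), optionally AR(1); an optional second multiplier on the
  cyanobacterial pigments after 1990 emulates a late cyanobacteria-
  dominance zone and is off by default;
* cladoceran body-part counts (headshields ×1, carapace valves ×2)
  Poisson-distributed around taxon baselines that drop by
  `cladoceran_decline_frac` (default 0.75, within the observed 60–85%
  band) after the 1957 collapse year; *Chaoborus* mandibles are rare
  (mean 0.5/sample) with no planted change, providing a null variable;
* marker spores N(9666, 671²), rounded and truncated at ≥1, with a
  binomially sampled counted fraction (35% expected);
* reflectance spectra on a 1-nm 590–730 nm grid: flat 0.5 continuum
  minus a Gaussian trough at 667 nm (σ = 6 nm) whose depth is
  proportional to the summed pigment concentration, plus N(0, 0.002)
  noise;
* bulk geochemistry with a declining atomic C:N (11 → 9.4), a Suess
  trend imprinted on δ¹³C from the packaged atmospheric curve, and
  flat δ¹⁵N.

A fixed seed reproduces every table byte for byte; each output CSV
records the seed in a comment header.

The generator deliberately omits several features of real cores:
sediment mixing/bioturbation (the paper-world motivation for flagging
rather than modelling negative unsupported values), compaction
gradients, ¹³⁷Cs pore-water diffusion, XRF element counts, phosphorus
fractions, pigment degradation gradients (CPI inputs are generated
like any other pigments), and spatial heterogeneity of subfossil
deposition. Passing the recovery tests therefore demonstrates the
statistical machinery is correct and calibrated under the stated
conditions — not that real, turbated, compacting cores will yield
equally clean recoveries.

## Numerical choices and problem sizes

Tolerances: CONISS conservation asserted at 1e-9 relative; RABD hand
examples at 1e-12; permutation-count ties use a 1e-12-scaled tolerance
on |Δ\*| comparisons. Degenerate inputs: all-identical series give
Δ = 0, p = 1; zero total dispersion gives one zone; all-zero CPI input
is NaN. Zone boundaries are reported at the midpoint between the
bounding samples' depths.

The simulation studies shipped with the package use the sizes chosen
for routine desk-scale verification: 200 seeds for noisy-rate and
zonation recovery, 500 replicates × 999 permutations for RIA
calibration, 50 random matrices (n ≤ 8) for the clustering oracle,
300 Monte-Carlo draws for pipeline CRS bands. The full suite runs in
well under a minute on one CPU.

## Known limitations

* CFCS/CRS assume constant ²¹⁰Pb supply; changing flux or slumping
  violates both, and the package flags rather than models such
  intervals. The Bayesian alternatives are intentionally out of scope;
  external chronologies can be supplied via CSV.
* The RIA's exchangeability assumption is routinely violated by
  autocorrelated proxy series; its p-values are anti-conservative in
  that regime.
* The broken-stick criterion's specificity depends on the number of
  variables (see above).
* The packaged Suess curve is a synthetic stand-in, adequate for
  pipeline demonstration only.
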