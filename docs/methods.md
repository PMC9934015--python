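# Methods

This note documents the models behind `carbonledger`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that are not visible from the API.

## Sign conventions and units

Positive NEE is a net source of CO₂ to the atmosphere throughout, so
NEE = R_eco − GPP with GPP ≥ 0. Tower fluxes are µmol CO₂ m⁻² s⁻¹,
daily aggregates g C m⁻² d⁻¹ (× 1800 s per half hour × 12.011 µg C µmol⁻¹),
plot budgets Mg C ha⁻¹ yr⁻¹ (365-day year; 1 g C m⁻² d⁻¹ =
3.65 Mg C ha⁻¹ yr⁻¹). The unit registry performs exact conversions; the
round trip is tested to floating point.

## Friction-velocity threshold (moving point method)

Nocturnal records (SW_IN ≤ 10 W m⁻²) are stratified by season
(year-quarter; collapsed to a single season when too sparse) and into six
air-temperature quantile classes; each class is sorted into twenty
equal-count u* bins. A class's threshold is found at the first bin whose
mean NEE reaches 95 % of the mean NEE of *all* higher bins, and set to the
midpoint between that bin's centre and the previous bin's centre. Class
thresholds are averaged into a single mean threshold.

Two choices deserve comment:

- **Reference = all higher bins.** Comparing against only the next ten
  bins fails when turbulence suppression is a plateau (roughly constant
  attenuation below the threshold) rather than a monotone ramp: every
  attenuated bin then resembles its attenuated neighbours and the search
  fires at the lowest bin. Using all higher bins keeps the criterion
  anchored to the unsuppressed plateau. Configurable via
  `n_compare_bins`.
- **Midpoint convention.** The first passing bin's own centre
  overestimates the threshold by about half a bin; the midpoint between
  the last failing and first passing centres removes most of that bias
  (verified by recovery simulations).

Classes where |Spearman ρ(Tair, u*)| > 0.5 are skipped (temperature–
turbulence confounding guard). If no class yields a threshold the
estimator raises an explicit "not estimable" error rather than defaulting.
A series with no detectable suppression is flagged `degenerate` when at
least half the classes fire at the lowest bin.

## Gap filling (marginal distribution sampling)

A missing half hour is filled with the mean of observed NEE under similar
meteorology; the filled value carries its donor set's sample SD and a tier
label. Similarity tolerances default to Rg ± 50 W m⁻², Tair ± 2.5 °C,
VPD ± 5 hPa (the method family's customary values; all configurable). The
tier ladder is: all three drivers at ± 7 then ± 14 days; radiation only at
± 7 days; same time of day ± 1 h at ± 1 then ± 2 days; then the same three
modes in windows expanding by 7 days up to ± 70. A fill requires at least
two donors. Only days containing at least one observation are filled; a
record unfillable at every tier stays missing and later excludes its day
from the daily table. Original observations are never altered and carry
fill SD 0.

## Daytime partitioning

NEE is modelled per moving window (7 days long, advancing 2 days) as a
rectangular-hyperbola light response plus Lloyd–Taylor respiration:

    NEE = −(α·β·Rg)/(α·Rg + β) + rb·exp(E0·(1/(T_ref − T₀) − 1/(T − T₀)))

with T_ref = 15 °C, T₀ = −46.02 °C, and β down-regulated exponentially
above VPD₀ = 10 hPa. E0 is fitted once from nocturnal observations over
the whole series — 7-day windows leave it unidentifiable — and held fixed;
windows then fit (α, β₀, k, rb) by trust-region least squares with
non-negative bounds. When a window has fewer than five records above VPD₀,
k is unidentifiable: it is fixed at 0 and flagged. Windows with fewer than
20 usable daytime points or non-convergent fits are flagged invalid and
bridged by the nearest valid window when the fits are applied.

Per record, R_eco comes from the fitted respiration term and
GPP = R_eco − NEE. Nocturnal GPP is forced to 0 (so nocturnal
R_eco = NEE), and rare negative daytime GPP half-hours (fit noise) are
clamped to 0 with the residual pushed into R_eco; both moves preserve the
per-record identity NEE = R_eco − GPP exactly, and the clamp count is
reported. Fits use observed (unfilled) values by default.

## Daily aggregation and uncertainty

A day is the half-open interval of 48 half-hour-ending records
(ending 00:30 … 24:00). Days enter the daily table only when complete —
48 records, none excluded from partitioning, at least one originally
observed value (days that are all gap or all filled-from-nothing are
dropped and logged). The NEE uncertainty budget combines three terms by
root sum of squares: a random-error term (configured per-source SDs in
quadrature; the default inventory names u*, wind speed, air density and
momentum flux at 0.25 g C m⁻² d⁻¹ each — a documented placeholder
magnitude, not a site measurement), a gap-filling term (per-day quadrature
of fill SDs, RMS across days) and the SD of the daily NEE estimates.
Squared-term fractions sum to 1 exactly. Relative uncertainties are
SD/mean × 100, reported to the nearest integer percent.

Period comparisons treat days as replicates. The default two-sample test
is the Wilcoxon rank-sum (the periods are unpaired samples of days); a
paired signed-rank variant is provided for parity with analyses that treat
them as paired. Small samples get an exact p by full enumeration over rank
assignments (valid under ties; two-sided p = 2 × smaller tail, clipped at
1); larger samples use the tie-corrected normal approximation.

## Biometric budgets

The component set is closed over eleven terms: woody/canopy/fine-root NPP;
stem, coarse-root, fine-root and leaf respiration (autotrophic); litter,
mycorrhiza, soil-organic-matter and deadwood respiration (heterotrophic).
"Woody respiration" is carried as stem + coarse-root so the set stays
closed. Choices:

- **Soil partition design is configuration, not code.** The default maps a
  cumulative exclusion design (total / no-roots / no-roots-no-mycorrhiza /
  SOM-only collars) to component differences; sites with a different
  collar scheme supply their own mapping. Component SEs combine the
  differenced treatment SEs in quadrature, and the components re-sum to
  total soil respiration by construction.
- **Chamber-to-plot scaling is linear**: mean per-surface-area flux times
  total surface area (allometric a·D^b summed over the census for stems;
  cylinder lateral area π·D·L summed over the ≥ 10 cm inventory for
  deadwood), divided by the 10⁴ m² plot ground area. Allometric
  coefficients are user-supplied; the synthetic generator documents its
  default (a = 0.05, b = 1.5, diameters in cm, areas in m²).
- **Leaf inhibition on daylight only.** The 0.67 light-inhibition factor
  applies to the daylight fraction of the diurnal integral (12 h at an
  aseasonal site), giving the 24-h multiplier (12·0.67 + 12)/24 = 0.835;
  both the factor and the daylight hours are configurable.
- **Welch t is the default** for group comparisons (plot groups are small
  with unequal variances); the pooled test is available where classical
  degrees of freedom are wanted. No multiple-testing correction is applied
  by default. Group means carry between-plot SEs (SD across plots / √n);
  plot budgets carry within-plot SEs from component error propagation —
  two different error bars for two different questions.
- NEE's propagated SE uses the R_h − NPP formulation; the autotrophic
  terms appearing in both R_eco and GPP cancel algebraically and would be
  double-counted by naive quadrature on R_eco − GPP.

A plot missing any component has its aggregates withheld (flagged
incomplete) unless an explicit imputation mapping fills it; imputed
components are labelled in the output.

## Method comparison

Both estimates are converted to a common unit (default Mg C ha⁻¹ yr⁻¹)
before comparison. The eddy 95 % CI is mean ± 1.96 × total RSS uncertainty
(daily estimates are numerous, so a normal multiplier); a biometric group
mean uses a t multiplier with n − 1 df, a single plot the normal
multiplier on its propagated SE. The comparison reports interval overlap
and the signed difference.

## Synthetic data: what it emulates, what it does not

The tower generator drives the *inverse* of the partitioning model:
clear-sky half-sine radiation over a 12-h photoperiod (aseasonal site, no
seasonal cycle), sinusoidal diurnal temperature (peak 14:00), VPD linearly
coupled to temperature, NEE from the light-response + Lloyd–Taylor model
with additive Gaussian noise (a flux-proportional switch exists), Gaussian
single-record gaps mixed with multi-day blocks, lognormal nocturnal u*,
and nocturnal NEE multiplied by 0.5 below the true threshold
(0.29 m s⁻¹). Defaults describe the targeted study conditions: three
measuring periods of 65, 100 and 290 sampled days; gap fraction 0.495;
per-period flux multipliers (1.15 / 1.0 / 0.85 on β₀ and rb) so the three
periods order as observed at the site (fluxes highest ~10 y after logging,
lowest 2–3 y after salvage logging); α = 0.06 µmol J⁻¹, β₀ = 45 µmol m⁻²
s⁻¹, k = 0.05 hPa⁻¹, rb = 8 µmol m⁻² s⁻¹, E0 = 180 K, chosen once to give
daily GPP ≈ 8 and R_eco ≈ 12 g C m⁻² d⁻¹ — magnitudes realistic for
lowland Bornean forest. The generator does **not** simulate footprint
heterogeneity, advection or storage fluxes, seasonality, weather
autocorrelation, or instrument spikes; passing recovery tests therefore
demonstrates correctness of the algorithms under the stated generative
model, not robustness to every artefact of real towers.

Period lengths count *sampled* days. With multi-day outage blocks
(default mix) whole days legitimately drop from the daily table, as only
days with observations are gap-filled; runs that need the daily table to
cover every sampled day (day-accounting checks, the acceptance script)
use single-record gaps (`block_gap_share = 0`).

The plot generator draws plot-level component truths around per-group
means (between-plot SD 0.5 Mg C ha⁻¹ yr⁻¹ per component), then emits
replicate-level raw tables consistent with those truths: collar fluxes per
exclusion treatment, per-tree stem fluxes back-calculated from a generated
census so that the scaled plot flux equals the truth, deadwood pieces and
inventory likewise, leaf respiration inputs solved from the truth given
LAI and sun/shade structure, and directly consumed NPP and coarse-root
values with SEs. Group means encode a realistic logging contrast: similar
NPP with an allocation shift from canopy to wood, and elevated
soil-organic-matter and deadwood respiration in logged classes (true group
NEE: −0.7 unlogged, 1.8 moderately, 5.5 heavily logged Mg C ha⁻¹ yr⁻¹).
Coarse-root respiration is emitted as a directly consumed value (field
protocols typically derive it from stem respiration rather than measuring
it per replicate). With all noise at zero the pipelines invert the
generator exactly; this is tested.

## Problem sizes in the tests and acceptance script

Recovery tests run the full 455-day record (single-seed) and 20 seeds for
threshold recovery; the Monte-Carlo group-mean check uses 100 seeds of the
11-plot design; the gap-filler oracle uses a 1,000-record hand-built
table. These sizes make every stochastic assertion stable at fixed seeds
while keeping the suite fast.

## Known limitations

- The moving-point u* detection assumes respiration is roughly stationary
  within a temperature class; strong seasonality would require the
  seasonal stratification to carry more weight than the aseasonal default.
- The MDS implementation searches donors on the uniform half-hour grid;
  irregular records must be reindexed first.
- E0 is global; sites with seasonally varying temperature sensitivity
  would need windowed E0 estimation.
- The random-error term of the uncertainty budget is a configured
  inventory, not an estimate from the data (no high-frequency information
  is available at the half-hourly level).
- Budget assembly treats component errors as independent; shared scaling
  inputs (e.g., LAI entering several components) would induce covariance
  that the quadrature ignores.
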