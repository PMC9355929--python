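# Methods

`croppsi` evaluates smallholder rice-based cropping systems on eight
agronomic, economic and environmental indicators, summarizes synergies and
trade-offs against the single-crop baseline, condenses seven indicators
into one latent performance score by factor analysis, and benchmarks each
household against the top-quintile performers of its own system.  This
note records the models, the defaults, and the design decisions.

## Setting and unit of analysis

The setting is coastal south-central Bangladesh.  Every household grows
rainfed transplanted aman rice in the monsoon (kharif-2) season; a subset
adds one dry-winter (rabi) crop — mungbean, lathyrus, groundnut, irrigated
boro rice, or chili — and kharif-1 stays fallow.  The unit of analysis is
a household × cropping-system annual bundle; households practicing several
systems contribute one observation per system.  Because polder embankments
change hydrology, salinity and crop choice, all models are fit separately
for households within and outside polders.

## Indicators

With `Y_x` the crop yield (t/ha), `P_x` its price, and `P_r` the
household's own aman paddy price:

* **Rice equivalent yield** `REY = Σ_x Y_x · P_x / P_r` (t/ha/yr), where
  for rice crops `Y_x` additionally counts straw converted to grain
  equivalent through the straw/grain price ratio.  Using the household's
  own `P_r` makes REY invariant to a common rescaling of all prices.
* **Economics** (BDT/ha/yr): gross returns = Σ yields × prices (straw
  included for rice); cost of cultivation = inputs + labor + land
  preparation + irrigation; net returns = gross − cost.  USD views divide
  by the study-year rate of 77.87 BDT/USD.
* **Agronomic energy input** `AEI` (GJ/ha/yr): each input quantity times
  its embedded-energy factor (MJ/kg nutrient, MJ/kg a.i., MJ/L diesel)
  plus labor person-hours × 1.96 MJ/h, summed over the system's crops.
* **Total energy production** `TEP` (GJ/ha/yr): grain yields × grain
  energy factors.  Straw energy is deliberately excluded: straw enters
  REY and gross returns but not TEP.  This asymmetry is intentional and
  kept; it implies TEP-based efficiency levels here are lower than in
  analyses that credit straw energy (see *Calibration*, below).
* **Net energy yield** `NEY = TEP − AEI`, may be negative.
* **Efficiencies**: energy efficiency `NEY/AEI`; partial N productivity
  `TEP / (system kg N)`; partial K productivity `TEP / (system kg K₂O)`;
  benefit-cost ratio `gross/cost`; hired-labor energy productivity
  `TEP / (hired person-days)`.  Denominators sum over all crops of the
  annual system (per-crop variants exist but are not the default).
* **Partial GHG footprint** (kg CO₂e/GJ): input production/use emissions
  (fertilizer, pesticide, diesel) plus fertilizer-derived N₂O, divided by
  TEP.  Direct and indirect N₂O follow the IPCC Tier-1 pathway:
  `N₂O-N = N·EF₁ + N·Frac_GASF·EF₄ + N·Frac_LEACH·EF₅`, converted by
  44/28 and a GWP₁₀₀ of 265 (AR5; configurable, since the choice of GWP
  horizon is a reporting convention).  Soil methane from flooded fields
  is **never** included — flood duration is not observable in this kind
  of survey — so footprints are "partial" and comparisons involving the
  double-rice system understate its true footprint.

**Masking.**  A zero denominator (e.g. no hired labor, no K applied, zero
TEP) yields a masked (NaN) indicator, never 0 or ±inf.  The row is kept;
each downstream analysis drops masked values for that indicator only,
preserving sample size elsewhere.

## Coefficient table

Energy and GHG factors are not estimable from the survey; results are
conditional on a coefficient table.  The packaged defaults are
literature-standard values (N 60.6, P₂O₅ 11.1, K₂O 6.7 MJ/kg; diesel
47.8 MJ/L; pesticide 120 MJ/kg a.i.; labor 1.96 MJ/h; rice grain
14.7 MJ/kg; pulses 14.7; groundnut pods 13.0; dried chili 13.0 MJ/kg;
GHG intensities N 4.8, P₂O₅ 0.73, K₂O 0.55 kg CO₂e/kg, pesticide 19
kg CO₂e/kg a.i., diesel 3.2 kg CO₂e/L including combustion).  Chili is
taken on a dry-weight basis — its market price and energy content refer
to dried pods — and groundnut on an unshelled-pod basis; both are
per-crop entries a user can override.  Every factor is overridable from a
YAML file; omitted keys fall back to the packaged defaults, including the
Tier-1 N₂O set (EF₁ 0.01, EF₄ 0.010, EF₅ 0.0075, Frac_GASF 0.10,
Frac_LEACH 0.30).

## Trade-off analysis

For each double-cropped system and each indicator, the relative change is
computed against the *same household's* single-aman baseline:
`(system − baseline)·100/baseline`.  The per-cell summary reports the
mean household-level change with a t-based 95% CI, labelled a synergy
when the mean moves in the desirable direction (higher for everything
except the GHG footprint, where lower is better) and a trade-off
otherwise.  The mean of household-level changes generally differs from
the relative change of group means; both are available and labelled.
Households lacking a baseline value for an indicator are dropped for that
indicator only, with a diagnostic.

## Multi-criteria performance index

Seven indicators enter the index: REY, partial N and K productivity,
energy efficiency, benefit-cost ratio, GHG footprint, hired-labor energy
productivity.  TEP is excluded because most efficiency indicators already
carry it in their numerator.  Per stratum, complete rows are standardized
(z-scores within stratum, since the two strata are modelled separately),
sampling adequacy is checked with the Kaiser-Meyer-Olkin measure
(anti-image partial correlations from the inverse correlation matrix;
pseudo-inverse with a warning if singular), loadings are extracted by
principal components (eigenvectors of the correlation matrix scaled by
√eigenvalue), varimax-rotated with Kaiser row normalization when two or
more factors are retained (for the default single factor rotation is the
identity; the general-k rotation exists for sensitivity analyses and is
oracle-tested), and per-observation scores are regression (Thurstone)
scores `Z R⁻¹ L` — switchable to Bartlett.  The first-factor score is the
index.  Sign indeterminacy is resolved by forcing the partial-N-
productivity loading positive, which anchors the efficiency block
positive and the GHG footprint negative on efficiency-structured data.
A sample-adequacy guard (default 30 complete rows) refuses underpowered
fits.  Reported diagnostics: loadings, SS loadings, proportion of
variance (SS/7), RMSR of the off-diagonal correlation residuals, KMO
overall and per variable.

## Benchmarking (scope for improvement)

Within each stratum × system × indicator cell with at least five
households, the benchmark `P_fy` is the mean of the best `⌈0.2·n⌉` values
— largest for higher-is-better indicators, smallest for the GHG footprint
(a choice flagged in the output metadata); ties at the cutoff are all
included, which keeps the statistic deterministic.  Each household's
scope is `(P_fy − A_FY)/A_FY · 100`; it is invariant to a common positive
rescaling of the cell's values.  Smaller cells are skipped with a
diagnostic rather than benchmarked on a handful of farms.

## Group comparisons

Per stratum and indicator, a one-way fixed-effects ANOVA with cropping
system as the factor.  Group (least-squares) means — equal to arithmetic
means in the one-way layout — are reported with 95% CIs
`mean ± t(0.975, df_error)·√(MSE/n_g)`, so unequal group sizes enter
through the standard error.  Pairwise separation uses Tukey-Kramer
(studentized-range quantiles with the unequal-n standard error) at
α = 0.05, rendered as a compact letter display built from the maximal
cliques of the non-significance graph: two groups share a letter exactly
when their pairwise comparison is not significant.  Rows are treated as
independent even though a household can appear in several system groups,
a simplification shared with the source methodology and a documented
caveat.

## Synthetic survey generator

The generator is first-class, tested code that defines the package's
study conditions.  Defaults: 297 households within polders and 204
outside; system prevalences 92.9 / 37.7 / 14.8 / 7.7 / 3.7 % (mungbean,
lathyrus, groundnut, chili, boro) within and 79.4 / 51.0 / 8.3 % outside,
sampled independently per system (the joint membership distribution is
unreported; independence is an assumption).  Group means are calibrated
so the implied REY per system matches the published group means exactly
(e.g. 2.48 t/ha single aman and 6.18 t/ha double rice within polders),
benefit-cost ratios match via cost totals, and N rates sit in the
published ranges (aman 31–32; legumes +11–17; chili +60; boro +120–121
kg N/ha).  Remaining inputs (P, K, pesticide, fuel, labor, hired labor,
cost split) are fixed at field-plausible values chosen once to reproduce
the published within-column orderings of the efficiency indicators.

Quantities are truncated log-normal (99.9th-percentile cap so single
draws cannot dominate group means; gamma and degenerate families are
switchable) with per-field CVs of 0.20 (0.10 for prices).  Two shared
household multipliers induce realistic correlation: a productivity
multiplier (CV 0.15) on yields and prices, and an input-intensity
multiplier (CV 0.25) on input rates, labor and costs.  The intensity
dimension — intensive vs extensive management — is what makes the
efficiency indicators co-vary across households and is the latent
structure the index extracts; without it the leading factor is pure yield
luck and REY would dominate the loadings, contrary to how these
indicators behave in survey data.  A household's aman record is drawn
once and shared across its systems, so within-household baseline
comparisons are exact and `P_r` is consistent.

**What the generator does not emulate**: spatial structure and land
elevation classes, multi-year panels, joint (non-independent) system
membership, reporting error, and any dependence of input intensity on the
rabi crop choice beyond group means.  Passing tests on this synthetic
population demonstrates that the pipeline recovers known structure and
orderings under survey-like noise — not that any particular real
population shows those orderings.

## Calibration note on energy levels

With grain-only TEP and the standard 14.7 MJ/kg paddy factor, absolute
energy-efficiency and partial-productivity *levels* are roughly half of
published values for comparable systems whose accounting credits straw
energy in output.  The package follows the grain-only definition
verbatim; the generator is therefore calibrated to match REY and
benefit-cost levels exactly but only the *orderings and ratios* of the
energy-based indicators.  Conclusions driven by ranks (index ordering,
synergy/trade-off signs, scope patterns) are unaffected; absolute energy
levels should be read as conditional on the coefficient table and the
grain-only convention.

## Numerical choices

* Masked values propagate as NaN; analyses drop them per indicator.
* Percentile set size `⌈0.2·n⌉` with inclusive ties (deterministic).
* Varimax: SVD-based iteration, tolerance 1e-12, 1000 iterations,
  rotation matrix orthonormal to 1e-10; non-convergence returns the best
  iterate with a warning.
* KMO on singular correlation matrices falls back to the pseudo-inverse
  with a warning.
* Compact letters by exhaustive maximal-clique search (group counts ≤ 6).
* Problem sizes: the test suite exercises identities on ~10,000
  observations, ordering properties on 100 seeds × 300 households per
  stratum, and type-I calibration on 500 ANOVA replicates — sizes chosen
  to make Monte-Carlo noise negligible relative to the tested margins.

## Known limitations

* Field methane, water footprints and machinery-embodied energy beyond
  fuel are out of scope; the GHG footprint is partial by design.
* The index reflects only the seven indicators; investment requirements
  and climate risk — central to adoption decisions — are not included.
* ANOVA treats household × system rows as independent.
* Coefficient defaults are literature values, not study-specific
  measurements; all results are conditional on them.
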