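# Methods

This note documents the models, unit conventions, parameter defaults and
design choices behind `crustfix`, and what the synthetic-data tests do and
do not demonstrate about real field data.

## Study design emulated

Two perennial-agroecosystem sites ("Grape", a vineyard; "Citrus", an orange
orchard) sampled in four seasons; six plots per site, each with an intact
biocrust and an adjacent bare-soil patch; three subreplicate cores (3 cm
diameter, 0.5 cm depth) per patch, each incubated in its own airtight
138 mL jar with 10% acetylene headspace for 2 h in the field. Whether
subreplicate cores shared a jar is not determinable from the study design
description; the generator defaults to one core per jar and the analysis
exposes `cores_per_jar` should the other convention be wanted. ¹⁵N₂
calibration incubations exist only for Grape-Summer (3 biocrust + 3 bare
plots) and Citrus-Fall (2 biocrust plots).

## Acetylene reduction (ara module)

Single-point GC calibration through the origin against a 100 ppm C₂H₄
standard: `response_factor = standard_conc / standard_peak`. Headspace
amount uses the ideal-gas molar volume at the analysis temperature,
defaulting to 25 °C and 1 atm — the storage/analysis condition — rather
than the variable field temperature. The nominal jar volume is used
uncorrected for sample displacement (cores sit on the lid); a correction
term is exposed and defaults to 0.

Blank correction subtracts the simultaneously incubated non-acetylated
blank and floors at zero. Net ethylene below a configurable detection
floor (default 1 nmol per jar) is recorded as a zero rate with a
below-detection flag, reflecting "undetectable" assays; flags, never
sentinel values, carry censoring downstream.

Per-mass (nmol g⁻¹ DW h⁻¹) and per-area (μmol m⁻² h⁻¹) rates are exact
algebraic inverses given the core area and dry mass. The published
per-mass/per-area range pairs cannot be reconciled without the unprinted
per-sample dry masses, so cross-basis agreement is treated as an
order-of-magnitude consistency check only, not an assertion.

## ¹⁵N₂ mass balance (isotope module)

Empty spiked jars (gas blanks) measure the headspace atom% ¹⁵N directly;
subtracting air (natural abundance 0.3663 atom%, configurable — the study
measured air but prints no value) gives the enrichment excess. The
fraction of biomass N from fixation divides the biomass atom% excess by
the headspace-minus-unenriched-biomass difference; a negative biomass
excess (IRMS noise) is floored to zero with a warning flag rather than
raised, while a headspace not enriched above the biomass control is a
hard assay error. Rates: `fraction × total N / 14 g mol⁻¹ / duration`,
in nmol N g⁻¹ DW h⁻¹; the molar-N₂ rate is exactly half. The conversion
factor is defined against the molar-N₂ basis because the theoretical 3:1
stoichiometry it is compared with is per mole N₂; both bases are reported
so the choice is auditable. No correction is applied for incomplete ¹⁵N₂
equilibration with pore water.

## Conversion factor (calibration module)

Ratio of means — mean(ARA mass rates) / mean(N₂ rates) — not the mean of
per-pair ratios: it matches the stated estimation procedure and is robust
to small individual N₂ denominators. SD by the delta method from the two
sample SDs, assuming independent means. N-mass conversion uses 28 g N per
mol N₂ (both atoms are nitrogen); this reproduces the study's own
conversion-table rows exactly after 1-decimal rounding. Literature rows of
that table imply a different (factor-of-two) mass convention and are out
of scope. Display values like "1.2" are treated as rounded presentations
of full-precision factors (1.22); computation never rounds, reports do.

## Biomass and nutrients (nutrients module)

Fumigation–extraction with efficiencies 0.37 (C), 0.54 (N), 1.0 (P).
Extract-to-soil conversion `mg kg⁻¹ = mg L⁻¹ × V_extract(L) / m_soil(g) × 1000`.
The extraction ratio is unstated in the study; the conventional 1 g : 25 mL
is the default and only affects the concentration↔soil-basis step, which
the generator inverts consistently. Extract-basis detection limits default
to 0.01 mg L⁻¹ (P), 0.05 (N), 0.1 (C); a negative or below-limit flush is
reported as not-detected (missing), never negative. Ratios are computed
per sample and summarized as mean ± sd (2 decimals, mirroring conventional
table formatting); a family is excluded when the below-detection fraction
of its denominator strictly exceeds the threshold (default 30%, the
microbial-P situation). Moisture is per-dry-mass by default —
`(wet − dry)/dry × 100` — because the basis is unstated in the source
protocol; the per-wet basis is selectable and the choice is flagged in
output metadata. For seasonal comparisons biocrust and bare moisture pool
to n = 12 per site-season; ordination uses the biocrust-only series.

## Budget (budget module)

Daily input = hourly N-mass rate × light hours (default 10; dark fixation
assumed zero, a stated assumption of the analysis — a dark-rate term can
be added as input for sensitivity). Seasons default to 365/4 = 91.25 d
each (no calendar convention is given); lengths are configurable but must
sum to 365 ± 1. Annual full-coverage input is Σ(daily × days) × 10⁻²
kg N ha⁻¹ yr⁻¹; the field-scale estimate multiplies by the coverage
fraction (default 0.125). Missing seasons are never silently imputed:
policy is `error` (default), `zero`, or `carry-nearest`. Budget seasonal
means include zero-rate plots (an inactive plot contributes a true zero);
the zero-filtering used before ordination is a separate, counted screen.
Fertigation comparisons: per-application percentage against 4 g N per
tree; the percent-of-annual-fertilizer computation requires a user-supplied
total because the underlying totals are not published.

## Synthetic campaigns (synthetic module)

Defaults are the study's printed site-season means/SDs for soil
temperature, light, moisture, 24-h rainfall, MBC, MBN, EC, EN and EP, and
the printed seasonal ethylene-rate levels. Printed ratio cells are carried
as reference parameters but never used to generate pools (a ratio of
generated pools cannot also match an independently printed mean of
per-sample ratios). Four generator parameters are not printed anywhere and
were fixed once from printed aggregates:

- Grape fall ethylene mean 88 μmol m⁻² h⁻¹ and winter 58: winter is the
  minimum of the printed significant-season range (58–260) under the
  monotone summer→spring decrease; fall is then set so the seasonal means
  integrate to the printed full-coverage annual (~39 kg N ha⁻¹ yr⁻¹).
- Citrus seasonal means 13 / 74 / 78 / 137: endpoints from the printed
  range, integrating to ~63 kg N ha⁻¹ yr⁻¹ against the printed 64. The
  source text is internally inconsistent here (a winter maximum of 78
  cannot coexist with a 74–137 seasonal range and a rising summer→spring
  trend); the generator follows the rising trend and the range endpoints.
- MBP seasonal means interpolate the printed per-site extremes (Grape
  29→10, Citrus 29.5→3 mg kg⁻¹) with SD = mean (high reported variability).
- Headspace enrichment ~18 atom% ¹⁵N: 20 mL of 98% ¹⁵N₂ diluted into
  ~92 mL of natural-abundance N₂ in a 138 mL jar (measured but unprinted
  in the study).

Distributions: strictly positive rates are lognormal (mean/CV
parameterization, default CV 0.6) with a zero-inflation mass — 3/24 for
Grape and 1/24 for Citrus, reproducing the reported zero-filter counts —
and the nonzero mean inflated by 1/(1−p) so the marginal mean equals the
configured mean. Nutrients and moisture are zero-truncated normals whose
location is solved (Brent root of the truncated-mean equation) so the
post-truncation mean equals the configured mean exactly; with heavy
truncation the realized SD is accordingly smaller than the nominal one.
Bare-soil rates are 2% of biocrust rates (the reported ≈98% contrast) and
bare nutrients 40% of biocrust values. Microbial-P censoring: with
probability 0.30 a sample's P flush is drawn below the detection limit and
flagged, mechanistically reproducing the reported 30% below-detection rate.

Covariate coupling is sign-only and modest by default: the Grape rate mean
scales log-linearly with the plot's moisture anomaly (+0.15 per SD), the
Citrus mean with temperature (−0.15) and EC:EN (+0.10); anomalies are
clamped at ±4 SD and each term carries a −c²/2 centering so the coupling
is mean-preserving. These couplings reproduce the reported directional
associations without asserting effect sizes as ground truth.

GC peaks are generated by inverting the ARA forward model from the target
rate (multiplicative noise, default CV 2%) plus a small blank, so the
pipeline round-trips to the generating rates; in a fully noiseless
configuration it recovers them exactly, including the conversion factors
(2.69, 1.22) and every nutrient-table pool mean. ¹⁵N₂ assays are paired to
their plots: each assay's true N₂ rate is the plot's own mean ARA mass
rate divided by the site's true factor, with multiplicative noise scaled
to the factor's reported between-assay SD.

What passing tests do *not* show about real data: the generator has no
within-day diel rate cycle, no spatial autocorrelation between plots, no
weather time series beyond the 24-h rainfall covariate, and independent
(rather than jointly distributed) nutrient pools; the couplings are
directional stand-ins, not estimated effects. Recovery tests demonstrate
the pipeline's arithmetic and the estimator's behavior under the assumed
distributions, not the field validity of those distributions.

## Replicate calibration experiments

`simulate_calibration_campaigns` draws paired ARA/¹⁵N₂ rates with a known
true factor; the multiplicative noise CV is set analytically to
`target_sd / factor × √n` so the ratio-of-means estimator's SD matches the
reported between-assay SD (0.92 at factor 2.69, n = 3) by the delta
method. Over 1000 replicates the estimator mean recovers the generating
factor to well within 0.15.

## Numerical choices and problem sizes

- Ideal-gas constant 0.082057 L atm mol⁻¹ K⁻¹; all physical constants in
  `crustfix.constants`.
- CSVs are written with `%.17g` floats and read with round-trip parsing,
  so write→read is bit-exact; fixed seeds give byte-identical campaigns.
- Mean-recovery tests use 200 plots per site (≈ 12 800 samples), enough
  for 3-standard-error checks on every site-season cell while keeping the
  default suite and acceptance runs to seconds.
- Ties/degenerate inputs: zero-variance covariates deactivate their
  coupling term; equal fumigated/unfumigated extracts are a true zero
  pool, not a censored one; a sample equal to its blank is below
  detection; empty campaigns (`plots_per_site=0`) produce valid
  header-only tables.

## Known limitations

- The experimental conversion factors rest on 3 (Grape) and 2 (Citrus)
  paired incubations; their sampling scatter is large and the pipeline
  reports the delta-method SD so downstream users can propagate it.
- Daily and annual budgets inherit the no-dark-fixation and single
  time-point assumptions and are best read as light-hour lower bounds.
- The percent-of-annual-fertilizer quantity depends entirely on the
  user-supplied fertilizer total.
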