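# crustfix

Biological soil crusts (biocrusts) — thin communities of cyanobacteria,
algae, lichens and heterotrophs on the soil surface — fix atmospheric N₂
and can contribute meaningful nitrogen even in fertilized perennial
agroecosystems such as vineyards and citrus orchards. Quantifying that
contribution takes a chain of small but error-prone calculations: closed-jar
acetylene-reduction assays (ARA) read out on a gas chromatograph, ¹⁵N₂
enrichment incubations to calibrate the ARA signal, chloroform
fumigation–extraction for microbial biomass, and an upscaling step from
per-core hourly rates to per-hectare annual nitrogen inputs.

`crustfix` implements that chain as a tested, scriptable pipeline for soil
biogeochemists, together with a seeded synthetic field-campaign generator
that emulates a two-site (vineyard "Grape", orchard "Citrus"), four-season,
six-plot design so every stage runs and is testable without external data.

## The core calculations

**ARA quantification.** Headspace ethylene from a 138 mL jar with 10%
acetylene incubated 2 h is quantified against a single 100 ppm C₂H₄
standard and the ideal-gas molar volume, blank-corrected, and expressed as
μmol C₂H₄ m⁻² h⁻¹ (per core surface area) and nmol C₂H₄ g⁻¹ DW h⁻¹.

**¹⁵N₂ mass balance.** The fraction of biomass N derived from fixation is

```
f = (atom%₁₅N,enriched − atom%₁₅N,unenriched) / (atom%₁₅N,headspace − atom%₁₅N,unenriched)
```

and the absolute rate is `f · N_total / 14 / t` (nmol N g⁻¹ DW h⁻¹), half
of that in moles of N₂.

**Calibration.** The C₂H₄:N₂ conversion factor is the ratio of the *mean*
ARA rate to the *mean* ¹⁵N₂-derived N₂ rate over paired incubations
(ratio of means, delta-method SD), with the theoretical 3:1 stoichiometry
available as an alternative basis. N-mass rates follow as
`rate / factor × 28 / 1000` mg N m⁻² h⁻¹.

**Biomass and nutrients.** Microbial C, N, P are the fumigated-minus-
unfumigated extract flush divided by extraction efficiencies 0.37, 0.54 and
1.0; unfumigated extracts are the extractable pools. Stoichiometric ratios
are computed per sample and a ratio family is dropped when its denominator
is below detection in more than 30% of samples.

**Upscaling.** Hourly N rates × 10 light hours give daily inputs; seasonal
means × season lengths summed give kg N ha⁻¹ yr⁻¹ at 100% biocrust cover,
scaled by the 12.5% of field area available to biocrusts
(1 mg N m⁻² d⁻¹ = 10⁻² kg N ha⁻¹ d⁻¹).

## Worked example

```sh
crustfix simulate --seed 1 --out demo/campaign
crustfix run --in demo/campaign --out demo/out
```

or equivalently from Python:

```python
from crustfix import CampaignConfig, generate_campaign
from crustfix.pipeline import run_pipeline
from crustfix.io import read_table

generate_campaign(CampaignConfig(seed=1)).to_dir("demo/campaign")
run_pipeline("demo/campaign", "demo/out")
print(read_table("demo/out/conversion.csv")[0].round(3))
print(read_table("demo/out/budget.csv")[0].round(3))
```

which prints

```
  site season        basis  factor_mol_c2h4_per_mol_n2  factor_sd  n_pairs
 Grape Summer experimental                       2.358      0.971        3
Citrus   Fall experimental                       1.130      0.366        2

  site  annual_full_coverage_kg_ha_yr  annual_at_coverage_kg_ha_yr  coverage_fraction  max_daily_mg_n_m2_d  percent_of_fertilizer_application
 Grape                         46.588                        5.823              0.125               33.099                              0.827
Citrus                         63.197                        7.900              0.125               26.291                              0.657
```

The conversion factors (2.36 and 1.13 mol C₂H₄ per mol N₂ for this seed)
are estimated from only 3 and 2 paired ¹⁵N₂ incubations, so they scatter
around the generating values (2.69 and 1.22) from seed to seed. The budget
rows say that at 12.5% biocrust cover the simulated vineyard receives
≈ 5.8 kg N ha⁻¹ yr⁻¹ from biocrust fixation and the orchard ≈ 7.9, and
that the largest daily biocrust input is below 1% of a single 4 g N
fertigation dose per tree.

Intermediate tables (`rates.csv`, `fixation.csv`, `nfix_rates.csv`,
`pools.csv`, `ratios.csv`, …) are written alongside with a `# units:`
header on every file and a `manifest.json` recording per-stage row counts.

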