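"""Physical constants and assay conversion factors used across the pipeline.

Every hard-coded physical quantity in crustfix lives here so the unit chain
can be audited in one place.
"""

#: Ideal gas constant, L atm mol^-1 K^-1 (CODATA, rounded to GC practice).
R_L_ATM_PER_MOL_K = 0.082057

#: 0 degrees Celsius in kelvin.
CELSIUS_TO_KELVIN = 273.15

#: Grams of N per mole of N2 — both atoms of the fixed dinitrogen are nitrogen.
N2_G_N_PER_MOL = 28.0

#: Atomic mass of nitrogen, g mol^-1.
ATOMIC_MASS_N = 14.0

#: Natural-abundance atom% 15N of atmospheric N2 (standard atmospheric value).
AIR_ATOM_PCT_15N = 0.3663

#: Theoretical moles of C2H4 reduced per mole of N2 fixed (electron-pair
#: stoichiometry: 2e- per C2H2 -> C2H4 vs 6e- per N2 -> 2NH3).
THEORETICAL_C2H4_N2_RATIO = 3.0

#: Chloroform fumigation-extraction efficiency factors: the microbial pool is
#: the fumigated-minus-unfumigated flush divided by these (no adjustment for P).
FUMIGATION_EFFICIENCY = {"C": 0.37, "N": 0.54, "P": 1.0}

#: 1 mg N m^-2 d^-1 equals 0.01 kg N ha^-1 d^-1 (1 ha = 1e4 m^2, 1 kg = 1e6 mg).
MG_M2_DAY_TO_KG_HA_DAY = 1e-2
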