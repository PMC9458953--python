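"""Physical constants and unit-conversion factors shared across the package."""

#: Universal gas constant, J/(K.mol).
R_GAS = 8.314

#: Molar masses, g/mol.
MW_SULPHATE = 96.06   # SO4^2-
MW_SULPHUR = 32.06    # elemental S
MW_LACTATE = 90.08
MW_ACETATE = 60.05
MW_PROPIONATE = 74.08

#: Chemical oxygen demand of the electron donors, g O2 per mol.
#: Lactate: C3H6O3 + 3 O2 -> 3 CO2 + 3 H2O; acetate: C2H4O2 + 2 O2 -> 2 CO2 + 2 H2O.
COD_G_O2_PER_MOL = {"lactate": 96.0, "acetate": 64.0}

#: Bulk-volume sampling ports and the effluent port label.
PORTS = ("P1", "P2", "P3", "P4")
EFFLUENT = "effluent"

#: Default dry-mass composition of the harvested floating sulphur biofilm
#: (mass fractions; the remainder is the inorganic mineral fraction).
FILM_COMPOSITION = {"C": 0.10, "H": 0.02, "N": 0.03, "S": 0.29}

CELSIUS_OFFSET = 273.15
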