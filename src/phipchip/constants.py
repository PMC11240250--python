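"""Physical constants and literature parameter values used across the package.

Every number here is either a CODATA fundamental constant or a literature
solubility/transport value for the chip's working fluids; the provenance is
recorded next to each entry so that any of them can be swapped for a better
measurement without touching model code.
"""

# --- fundamental constants (CODATA 2018) ---
HBAR = 1.054571817e-34  # J s
K_BOLTZMANN = 1.380649e-23  # J/K

#: Gyromagnetic ratios, rad s^-1 T^-1 (CODATA 2018 for 1H; 13C from the
#: shielded-proton ratio gamma_C/gamma_H = 0.2514804 applied to gamma_H).
GYROMAGNETIC_RATIO = {
    "1H": 2.6752218744e8,
    "13C": 6.728284e7,
}

# --- solvent / membrane transport values for H2 at ~298 K ---

#: Henry-law solubility of H2 in methanol, mM per bar of H2 partial pressure.
#: From the IUPAC solubility series mole fraction x ~= 1.6e-4 at 1.013 bar and
#: 298 K, times the molar density of methanol (24.5 mol/L).
HENRY_H2_METHANOL_MM_PER_BAR = 3.96

#: Effective diffusivity of H2 in liquid methanol, m^2/s (order of magnitude
#: from Stokes-Einstein scaling of the aqueous value with methanol viscosity).
DIFFUSIVITY_H2_METHANOL = 5.0e-9

#: Diffusivity of H2 in PDMS, m^2/s. Silicones are highly hydrogen-permeable;
#: literature values cluster around 1e-8.
DIFFUSIVITY_H2_PDMS = 1.4e-8

#: Equilibrium solubility of H2 in PDMS relative to the adjacent liquid
#: (dimensionless concentration partition coefficient, order unity).
PARTITION_H2_PDMS_LIQUID = 0.5
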