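"""Exact unit-conversion constants.

Every conversion between the internal units (mg, h, cm3/mm3, m/um) and the
particle-count scale goes through this table so that per-segment flux numbers
are pure unit arithmetic on simulation output and cannot drift between
modules.
"""

AVOGADRO = 6.02214076e23  # molecules per mol (exact, SI 2019)

G_PER_MG = 1e-3
S_PER_H = 3600.0
MM3_PER_CM3 = 1000.0
M_PER_MM = 1e-3
M_PER_UM = 1e-6


def mg_to_molecules(amount_mg: float, molar_mass_g_per_mol: float) -> float:
    """Convert a drug amount in mg to a molecule count."""
    return amount_mg * G_PER_MG / molar_mass_g_per_mol * AVOGADRO


def molecules_to_mg(count: float, molar_mass_g_per_mol: float) -> float:
    return count / AVOGADRO * molar_mass_g_per_mol / G_PER_MG
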