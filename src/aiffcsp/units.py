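"""Unit conventions and physical constants.

All energies are in kJ/mol, distances in Angstrom, charges in elementary
charges, masses in amu.  The Coulomb prefactor ``KC`` converts
q_a*q_b/r (e^2/Angstrom) to kJ/mol.
"""

# Coulomb constant, kJ mol^-1 Angstrom e^-2
KC = 1389.35458

# Avogadro constant, mol^-1
N_AVOGADRO = 6.02214076e23

ATOMIC_MASSES = {
    "H": 1.008, "He": 4.0026, "Li": 6.94, "Be": 9.0122, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.948, "K": 39.098, "Ca": 40.078,
    "Br": 79.904, "I": 126.904, "Cs": 132.905,
}

# covalent radii (Angstrom), used for bond perception when reassembling
# molecules from crystallographic atom sites
COVALENT_RADII = {
    "H": 0.31, "He": 0.28, "Li": 1.28, "Be": 0.96, "B": 0.84,
    "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57, "Ne": 0.58,
    "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11, "P": 1.07,
    "S": 1.05, "Cl": 1.02, "Ar": 1.06, "K": 2.03, "Ca": 1.76,
    "Br": 1.20, "I": 1.39, "Cs": 2.44,
}

# van der Waals radii (Angstrom), used for contact-distance heuristics
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "Na": 2.27, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
    "Cs": 3.43,
}


def mass_of(element: str) -> float:
    try:
        return ATOMIC_MASSES[element]
    except KeyError:
        raise KeyError(f"no tabulated atomic mass for element {element!r}")
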