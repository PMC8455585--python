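"""Physical constants and per-element parameter tables.

All coordinates and radii are in Angstrom, energies in kcal/mol, charges in
elementary charge units.  The tables below are deliberately small: they cover
the organic elements that occur in kinase-inhibitor chemistry plus the
pseudo-atoms used by the synthetic generators.
"""

from __future__ import annotations

#: Coulomb conversion factor, kcal/mol * Angstrom / e^2 (Amber convention).
COULOMB_CONSTANT = 332.0637

#: Boltzmann constant in kcal/mol/K.
KBOLTZ = 0.0019872041

#: Solvent (water) relative dielectric used by the generalized Born model.
SOLVENT_DIELECTRIC = 78.5

#: Nonpolar solvation coefficient, kcal/mol per Angstrom^2 of buried SASA.
NONPOLAR_COEFFICIENT = 0.0072

#: Water probe radius for solvent-accessible surface area.
SASA_PROBE_RADIUS = 1.4

#: Bondi-style van der Waals radii (Angstrom).
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Br": 1.85,
    "I": 1.98,
    # single-site water pseudo-atom and generic dummy used by toy systems
    "W": 1.60,
    "X": 1.70,
}

#: Lennard-Jones well depths (kcal/mol) for the same elements.  Values follow
#: common force-field magnitudes; the molecular-field probe only needs an
#: order-of-magnitude realistic dispersion term.
LJ_EPSILON = {
    "H": 0.016,
    "C": 0.107,
    "N": 0.095,
    "O": 0.116,
    "F": 0.061,
    "P": 0.200,
    "S": 0.250,
    "Cl": 0.265,
    "Br": 0.320,
    "I": 0.400,
    "W": 0.155,
    "X": 0.107,
}

#: sp3-carbon probe used for the steric/electrostatic molecular fields.
PROBE_CHARGE = 1.0
PROBE_LJ_RADIUS = 1.7
PROBE_LJ_EPSILON = 0.107

#: Gaussian attenuation factor (1/Angstrom^2) for the similarity-index fields.
COMSIA_ALPHA = 0.3

#: Steric field cap, kcal/mol.
STERIC_CAP = 30.0

#: Charge magnitude above which a C/S/halogen atom stops counting as
#: hydrophobic.
HYDROPHOBIC_CHARGE_CUTOFF = 0.2

HALOGENS = {"F", "Cl", "Br", "I"}

#: Elements that can act as H-bond acceptors (lone-pair bearing).
ACCEPTOR_ELEMENTS = {"N", "O"}

#: Heavy elements that can carry a donatable hydrogen.
DONOR_PARENT_ELEMENTS = {"N", "O", "S"}

#: Covalent X-H bond cutoff used when inferring connectivity (Angstrom).
H_BOND_LENGTH_CUTOFF = 1.25

#: Heavy-atom covalent bond cutoff for distance-based connectivity.
HEAVY_BOND_CUTOFF = 1.85


def vdw_radius(element: str) -> float:
    try:
        return VDW_RADII[element]
    except KeyError:
        raise KeyError(f"no van der Waals radius tabulated for element {element!r}")


def lj_epsilon(element: str) -> float:
    try:
        return LJ_EPSILON[element]
    except KeyError:
        raise KeyError(f"no Lennard-Jones well depth tabulated for element {element!r}")
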