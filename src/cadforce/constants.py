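"""Physical constants and lookup tables used across the package.

Units follow AFM/MD practice: forces in pN, AFM lengths in nm, atomic
coordinates and radii in Å, temperatures in K, masses in Da.
"""

from __future__ import annotations

#: Boltzmann constant in pN·nm/K (1.380649e-23 J/K expressed in pN·nm).
KB_PN_NM_PER_K: float = 1.380649e-2

#: Avogadro constant, 1/mol.
AVOGADRO: float = 6.02214076e23

#: Conversion factor from kJ·mol⁻¹·nm⁻¹ to pN.
#: 1 kJ/mol = 1e3 J / N_A per molecule; dividing by 1 nm = 1e-9 m gives
#: 1.66054e-12 N = 1.66054 pN.
KJ_PER_MOL_NM_TO_PN: float = 1e3 / AVOGADRO / 1e-9 * 1e12

#: Default laboratory temperature (K); kB·T = 4.114 pN·nm at 298 K.
DEFAULT_TEMPERATURE_K: float = 298.0


def kbt(temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """Thermal energy kB·T in pN·nm at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_PN_NM_PER_K * temperature


#: Bondi van der Waals radii (Å) by element symbol.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
    "NA": 2.27,
    "K": 2.75,
    "MG": 1.73,
    "CA": 2.31,
    "ZN": 1.39,
}

#: Standard atomic masses (Da) by element symbol.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "P": 30.974,
    "S": 32.06,
    "CL": 35.45,
    "BR": 79.904,
    "I": 126.904,
    "SE": 78.971,
    "NA": 22.990,
    "K": 39.098,
    "MG": 24.305,
    "CA": 40.078,
    "ZN": 65.38,
}

#: Side-chain atoms carrying the formal charge, by residue name.  Used for
#: salt-bridge distance traces; configurable at call sites.
CHARGED_ATOMS: dict[str, tuple[str, ...]] = {
    "GLU": ("OE1", "OE2"),
    "ASP": ("OD1", "OD2"),
    "LYS": ("NZ",),
    "ARG": ("NH1", "NH2", "NE"),
    "HIS": ("ND1", "NE2"),
}

#: Residues lining the hydrophobic anchor pocket of the cadherin EC1 domain
#: that receives the partner's Trp2 side chain (mature-protein numbering).
POCKET_RESIDUES: tuple[int, ...] = tuple(range(22, 29)) + (36,) + tuple(
    range(78, 81)
) + tuple(range(89, 93))
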