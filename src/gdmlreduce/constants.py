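"""Physical constants and unit bridges.

Canonical internal units: Å (length), kcal mol⁻¹ (energy),
kcal (mol Å)⁻¹ (force), fs (time), K (temperature), amu (mass),
elementary charge e (charge).
"""

# CODATA-derived base quantities
AVOGADRO = 6.02214076e23  # mol⁻¹ (exact, SI 2019)
CAL_TO_J = 4.184  # thermochemical calorie, J

#: Boltzmann constant, kcal mol⁻¹ K⁻¹
KB = 1.380649e-23 * AVOGADRO / (CAL_TO_J * 1000.0)

#: 1 kcal mol⁻¹ Å⁻¹ expressed in piconewton (computed, ≈69.477)
KCAL_MOL_ANG_TO_PN = CAL_TO_J * 1000.0 / AVOGADRO / 1.0e-10 * 1.0e12

#: Coulomb prefactor, kcal mol⁻¹ Å e⁻² (standard biomolecular convention)
COULOMB_CONSTANT = 332.06

#: acceleration factor: F [kcal mol⁻¹ Å⁻¹] / m [amu] × ACC_FACTOR = a [Å fs⁻²];
#: its inverse converts ½ m v² [amu Å² fs⁻²] to kcal mol⁻¹
ACC_FACTOR = CAL_TO_J * 1000.0 * 1.0e-7 / 1.0e3  # = 4.184e-4

#: 1 eV in kcal mol⁻¹
EV_TO_KCAL_MOL = 23.060548

#: standard atomic weights (amu) keyed by atomic number; beads may override
ATOMIC_MASSES = {
    1: 1.008, 2: 4.0026, 3: 6.94, 5: 10.81, 6: 12.011, 7: 14.007,
    8: 15.999, 9: 18.998, 11: 22.990, 12: 24.305, 15: 30.974,
    16: 32.06, 17: 35.45, 19: 39.098, 20: 40.078, 35: 79.904, 53: 126.90,
}

ATOMIC_SYMBOLS = {
    1: "H", 2: "He", 3: "Li", 5: "B", 6: "C", 7: "N", 8: "O", 9: "F",
    11: "Na", 12: "Mg", 15: "P", 16: "S", 17: "Cl", 19: "K", 20: "Ca",
    35: "Br", 53: "I",
}
SYMBOL_TO_Z = {v: k for k, v in ATOMIC_SYMBOLS.items()}


def mass_of(z: int) -> float:
    """Standard atomic weight for atomic number ``z`` (amu)."""
    try:
        return ATOMIC_MASSES[int(z)]
    except KeyError:
        raise KeyError(f"no tabulated mass for atomic number {z}") from None
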