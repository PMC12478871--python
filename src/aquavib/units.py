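"""Unit system and conversion constants.

All internal computation is done in Hartree atomic units (hbar = 1, mass in
electron masses, length in bohr, energy in hartree, imaginary time in inverse
hartree).  I/O uses the conventional chemistry units: Å for coordinates,
amu for masses, kcal/mol for potential parameters, cm^-1 for frequencies.
Constants are taken from scipy (CODATA) so the conversions are reproducible.
"""

from __future__ import annotations

import scipy.constants as _c

#: bohr radius in Å
BOHR_TO_ANGSTROM = _c.value("Bohr radius") * 1e10
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM

#: one hartree in J
HARTREE_J = _c.value("Hartree energy")

#: thermochemical kcal/mol in hartree
KCALMOL_TO_HARTREE = (_c.calorie * 1000.0 / _c.Avogadro) / HARTREE_J
HARTREE_TO_KCALMOL = 1.0 / KCALMOL_TO_HARTREE

#: atomic mass unit in electron masses
AMU_TO_ME = _c.value("atomic mass constant") / _c.value("electron mass")

#: hartree expressed as a spectroscopic wavenumber (cm^-1)
HARTREE_TO_WAVENUMBER = _c.value("hartree-inverse meter relationship") / 100.0
WAVENUMBER_TO_HARTREE = 1.0 / HARTREE_TO_WAVENUMBER

#: Boltzmann constant in hartree/K (for the Metropolis isomer search)
KB_HARTREE = _c.Boltzmann / HARTREE_J

#: standard atomic weights, amu (not isotopic masses)
ATOMIC_WEIGHTS = {"H": 1.008, "O": 15.999}


def angular_frequency_to_wavenumber(omega_au: float) -> float:
    """Convert an angular frequency in atomic units to cm^-1 (nu~ = hbar*omega/hc)."""
    return omega_au * HARTREE_TO_WAVENUMBER
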