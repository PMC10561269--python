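"""Physical constants and isotope masses.

Everything inside the package runs in Hartree atomic units
(bohr, hartree, electron mass, hbar = 1); the conversions here are applied
only at I/O boundaries (XYZ files in angstrom, spectra in cm^-1, protocol
times quoted in fs).
"""

from __future__ import annotations

#: bohr per angstrom (CODATA 2018)
BOHR_PER_ANGSTROM = 1.8897259886

#: 1 cm^-1 expressed in hartree
HARTREE_PER_INV_CM = 4.556335252912088e-6

#: 1 hartree expressed in cm^-1
INV_CM_PER_HARTREE = 1.0 / HARTREE_PER_INV_CM

#: 1 atomic unit of time expressed in femtoseconds
FS_PER_AU_TIME = 2.4188843265857e-2

#: 1 unified atomic mass unit (dalton) in electron masses
ME_PER_AMU = 1822.888486209


class UnknownIsotopeError(KeyError):
    """Raised when an isotope tag has no entry in the bundled mass table."""


# Atomic masses in dalton (AME2020 / CODATA). A bare element symbol refers to
# the most abundant isotope; explicit tags select specific isotopes.
ISOTOPE_MASSES_AMU: dict[str, float] = {
    "H": 1.00782503207,
    "1H": 1.00782503207,
    "D": 2.01410177785,
    "2H": 2.01410177785,
    "T": 3.0160492779,
    "3H": 3.0160492779,
    "He": 4.002603254,
    "B": 11.009305,
    "C": 12.0,
    "12C": 12.0,
    "13C": 13.0033548352,
    "N": 14.0030740048,
    "14N": 14.0030740048,
    "15N": 15.0001088989,
    "O": 15.9949146196,
    "16O": 15.9949146196,
    "17O": 16.9991317565,
    "18O": 17.9991596129,
    "F": 18.9984031627,
    "Na": 22.9897692820,
    "P": 30.9737619984,
    "S": 31.9720711744,
    "Cl": 34.968852682,
    "35Cl": 34.968852682,
    "37Cl": 36.965902602,
    "Br": 78.9183376,
    "I": 126.9044719,
}


def isotope_mass(tag: str) -> float:
    """Mass of isotope ``tag`` in atomic units (electron masses).

    Raises :class:`UnknownIsotopeError` naming the tag if it is not in the
    bundled table.
    """
    try:
        return ISOTOPE_MASSES_AMU[tag] * ME_PER_AMU
    except KeyError:
        raise UnknownIsotopeError(
            f"unknown isotope tag {tag!r}; known tags: "
            + ", ".join(sorted(ISOTOPE_MASSES_AMU))
        ) from None
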