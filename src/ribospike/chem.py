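"""Elemental compositions and monoisotopic masses for peptides.

All atomic constants are embedded here (CODATA/IUPAC values to >= 6
decimals) so that mass arithmetic is reproducible without reference to
any external library.  Residue compositions are the 20 canonical amino
acid *residues* (i.e. minus one water); a peptide is the residue sum
plus one water, plus fixed modifications.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "Composition",
    "ELEMENTS",
    "MONOISOTOPIC",
    "ISOTOPES",
    "RESIDUES",
    "WATER",
    "CARBAMIDOMETHYL",
    "PROTON_MASS",
    "peptide_composition",
    "monoisotopic_mass",
]

ELEMENTS = ("C", "H", "N", "O", "S")

#: monoisotopic mass of the lightest isotope of each element, Da
MONOISOTOPIC = {
    "C": 12.000000,
    "H": 1.007825,
    "N": 14.003074,
    "O": 15.994915,
    "S": 31.972071,
}

#: natural isotope distributions: element -> ((mass, abundance), ...),
#: ordered by mass.  Abundances are IUPAC representative values.
ISOTOPES = {
    "C": ((12.000000, 0.9893), (13.003355, 0.0107)),
    "H": ((1.007825, 0.999885), (2.014102, 0.000115)),
    "N": ((14.003074, 0.99636), (15.000109, 0.00364)),
    "O": ((15.994915, 0.99757), (16.999132, 0.00038), (17.999160, 0.00205)),
    "S": (
        (31.972071, 0.9499),
        (32.971459, 0.0075),
        (33.967867, 0.0425),
        (35.967081, 0.0001),
    ),
}

PROTON_MASS = 1.007276

#: natural abundance of 15N, used as the enrichment of the unlabeled channel
NATURAL_15N = 0.00364

#: 15N - 14N mass difference, Da (one unit of the nitrogen mass shift)
N15_MASS_SHIFT = 15.000109 - 14.003074


@dataclass(frozen=True)
class Composition:
    """Counts of C, H, N, O, S atoms; immutable and hashable.

    Supports addition and subtraction (closed over non-negative counts;
    subtraction below zero raises).
    """

    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    S: int = 0

    def __post_init__(self) -> None:
        for el in ELEMENTS:
            v = getattr(self, el)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"element count {el}={v!r} must be a non-negative integer")

    def __add__(self, other: "Composition") -> "Composition":
        return Composition(*(getattr(self, e) + getattr(other, e) for e in ELEMENTS))

    def __sub__(self, other: "Composition") -> "Composition":
        return Composition(*(getattr(self, e) - getattr(other, e) for e in ELEMENTS))

    def __mul__(self, n: int) -> "Composition":
        return Composition(*(getattr(self, e) * n for e in ELEMENTS))

    __rmul__ = __mul__

    @property
    def total_atoms(self) -> int:
        return sum(getattr(self, e) for e in ELEMENTS)

    def monoisotopic_mass(self) -> float:
        return sum(getattr(self, e) * MONOISOTOPIC[e] for e in ELEMENTS)

    def hill_formula(self) -> str:
        """Formula string in Hill order (C, H, then alphabetical)."""
        parts = []
        for el in ("C", "H", "N", "O", "S"):
            n = getattr(self, el)
            if n == 1:
                parts.append(el)
            elif n > 1:
                parts.append(f"{el}{n}")
        return "".join(parts)


WATER = Composition(H=2, O=1)

#: carbamidomethylation adduct on cysteine (iodoacetamide alkylation)
CARBAMIDOMETHYL = Composition(C=2, H=3, N=1, O=1)

#: canonical amino-acid residue compositions (peptide-bond residues, no water)
RESIDUES = {
    "G": Composition(C=2, H=3, N=1, O=1),
    "A": Composition(C=3, H=5, N=1, O=1),
    "S": Composition(C=3, H=5, N=1, O=2),
    "P": Composition(C=5, H=7, N=1, O=1),
    "V": Composition(C=5, H=9, N=1, O=1),
    "T": Composition(C=4, H=7, N=1, O=2),
    "C": Composition(C=3, H=5, N=1, O=1, S=1),
    "L": Composition(C=6, H=11, N=1, O=1),
    "I": Composition(C=6, H=11, N=1, O=1),
    "N": Composition(C=4, H=6, N=2, O=2),
    "D": Composition(C=4, H=5, N=1, O=3),
    "Q": Composition(C=5, H=8, N=2, O=2),
    "K": Composition(C=6, H=12, N=2, O=1),
    "E": Composition(C=5, H=7, N=1, O=3),
    "M": Composition(C=5, H=9, N=1, O=1, S=1),
    "H": Composition(C=6, H=7, N=3, O=1),
    "F": Composition(C=9, H=9, N=1, O=1),
    "R": Composition(C=6, H=12, N=4, O=1),
    "Y": Composition(C=9, H=9, N=1, O=2),
    "W": Composition(C=11, H=10, N=2, O=1),
}

CANONICAL_RESIDUES = frozenset(RESIDUES)


def peptide_composition(sequence: str, carbamidomethyl: bool = True) -> Composition:
    """Elemental composition of a peptide: residue sum + one water.

    With ``carbamidomethyl`` (the default, matching iodoacetamide
    alkylation during sample preparation) every cysteine gains C2H3NO.
    Raises ``ValueError`` on an empty sequence or unknown residue.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    total = WATER
    for i, aa in enumerate(sequence):
        try:
            total = total + RESIDUES[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r} at position {i} in {sequence!r}") from None
        if carbamidomethyl and aa == "C":
            total = total + CARBAMIDOMETHYL
    return total


def monoisotopic_mass(composition: Composition) -> float:
    """Monoisotopic (all-lightest-isotope) mass of a composition, Da."""
    return composition.monoisotopic_mass()
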