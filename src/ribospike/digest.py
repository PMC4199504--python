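"""In-silico tryptic digestion and the unique-peptide index.

Builds the theoretical digest used to assign observed isotope-envelope
pairs to peptides: proteins are cleaved with trypsin specificity
(after K/R, suppressed before P), peptides carrying up to a configured
number of missed cleavages are enumerated, and any peptide sequence
shared between two proteins is flagged non-unique and excluded from
quantitation.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO

from .chem import CANONICAL_RESIDUES, Composition, peptide_composition

__all__ = [
    "ProteinRecord",
    "PeptideSpecies",
    "PeptideIndex",
    "parse_fasta",
    "cleavage_fragments",
    "tryptic_digest",
    "build_unique_peptide_index",
]

DEFAULT_MAX_MISSED = 1
DEFAULT_MIN_LENGTH = 6
DEFAULT_MAX_LENGTH = 30


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identified by a short name (e.g. ``"L20"``)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"protein {self.id}: empty sequence")
        for i, aa in enumerate(self.sequence):
            if aa not in CANONICAL_RESIDUES:
                raise ValueError(
                    f"protein {self.id}: non-canonical residue {aa!r} at position {i + 1}"
                )


@dataclass(frozen=True)
class PeptideSpecies:
    """One tryptic peptide of one protein, with fixed mods applied."""

    sequence: str
    protein_id: str
    missed_cleavages: int
    composition: Composition
    monoisotopic_mass: float
    is_unique: bool = True


def parse_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record FASTA into validated :class:`ProteinRecord` s.

    The header token before the first whitespace becomes the protein id;
    sequences are uppercased.  Duplicate ids and non-canonical residues
    raise ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    stripped = text.lstrip()
    if stripped and not stripped.startswith(">"):
        offending = stripped.splitlines()[0]
        raise ValueError(f"malformed FASTA {path}: expected '>' header, got {offending!r}")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if pid in seen:
            raise ValueError(f"duplicate protein id {pid!r} in {path}")
        seen.add(pid)
        records.append(ProteinRecord(id=pid, sequence=str(rec.seq).upper()))
    return records


def cleavage_sites(sequence: str) -> list[int]:
    """Indices after which trypsin cuts: after K/R unless followed by P."""
    return [
        i + 1
        for i, aa in enumerate(sequence[:-1])
        if aa in "KR" and sequence[i + 1] != "P"
    ]


def cleavage_fragments(sequence: str) -> list[str]:
    """Fully cleaved (0 missed cleavages) fragments, unfiltered.

    Concatenating the result reconstructs ``sequence`` exactly.
    """
    cuts = [0, *cleavage_sites(sequence), len(sequence)]
    return [sequence[a:b] for a, b in zip(cuts, cuts[1:])]


def tryptic_digest(
    protein: ProteinRecord,
    max_missed: int = DEFAULT_MAX_MISSED,
    min_length: int = DEFAULT_MIN_LENGTH,
    max_length: int = DEFAULT_MAX_LENGTH,
    carbamidomethyl: bool = True,
) -> list[PeptideSpecies]:
    """Enumerate tryptic peptides with 0..max_missed missed cleavages.

    Peptides outside [min_length, max_length] residues are dropped
    (typical detectability window of a TOF instrument).  Order follows
    position in the protein, then missed-cleavage count.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    frags = cleavage_fragments(protein.sequence)
    peptides: list[PeptideSpecies] = []
    for start in range(len(frags)):
        for mc in range(min(max_missed, len(frags) - start - 1) + 1):
            seq = "".join(frags[start : start + mc + 1])
            if not (min_length <= len(seq) <= max_length):
                continue
            comp = peptide_composition(seq, carbamidomethyl=carbamidomethyl)
            peptides.append(
                PeptideSpecies(
                    sequence=seq,
                    protein_id=protein.id,
                    missed_cleavages=mc,
                    composition=comp,
                    monoisotopic_mass=comp.monoisotopic_mass(),
                )
            )
    return peptides


class PeptideIndex:
    """Mass-searchable index of theoretical peptides from a protein set.

    Peptide sequences occurring in more than one protein are retained
    for audit but flagged ``is_unique=False`` and excluded from the
    quantitation set (:attr:`unique_peptides`).
    """

    def __init__(self, peptides: Sequence[PeptideSpecies]):
        self.peptides = list(peptides)
        self._unique = [p for p in self.peptides if p.is_unique]
        self._unique.sort(key=lambda p: p.monoisotopic_mass)
        self._masses = [p.monoisotopic_mass for p in self._unique]

    @property
    def unique_peptides(self) -> list[PeptideSpecies]:
        return list(self._unique)

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self) -> Iterator[PeptideSpecies]:
        return iter(self.peptides)

    def lookup_mass_window(self, mass: float, ppm: float) -> list[PeptideSpecies]:
        """Unique peptides whose monoisotopic mass is within ±ppm of mass."""
        delta = mass * ppm * 1e-6
        lo = bisect.bisect_left(self._masses, mass - delta)
        hi = bisect.bisect_right(self._masses, mass + delta)
        return self._unique[lo:hi]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_id": [p.protein_id for p in self.peptides],
                "sequence": [p.sequence for p in self.peptides],
                "missed_cleavages": [p.missed_cleavages for p in self.peptides],
                "composition": [p.composition.hill_formula() for p in self.peptides],
                "monoisotopic_mass": [p.monoisotopic_mass for p in self.peptides],
                "is_unique": [p.is_unique for p in self.peptides],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def build_unique_peptide_index(
    proteins: Iterable[ProteinRecord],
    max_missed: int = DEFAULT_MAX_MISSED,
    min_length: int = DEFAULT_MIN_LENGTH,
    max_length: int = DEFAULT_MAX_LENGTH,
    carbamidomethyl: bool = True,
) -> PeptideIndex:
    """Digest all proteins and flag cross-protein shared peptides non-unique.

    The outcome is independent of the input protein order (uniqueness is
    a set property of the peptide sequences).
    """
    proteins = list(proteins)
    if not proteins:
        raise ValueError("empty protein list")
    ids = [p.id for p in proteins]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein ids in proteome")
    all_peps: list[PeptideSpecies] = []
    seen_pairs: set[tuple[str, str]] = set()
    for prot in proteins:
        for pep in (
            tryptic_digest(
                prot,
                max_missed=max_missed,
                min_length=min_length,
                max_length=max_length,
                carbamidomethyl=carbamidomethyl,
            )
        ):
            # a repeated sequence within one protein is one species
            key = (prot.id, pep.sequence)
            if key not in seen_pairs:
                seen_pairs.add(key)
                all_peps.append(pep)
    owners: dict[str, set[str]] = {}
    for p in all_peps:
        owners.setdefault(p.sequence, set()).add(p.protein_id)
    flagged = [
        p if len(owners[p.sequence]) == 1
        else PeptideSpecies(
            sequence=p.sequence,
            protein_id=p.protein_id,
            missed_cleavages=p.missed_cleavages,
            composition=p.composition,
            monoisotopic_mass=p.monoisotopic_mass,
            is_unique=False,
        )
        for p in all_peps
    ]
    return PeptideIndex(flagged)
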