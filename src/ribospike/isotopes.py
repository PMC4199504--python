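"""Isotopologue distributions for peptides under 14N and 15N labeling.

The isotope envelope of a peptide is the distribution of its total
neutral mass over isotopologues.  It is computed by convolving the
per-atom isotope distributions of all atoms in the elemental
composition on a nominal-mass-offset grid (integer Da relative to the
all-lightest-isotope configuration), aggregating isotopologues that
share a nominal offset into one centroid at the abundance-weighted
mean mass.  This matches the granularity of centroided TOF data, where
fine structure within one nominal bin is never resolved.

Metabolic 15N labeling is modeled by replacing the nitrogen per-atom
distribution with {14N: 1 - enrichment, 15N: enrichment}; all other
elements keep natural abundances (the carbon/oxygen/sulfur pools of
the labeled culture are unenriched).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import ELEMENTS, ISOTOPES, NATURAL_15N, PROTON_MASS, Composition

__all__ = [
    "LabelingState",
    "IsotopePattern",
    "element_distribution",
    "isotope_pattern",
    "pattern_to_mz",
]

DEFAULT_PRUNE = 1e-4


@dataclass(frozen=True)
class LabelingState:
    """Isotope channel of a sample: natural abundance or 15N-enriched.

    ``enrichment`` is the fraction of nitrogen atoms that are 15N.  For
    the natural channel it is pinned to the natural 15N abundance.
    """

    kind: str  # "natural" | "nitrogen15"
    enrichment: float

    def __post_init__(self) -> None:
        if self.kind not in ("natural", "nitrogen15"):
            raise ValueError(f"unknown labeling kind {self.kind!r}")
        if not 0.0 <= self.enrichment <= 1.0:
            raise ValueError(f"enrichment {self.enrichment} outside [0, 1]")

    @classmethod
    def natural(cls) -> "LabelingState":
        return cls(kind="natural", enrichment=NATURAL_15N)

    @classmethod
    def nitrogen15(cls, enrichment: float) -> "LabelingState":
        return cls(kind="nitrogen15", enrichment=enrichment)


@dataclass(frozen=True)
class IsotopePattern:
    """Normalized isotope envelope: centroid (neutral mass, abundance) pairs."""

    masses: tuple[float, ...]
    abundances: tuple[float, ...]
    label: LabelingState
    composition: Composition

    def __post_init__(self) -> None:
        if len(self.masses) != len(self.abundances):
            raise ValueError("masses and abundances length mismatch")

    def __len__(self) -> int:
        return len(self.masses)

    @property
    def base_peak_mass(self) -> float:
        return self.masses[int(np.argmax(self.abundances))]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mass": self.masses,
                "abundance": self.abundances,
                "label": self.label.kind,
                "formula": self.composition.hill_formula(),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def element_distribution(element: str, label: LabelingState) -> list[tuple[float, float]]:
    """Per-atom (mass, probability) distribution of one element.

    Under ``nitrogen15`` labeling only nitrogen is altered; every other
    element keeps its natural distribution.
    """
    if element not in ISOTOPES:
        raise ValueError(f"unknown element {element!r}")
    if element == "N":
        e = label.enrichment if label.kind == "nitrogen15" else NATURAL_15N
        n14, n15 = ISOTOPES["N"][0][0], ISOTOPES["N"][1][0]
        return [(n14, 1.0 - e), (n15, e)]
    return [(m, p) for m, p in ISOTOPES[element]]


def _atom_grid(dist: list[tuple[float, float]]) -> tuple[np.ndarray, np.ndarray]:
    """One atom's distribution on the nominal-offset grid: (P, P*mass)."""
    base = dist[0][0]
    offsets = [round(m - base) for m, _ in dist]
    size = max(offsets) + 1
    prob = np.zeros(size)
    wmass = np.zeros(size)
    for (m, p), k in zip(dist, offsets):
        prob[k] += p
        wmass[k] += p * m
    return prob, wmass


def _convolve(a: tuple[np.ndarray, np.ndarray], b: tuple[np.ndarray, np.ndarray]):
    pa, ma = a
    pb, mb = b
    prob = np.convolve(pa, pb)
    wmass = np.convolve(ma, pb) + np.convolve(pa, mb)
    # drop a negligible tail to bound envelope length
    keep = np.nonzero(prob > 1e-15)[0]
    if keep.size and keep[-1] + 1 < prob.size:
        prob = prob[: keep[-1] + 1]
        wmass = wmass[: keep[-1] + 1]
    return prob, wmass


def _atom_power(dist: list[tuple[float, float]], n: int):
    """n-fold self-convolution by exponentiation-by-squaring."""
    result = None
    sq = _atom_grid(dist)
    while n > 0:
        if n & 1:
            result = sq if result is None else _convolve(result, sq)
        n >>= 1
        if n:
            sq = _convolve(sq, sq)
    return result


@lru_cache(maxsize=4096)
def _pattern_cached(composition: Composition, label: LabelingState, prune: float):
    acc = None
    for el in ELEMENTS:
        n = getattr(composition, el)
        if n == 0:
            continue
        grid = _atom_power(element_distribution(el, label), n)
        acc = grid if acc is None else _convolve(acc, grid)
    if acc is None:
        raise ValueError("empty composition has no isotope pattern")
    prob, wmass = acc
    nz = prob > 0
    masses = np.where(nz, wmass, 0.0)
    masses[nz] /= prob[nz]
    keep = (prob > 0) & (prob >= prune * prob.max())
    prob = prob[keep]
    masses = masses[keep]
    prob = prob / prob.sum()
    return tuple(masses.tolist()), tuple(prob.tolist())


def isotope_pattern(
    composition: Composition,
    label: LabelingState,
    prune: float = DEFAULT_PRUNE,
) -> IsotopePattern:
    """Envelope of a composition under a labeling state.

    Peaks below ``prune`` (relative to the base peak) are dropped and
    the remaining abundances renormalized to sum to 1.
    """
    if not 0.0 <= prune < 0.01:
        raise ValueError("prune must be in [0, 0.01)")
    if composition.total_atoms == 0:
        raise ValueError("empty composition has no isotope pattern")
    masses, abund = _pattern_cached(composition, label, prune)
    return IsotopePattern(masses=masses, abundances=abund, label=label, composition=composition)


def pattern_to_mz(pattern: IsotopePattern, charge: int) -> list[tuple[float, float]]:
    """Project a neutral-mass envelope to m/z for a protonated ion.

    m/z = (M + z * m_proton) / z; abundances are unchanged.
    """
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return [
        ((m + charge * PROTON_MASS) / charge, a)
        for m, a in zip(pattern.masses, pattern.abundances)
    ]
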