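"""Synthetic centroided MS1 spectra for double-spike mixture designs.

Emulates the measurement design in which each 14N-labeled experimental
sample (20 pmol of purified particles) is mixed with a "double spike"
internal reference of 10 pmol 14N- plus 30 pmol 15N-labeled mature 70S
ribosomes before digestion and ESI-TOF analysis.  Every detectable
tryptic peptide then appears as a natural-abundance 14N envelope whose
generating amplitude is proportional to

    experimental_pmol x occupancy(protein) + spike14_pmol

and a mass-shifted 15N-enriched envelope proportional to spike15_pmol.
The simulator emits one summed centroid spectrum per sample (no
chromatographic dimension: quantitation operates per peptide on
envelope amplitudes, so retention time adds nothing testable here).

Noise model: per-centroid multiplicative log-normal noise with a given
CV, an additive uniform baseline floor, and optional ppm-scale m/z
jitter; all draws come from one seeded generator, so a fixed seed
reproduces the spectrum bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .digest import PeptideIndex, ProteinRecord
from .isotopes import LabelingState, isotope_pattern, pattern_to_mz

__all__ = [
    "SampleDesign",
    "OccupancyTruth",
    "CentroidSpectrum",
    "simulate_sample",
    "standard_curve_designs",
    "synthetic_proteome",
    "save_peaklist",
    "read_peaklist",
]

#: m/z bin within which co-located centroids are merged (below TOF resolution)
CENTROID_MERGE_BIN = 0.005

#: protein names from the B. subtilis large-subunit set studied; the
#: late-binding proteins depleted from 44S/45S intermediates are L16,
#: L27, L28, L33, L35, L36, and L20 is the stoichiometric reference
DEFAULT_PROTEIN_IDS = ("L20", "L6", "L16", "L27", "L28", "L33", "L35", "L36")

# residue frequencies (approximately bacterial cytosolic proteome);
# K+R ~ 11% gives realistic tryptic peptide lengths
_RESIDUE_FREQS = {
    "A": 0.089, "R": 0.055, "N": 0.040, "D": 0.054, "C": 0.012,
    "Q": 0.039, "E": 0.061, "G": 0.074, "H": 0.022, "I": 0.059,
    "L": 0.097, "K": 0.056, "M": 0.024, "F": 0.039, "P": 0.042,
    "S": 0.058, "T": 0.054, "W": 0.013, "Y": 0.032, "V": 0.070,
}


@dataclass(frozen=True)
class SampleDesign:
    """Mixture composition and acquisition parameters for one sample.

    Amounts are pmol of particles; ``response_factor`` converts
    pmol x relative isotopologue abundance into intensity counts.
    ``efficiency`` optionally maps peptide sequence -> ionization
    efficiency multiplier (applied to both channels; the 15N internal
    standard is expected to cancel it).
    """

    experimental_pmol: float
    spike14_pmol: float = 10.0
    spike15_pmol: float = 30.0
    enrichment: float = 0.995
    charges: tuple[int, ...] = (1, 2, 3)
    noise_cv: float = 0.0
    baseline: float = 0.0
    mz_jitter_ppm: float = 0.0
    seed: int = 0
    response_factor: float = 1e4
    efficiency: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        for name in ("experimental_pmol", "spike14_pmol", "spike15_pmol"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not 0.0 <= self.enrichment <= 1.0:
            raise ValueError("enrichment must be in [0, 1]")
        if not self.charges or any(z < 1 for z in self.charges):
            raise ValueError("charges must be positive integers")


class OccupancyTruth:
    """Ground-truth per-protein occupancy; proteins absent default to 1.0."""

    def __init__(self, values: Mapping[str, float] | None = None):
        self._values = dict(values or {})
        for pid, v in self._values.items():
            if v < 0:
                raise ValueError(f"occupancy of {pid} must be >= 0")

    @classmethod
    def uniform(cls, value: float = 1.0) -> "OccupancyTruth":
        t = cls()
        t._default = value  # type: ignore[attr-defined]
        return t

    def __getitem__(self, protein_id: str) -> float:
        return self._values.get(protein_id, getattr(self, "_default", 1.0))

    def items(self):
        return self._values.items()


@dataclass
class CentroidSpectrum:
    """Sorted centroided peak list (m/z strictly increasing)."""

    mz: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity shape mismatch")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")

    def __len__(self) -> int:
        return self.mz.size

    def scaled(self, factor: float) -> "CentroidSpectrum":
        """Same spectrum with all intensities multiplied by ``factor``."""
        return CentroidSpectrum(self.mz.copy(), self.intensity * factor, dict(self.metadata))


def _merge_centroids(mz: np.ndarray, intensity: np.ndarray, bin_width: float):
    """Merge peaks closer than bin_width: intensity-weighted m/z, summed height."""
    order = np.argsort(mz, kind="stable")
    mz, intensity = mz[order], intensity[order]
    out_mz: list[float] = []
    out_int: list[float] = []
    i = 0
    n = mz.size
    while i < n:
        j = i + 1
        while j < n and mz[j] - mz[j - 1] < bin_width:
            j += 1
        chunk_i = intensity[i:j]
        total = chunk_i.sum()
        center = float(np.dot(mz[i:j], chunk_i) / total) if total > 0 else float(mz[i:j].mean())
        out_mz.append(center)
        out_int.append(float(total))
        i = j
    return np.array(out_mz), np.array(out_int)


def simulate_sample(
    design: SampleDesign,
    truth: OccupancyTruth,
    index: PeptideIndex,
    label: str = "sample",
) -> CentroidSpectrum:
    """Generate the centroid spectrum of one double-spike mixture.

    For every unique peptide and every charge state the 14N envelope is
    scaled by ``response_factor x (experimental_pmol x occupancy +
    spike14_pmol)`` and the 15N envelope (at the design's enrichment)
    by ``response_factor x spike15_pmol``; co-located centroids are
    merged, then noise and baseline are applied.
    """
    peptides = index.unique_peptides
    if not peptides:
        raise ValueError("peptide index is empty")
    natural = LabelingState.natural()
    labeled = LabelingState.nitrogen15(design.enrichment)
    mzs: list[float] = []
    heights: list[float] = []
    for pep in peptides:
        eff = 1.0 if design.efficiency is None else design.efficiency.get(pep.sequence, 1.0)
        amp14 = design.response_factor * eff * (
            design.experimental_pmol * truth[pep.protein_id] + design.spike14_pmol
        )
        amp15 = design.response_factor * eff * design.spike15_pmol
        for amp, state in ((amp14, natural), (amp15, labeled)):
            if amp <= 0:
                continue
            pattern = isotope_pattern(pep.composition, state)
            for z in design.charges:
                for mz, ab in pattern_to_mz(pattern, z):
                    mzs.append(mz)
                    heights.append(amp * ab)
    mz_arr, int_arr = _merge_centroids(np.array(mzs), np.array(heights), CENTROID_MERGE_BIN)

    rng = np.random.default_rng(design.seed)
    if design.mz_jitter_ppm > 0:
        mz_arr = mz_arr * (1.0 + rng.normal(0.0, design.mz_jitter_ppm * 1e-6, mz_arr.size))
    if design.noise_cv > 0:
        sigma = np.sqrt(np.log1p(design.noise_cv**2))
        int_arr = int_arr * rng.lognormal(-0.5 * sigma**2, sigma, int_arr.size)
    if design.baseline > 0:
        int_arr = int_arr + design.baseline * rng.uniform(0.5, 1.5, int_arr.size)
    order = np.argsort(mz_arr, kind="stable")
    meta = {
        "label": label,
        "design": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(design).items()
            if k != "efficiency"
        },
    }
    return CentroidSpectrum(mz_arr[order], int_arr[order], meta)


def simulate_spike_alone(design: SampleDesign, index: PeptideIndex) -> CentroidSpectrum:
    """The double-spike reference measured in isolation (no experimental 14N)."""
    blank = dataclasses.replace(design, experimental_pmol=0.0)
    return simulate_sample(blank, OccupancyTruth(), index, label="spike_alone")


def standard_curve_designs(
    amounts: Sequence[float], base: SampleDesign
) -> list[SampleDesign]:
    """One design per experimental amount, all else copied from ``base``.

    Mirrors the validation series in which 0, 2, 4, 8, 16 or 32 pmol of
    14N 70S ribosomes are mixed with the 10 + 30 pmol double spike.
    """
    if not len(amounts):
        raise ValueError("amounts must be non-empty")
    if any(a < 0 for a in amounts):
        raise ValueError("amounts must be >= 0")
    return [dataclasses.replace(base, experimental_pmol=float(a)) for a in amounts]


def synthetic_proteome(
    ids: Iterable[str] = DEFAULT_PROTEIN_IDS,
    mean_length: int = 130,
    seed: int = 0,
) -> list[ProteinRecord]:
    """Random synthetic protein set standing in for the ribosomal proteins.

    Sequences are drawn i.i.d. from bacterial residue frequencies (the
    real B. subtilis sequences are not bundled); lengths vary +/-20%
    around ``mean_length``.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    residues = np.array(list(_RESIDUE_FREQS))
    probs = np.array(list(_RESIDUE_FREQS.values()))
    probs = probs / probs.sum()
    records = []
    for pid in ids:
        length = int(rng.integers(round(mean_length * 0.8), round(mean_length * 1.2) + 1))
        seq = "M" + "".join(rng.choice(residues, size=length - 1, p=probs))
        records.append(ProteinRecord(id=pid, sequence=seq))
    return records


def save_peaklist(spectrum: CentroidSpectrum, path: str | Path) -> None:
    """Write a two-column CSV peak list plus a JSON metadata sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("mz,intensity\n")
        for mz, inten in zip(spectrum.mz, spectrum.intensity):
            fh.write(f"{mz:.6f},{inten:.6f}\n")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(spectrum.metadata, indent=2))


def read_peaklist(path: str | Path) -> CentroidSpectrum:
    """Read a two-column (m/z, intensity) peak list; delimiter comma or space."""
    path = Path(path)
    try:
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    except ValueError:
        data = np.loadtxt(path, skiprows=1, ndmin=2)
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    order = np.argsort(data[:, 0])
    return CentroidSpectrum(data[order, 0], data[order, 1], meta)
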