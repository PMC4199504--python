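"""End-to-end convenience wrappers: spectrum -> fits -> occupancy.

These chain the stage functions with one shared configuration so that
the same matching tolerance, enrichment and exclusion thresholds are
used for the experimental sample and the spike-alone reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .digest import PeptideIndex
from .fitting import (
    DEFAULT_CHARGES,
    DEFAULT_RESIDUAL_MAX,
    DEFAULT_SNR_MIN,
    DEFAULT_TOLERANCE_PPM,
    PairFit,
    filter_fits,
    fit_pairs,
    match_peak_pairs,
)
from .quantify import (
    DEFAULT_REFERENCE_PROTEIN,
    CurveReport,
    OccupancyTable,
    RatioRecord,
    accepted_fits,
    protein_occupancy,
    raw_ratios,
    spike_correct,
    standard_curve_report,
)
from .synthetic import (
    CentroidSpectrum,
    OccupancyTruth,
    SampleDesign,
    simulate_sample,
    simulate_spike_alone,
    standard_curve_designs,
)

__all__ = ["FitConfig", "fit_spectrum", "corrected_ratios", "analyze_sample", "run_standard_curve"]


@dataclass(frozen=True)
class FitConfig:
    """Shared matching / fitting / exclusion parameters."""

    charges: tuple[int, ...] = DEFAULT_CHARGES
    tolerance_ppm: float = DEFAULT_TOLERANCE_PPM
    enrichment: float = 0.995
    prune: float = 1e-4
    snr_min: float = DEFAULT_SNR_MIN
    residual_max: float = DEFAULT_RESIDUAL_MAX

    @classmethod
    def for_design(cls, design: SampleDesign, **overrides) -> "FitConfig":
        """Config matched to a simulated design's enrichment and charges."""
        return cls(charges=tuple(design.charges), enrichment=design.enrichment, **overrides)


def fit_spectrum(
    spectrum: CentroidSpectrum, index: PeptideIndex, config: FitConfig = FitConfig()
) -> list[PairFit]:
    """Match peak pairs, fit amplitudes, and apply the exclusion rule."""
    windows = match_peak_pairs(
        spectrum,
        index,
        charges=config.charges,
        tolerance_ppm=config.tolerance_ppm,
        enrichment=config.enrichment,
        prune=config.prune,
    )
    return filter_fits(fit_pairs(windows), config.snr_min, config.residual_max)


def corrected_ratios(
    sample_spectrum: CentroidSpectrum,
    spike_spectrum: CentroidSpectrum,
    index: PeptideIndex,
    config: FitConfig = FitConfig(),
) -> list[RatioRecord]:
    """Raw ratios of both runs, spike-corrected per peptide."""
    sample_fits = accepted_fits(fit_spectrum(sample_spectrum, index, config))
    spike_fits = accepted_fits(fit_spectrum(spike_spectrum, index, config))
    return spike_correct(raw_ratios(sample_fits), raw_ratios(spike_fits))


def analyze_sample(
    sample_spectrum: CentroidSpectrum,
    spike_spectrum: CentroidSpectrum,
    index: PeptideIndex,
    config: FitConfig = FitConfig(),
    reference: str = DEFAULT_REFERENCE_PROTEIN,
) -> OccupancyTable:
    """Full pipeline for one sample: fits -> corrected ratios -> occupancy."""
    return protein_occupancy(
        corrected_ratios(sample_spectrum, spike_spectrum, index, config), reference=reference
    )


def run_standard_curve(
    index: PeptideIndex,
    base_design: SampleDesign,
    amounts: Sequence[float] = (0, 2, 4, 8, 16, 32),
    reference_amount: float = 20.0,
    config: FitConfig | None = None,
) -> CurveReport:
    """Simulate and analyze a spiked dilution series end to end.

    Each point is simulated with occupancy-1.0 truth, fitted, and
    spike-corrected against a spike-alone run simulated from the same
    base design.
    """
    if config is None:
        config = FitConfig.for_design(base_design)
    spike_spec = simulate_spike_alone(base_design, index)
    spike_records = raw_ratios(accepted_fits(fit_spectrum(spike_spec, index, config)))
    truth = OccupancyTruth()
    corrected_points = []
    for design in standard_curve_designs(amounts, base_design):
        spec = simulate_sample(design, truth, index)
        recs = raw_ratios(accepted_fits(fit_spectrum(spec, index, config)))
        corrected_points.append(spike_correct(recs, spike_records))
    return standard_curve_report(
        corrected_points,
        amounts,
        reference_amount=reference_amount,
        spike15_pmol=base_design.spike15_pmol,
    )
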