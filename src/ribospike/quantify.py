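"""Spike-corrected ratios, occupancy and abundance reporting.

The measured quantity for each peptide is the 14N/15N fitted-amplitude
ratio.  Because every sample contains the same 30 pmol of 15N-labeled
70S ribosomes, dividing by the 15N amplitude normalizes out sample
preparation and ionization-efficiency differences.  The 14N half of
the double spike (10 pmol) contributes to every 14N amplitude; its
share is removed by subtracting, per peptide, the ratio measured for
the double spike analyzed in isolation.  Per-protein occupancy is the
median corrected ratio across a protein's peptides divided by that of
a stoichiometric reference protein (L20), so that a full-stoichiometry
protein reads 1.0 regardless of the amount of sample loaded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import PairFit

__all__ = [
    "RatioRecord",
    "OccupancyTable",
    "CurveReport",
    "accepted_fits",
    "raw_ratios",
    "spike_correct",
    "protein_occupancy",
    "whole_cell_abundance",
    "standard_curve_report",
    "pearson_r",
]

logger = logging.getLogger(__name__)

DEFAULT_REFERENCE_PROTEIN = "L20"
#: occupancy below which a value sits under the validated linear range
#: (2 pmol experimental vs the 20 pmol full-stoichiometry load)
QUANTITATION_FLOOR = 0.1


@dataclass(frozen=True)
class RatioRecord:
    """Per-peptide 14N/15N ratio, optionally spike-corrected."""

    protein_id: str
    sequence: str
    charge: int
    ratio_raw: float
    ratio_corrected: float | None = None
    flags: tuple[str, ...] = ()


@dataclass
class OccupancyTable:
    """Per-protein occupancy with per-peptide detail."""

    proteins: pd.DataFrame  # protein_id, median_corrected_ratio, occupancy, n_peptides, flags
    peptides: pd.DataFrame  # long format, one row per corrected peptide record
    reference: str

    def occupancy_of(self, protein_id: str) -> float:
        row = self.proteins.loc[self.proteins["protein_id"] == protein_id, "occupancy"]
        if row.empty:
            raise KeyError(protein_id)
        return float(row.iloc[0])


def accepted_fits(fits: Sequence[PairFit], include_overlapping: bool = False) -> list[PairFit]:
    """Accepted fits, by default also excluding overlapping windows."""
    return [f for f in fits if f.accepted and (include_overlapping or not f.overlapping)]


def raw_ratios(fits: Sequence[PairFit]) -> list[RatioRecord]:
    """14N/15N amplitude ratio per accepted fit.

    Fits with a zero 15N amplitude cannot be normalized and are
    excluded (logged); the 15N internal standard is present in every
    sample by design, so this indicates a failed fit.
    """
    records = []
    for f in fits:
        if f.amp15 <= 0:
            logger.warning(
                "excluding %s/%d+: zero 15N amplitude", f.peptide.sequence, f.charge
            )
            continue
        records.append(
            RatioRecord(
                protein_id=f.peptide.protein_id,
                sequence=f.peptide.sequence,
                charge=f.charge,
                ratio_raw=f.amp14 / f.amp15,
            )
        )
    return records


def spike_correct(
    sample: Sequence[RatioRecord], spike_alone: Sequence[RatioRecord]
) -> list[RatioRecord]:
    """Subtract the double spike's 14N contribution on the ratio scale.

    Each sample peptide is matched to the spike-alone run by
    (sequence, charge).  Peptides absent from the spike-alone run fall
    back to their protein's median spike-alone ratio (flagged
    ``spike_fallback``); with no fallback available the record is
    excluded and logged.  Negative corrected ratios are flagged, never
    clamped: clamping would bias occupancy exactly where depletion
    calls live.
    """
    by_key = {(r.sequence, r.charge): r.ratio_raw for r in spike_alone}
    by_protein: dict[str, list[float]] = {}
    for r in spike_alone:
        by_protein.setdefault(r.protein_id, []).append(r.ratio_raw)
    out = []
    for r in sample:
        flags: tuple[str, ...] = ()
        key = (r.sequence, r.charge)
        if key in by_key:
            spike_ratio = by_key[key]
        elif r.protein_id in by_protein:
            spike_ratio = float(np.median(by_protein[r.protein_id]))
            flags = ("spike_fallback",)
        else:
            logger.warning(
                "excluding %s/%d+: absent from spike-alone run", r.sequence, r.charge
            )
            continue
        corrected = r.ratio_raw - spike_ratio
        if corrected < 0:
            flags = flags + ("negative_corrected",)
        out.append(replace(r, ratio_corrected=corrected, flags=flags))
    return out


def protein_occupancy(
    records: Sequence[RatioRecord],
    reference: str = DEFAULT_REFERENCE_PROTEIN,
    aggregate: str = "median",
) -> OccupancyTable:
    """Aggregate corrected ratios per protein and normalize to a reference.

    Per-protein value = median (or mean) of its peptides' corrected
    ratios; occupancy = that value / the reference protein's value.
    The reference protein's occupancy is exactly 1.0 by construction.
    A missing reference is a hard error: silently renormalizing to
    another protein would change the meaning of every number.
    """
    records = [r for r in records if r.ratio_corrected is not None]
    if not records:
        raise ValueError("no corrected ratio records")
    if aggregate not in ("median", "mean"):
        raise ValueError("aggregate must be 'median' or 'mean'")
    agg = np.median if aggregate == "median" else np.mean
    peptides = pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in records],
            "sequence": [r.sequence for r in records],
            "charge": [r.charge for r in records],
            "ratio_raw": [r.ratio_raw for r in records],
            "ratio_corrected": [r.ratio_corrected for r in records],
            "flags": [";".join(r.flags) for r in records],
        }
    )
    grouped = peptides.groupby("protein_id")["ratio_corrected"]
    medians = grouped.apply(lambda s: float(agg(s.to_numpy())))
    counts = grouped.size()
    if reference not in medians.index:
        raise ValueError(f"reference protein {reference!r} has no accepted records")
    ref_value = medians[reference]
    if ref_value <= 0:
        raise ValueError(f"reference protein {reference!r} has non-positive median ratio")
    proteins = pd.DataFrame(
        {
            "protein_id": medians.index,
            "median_corrected_ratio": medians.to_numpy(),
            "occupancy": medians.to_numpy() / ref_value,
            "n_peptides": counts.reindex(medians.index).to_numpy(),
        }
    ).reset_index(drop=True)
    proteins.loc[proteins["protein_id"] == reference, "occupancy"] = 1.0
    flags = []
    for _, row in proteins.iterrows():
        f = []
        if row["occupancy"] < QUANTITATION_FLOOR:
            f.append("below_quantitation_limit")
        if row["median_corrected_ratio"] < 0:
            f.append("negative_median")
        flags.append(";".join(f))
    proteins["flags"] = flags
    return OccupancyTable(proteins=proteins, peptides=peptides, reference=reference)


def whole_cell_abundance(
    tables: Mapping[str, OccupancyTable], reference_condition: str
) -> pd.DataFrame:
    """Protein x condition abundance, doubly normalized.

    Each table is already normalized to the reference protein within
    its condition; this divides each protein's value by its value in
    ``reference_condition``, so the reference condition's column is
    identically 1.  Proteins missing from the reference condition (or
    at zero there) are excluded with a logged reason.
    """
    if reference_condition not in tables:
        raise ValueError(f"reference condition {reference_condition!r} missing")
    ref = tables[reference_condition].proteins.set_index("protein_id")["occupancy"]
    cols = {}
    for cond, table in tables.items():
        cols[cond] = table.proteins.set_index("protein_id")["occupancy"]
    matrix = pd.DataFrame(cols)
    keep = []
    for pid in matrix.index:
        if pid not in ref.index or ref[pid] == 0 or pd.isna(ref[pid]):
            logger.warning("excluding %s: no nonzero value in reference condition", pid)
            continue
        keep.append(pid)
    matrix = matrix.loc[keep]
    return matrix.div(ref[keep], axis=0)


@dataclass
class CurveReport:
    """Standard-curve linear fit and per-point r-protein equivalents."""

    slope: float
    intercept: float
    r_squared: float
    points: pd.DataFrame = field(repr=False)  # amount_pmol, median_ratio, equivalents


def standard_curve_report(
    corrected_per_point: Sequence[Sequence[RatioRecord]],
    amounts: Sequence[float],
    reference_amount: float = 20.0,
    spike15_pmol: float = 30.0,
) -> CurveReport:
    """Dose-response statistics of a spiked dilution series.

    Fits an ordinary least-squares line of the median corrected ratio
    against the 14N amount added and expresses each point in r-protein
    equivalents: the corrected ratio relative to that of the
    ``reference_amount`` load that defines occupancy 1.0 (by
    construction reference_amount / spike15_pmol on the ratio scale).
    """
    if len(corrected_per_point) != len(amounts):
        raise ValueError("one record list required per amount")
    if len(amounts) < 3:
        raise ValueError("need >= 3 curve points")
    medians = []
    for recs in corrected_per_point:
        vals = [r.ratio_corrected for r in recs if r.ratio_corrected is not None]
        if not vals:
            raise ValueError("curve point with no corrected records")
        medians.append(float(np.median(vals)))
    fit = stats.linregress(np.asarray(amounts, dtype=float), np.asarray(medians))
    full_scale = reference_amount / spike15_pmol
    points = pd.DataFrame(
        {
            "amount_pmol": list(amounts),
            "median_ratio": medians,
            "equivalents": [m / full_scale for m in medians],
        }
    )
    return CurveReport(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        points=points,
    )


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation between paired vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)
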