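"""Peak-pair detection and isotope-envelope amplitude fitting.

For every unique theoretical peptide and charge state, the observed
centroids lying within a ppm tolerance of the 14N and 15N envelope
positions form a *pair window*.  Within a window the observed
intensities are modeled linearly,

    observed ~= amp14 * template14 + amp15 * template15 + baseline,

where the templates are the normalized theoretical abundance vectors,
and solved by non-negative least squares.  On centroided data this
linear model is what envelope-amplitude fitting reduces to, whatever
solver realizes it.  Windows of different peptides that claim the same
observed centroid are flagged as overlapping and fitted jointly so
that a shared peak's intensity is apportioned rather than counted
twice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .digest import PeptideIndex, PeptideSpecies
from .isotopes import LabelingState, isotope_pattern, pattern_to_mz
from .synthetic import CENTROID_MERGE_BIN, CentroidSpectrum

__all__ = [
    "PairWindow",
    "PairFit",
    "match_peak_pairs",
    "fit_pair",
    "fit_pairs",
    "filter_fits",
    "fits_to_dataframe",
]

DEFAULT_TOLERANCE_PPM = 10.0
DEFAULT_SNR_MIN = 3.0
DEFAULT_RESIDUAL_MAX = 0.3
DEFAULT_CHARGES = (1, 2, 3)
#: a window must match this many of the top theoretical peaks of at
#: least one channel; prevents one-peak "envelopes" from passing
MIN_TOP_PEAKS = 3


@dataclass
class PairWindow:
    """Observed peaks around one peptide/charge's 14N+15N envelope pair."""

    peptide: PeptideSpecies
    charge: int
    positions: np.ndarray  # theoretical m/z (union of both channels)
    template14: np.ndarray  # 14N abundance at each position
    template15: np.ndarray  # 15N abundance at each position
    peak_ids: np.ndarray  # index into the spectrum, -1 where unmatched
    observed: np.ndarray  # observed intensity, 0 where unmatched
    overlapping: bool = False

    def __len__(self) -> int:
        return self.positions.size


@dataclass
class PairFit:
    """Fitted channel amplitudes for one peptide/charge."""

    peptide: PeptideSpecies
    charge: int
    amp14: float
    amp15: float
    baseline: float
    residual_fraction: float
    snr: float
    accepted: bool = True
    overlapping: bool = False


def _cluster_positions(
    mz14: np.ndarray, ab14: np.ndarray, mz15: np.ndarray, ab15: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Union of both envelopes' positions, merging within the centroid bin."""
    mz = np.concatenate([mz14, mz15])
    a14 = np.concatenate([ab14, np.zeros_like(ab15)])
    a15 = np.concatenate([np.zeros_like(ab14), ab15])
    order = np.argsort(mz, kind="stable")
    mz, a14, a15 = mz[order], a14[order], a15[order]
    pos, t14, t15 = [], [], []
    i = 0
    while i < mz.size:
        j = i + 1
        while j < mz.size and mz[j] - mz[j - 1] < CENTROID_MERGE_BIN:
            j += 1
        w = a14[i:j] + a15[i:j]
        center = float(np.dot(mz[i:j], w) / w.sum()) if w.sum() > 0 else float(mz[i:j].mean())
        pos.append(center)
        t14.append(float(a14[i:j].sum()))
        t15.append(float(a15[i:j].sum()))
        i = j
    return np.array(pos), np.array(t14), np.array(t15)


def _top_peaks_matched(template: np.ndarray, matched: np.ndarray, k: int = MIN_TOP_PEAKS) -> bool:
    idx = np.nonzero(template > 0)[0]
    if idx.size == 0:
        return False
    top = idx[np.argsort(template[idx])[::-1]][: min(k, idx.size)]
    return bool(np.all(matched[top]))


def match_peak_pairs(
    spectrum: CentroidSpectrum,
    index: PeptideIndex,
    charges: Sequence[int] = DEFAULT_CHARGES,
    tolerance_ppm: float = DEFAULT_TOLERANCE_PPM,
    enrichment: float = 0.995,
    prune: float = 1e-4,
) -> list[PairWindow]:
    """Assign observed centroids to theoretical 14N:15N peak pairs.

    Returns one window per (unique peptide, charge) that matches at
    least the top :data:`MIN_TOP_PEAKS` theoretical peaks of one
    channel.  Windows sharing an observed centroid are flagged
    ``overlapping``.  An empty spectrum yields an empty list.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be > 0")
    if len(spectrum) == 0:
        return []
    natural = LabelingState.natural()
    labeled = LabelingState.nitrogen15(enrichment)
    windows: list[PairWindow] = []
    mz_obs = spectrum.mz
    for pep in index.unique_peptides:
        p14 = isotope_pattern(pep.composition, natural, prune)
        p15 = isotope_pattern(pep.composition, labeled, prune)
        for z in charges:
            mz14, ab14 = map(np.array, zip(*pattern_to_mz(p14, z)))
            mz15, ab15 = map(np.array, zip(*pattern_to_mz(p15, z)))
            pos, t14, t15 = _cluster_positions(mz14, ab14, mz15, ab15)
            tol = pos * tolerance_ppm * 1e-6
            nearest = np.clip(np.searchsorted(mz_obs, pos), 0, mz_obs.size - 1)
            prev = np.clip(nearest - 1, 0, mz_obs.size - 1)
            pick = np.where(
                np.abs(mz_obs[prev] - pos) <= np.abs(mz_obs[nearest] - pos), prev, nearest
            )
            matched = np.abs(mz_obs[pick] - pos) <= tol
            peak_ids = np.where(matched, pick, -1)
            if not (_top_peaks_matched(t14, matched) or _top_peaks_matched(t15, matched)):
                continue
            observed = np.where(matched, spectrum.intensity[np.clip(peak_ids, 0, None)], 0.0)
            windows.append(
                PairWindow(
                    peptide=pep,
                    charge=z,
                    positions=pos,
                    template14=t14,
                    template15=t15,
                    peak_ids=peak_ids,
                    observed=observed,
                )
            )
    # flag windows that claim the same observed centroid
    usage: dict[int, int] = {}
    for w in windows:
        for pid in w.peak_ids:
            if pid >= 0:
                usage[int(pid)] = usage.get(int(pid), 0) + 1
    for w in windows:
        w.overlapping = any(usage[int(p)] > 1 for p in w.peak_ids if p >= 0)
    return windows


def _fit_metrics(y: np.ndarray, pred: np.ndarray, base: float) -> tuple[float, float]:
    norm_y = float(np.linalg.norm(y))
    residual = float(np.linalg.norm(y - pred)) / norm_y if norm_y > 0 else 1.0
    snr = float(y.max()) / base if base > 1e-12 else math.inf
    return residual, snr


def fit_pair(window: PairWindow) -> PairFit:
    """Non-negative least-squares fit of one isolated window."""
    y = window.observed
    if not np.any(y > 0):
        return PairFit(
            peptide=window.peptide,
            charge=window.charge,
            amp14=0.0,
            amp15=0.0,
            baseline=0.0,
            residual_fraction=1.0,
            snr=0.0,
            accepted=False,
            overlapping=window.overlapping,
        )
    a = np.column_stack([window.template14, window.template15, np.ones_like(y)])
    x, _ = nnls(a, y)
    pred = a @ x
    residual, snr = _fit_metrics(y, pred, x[2])
    return PairFit(
        peptide=window.peptide,
        charge=window.charge,
        amp14=float(x[0]),
        amp15=float(x[1]),
        baseline=float(x[2]),
        residual_fraction=residual,
        snr=snr,
        overlapping=window.overlapping,
    )


def _joint_fit(group: list[PairWindow]) -> list[PairFit]:
    """Fit windows sharing observed centroids together, one amplitude
    pair per window plus a common baseline, so shared intensity is
    apportioned rather than double-counted."""
    row_of_peak: dict[int, int] = {}
    rows = 0
    window_rows: list[np.ndarray] = []
    y_vals: dict[int, float] = {}
    for w in group:
        wr = np.empty(len(w), dtype=int)
        for i, pid in enumerate(w.peak_ids):
            if pid >= 0:
                pid = int(pid)
                if pid not in row_of_peak:
                    row_of_peak[pid] = rows
                    y_vals[rows] = float(w.observed[i])
                    rows += 1
                wr[i] = row_of_peak[pid]
            else:
                y_vals[rows] = 0.0
                wr[i] = rows
                rows += 1
        window_rows.append(wr)
    y = np.array([y_vals[r] for r in range(rows)])
    a = np.zeros((rows, 2 * len(group) + 1))
    for k, (w, wr) in enumerate(zip(group, window_rows)):
        np.add.at(a[:, 2 * k], wr, w.template14)
        np.add.at(a[:, 2 * k + 1], wr, w.template15)
    a[:, -1] = 1.0
    x, _ = nnls(a, y)
    pred = a @ x
    base = float(x[-1])
    fits = []
    for k, (w, wr) in enumerate(zip(group, window_rows)):
        residual, snr = _fit_metrics(y[wr], pred[wr], base)
        fits.append(
            PairFit(
                peptide=w.peptide,
                charge=w.charge,
                amp14=float(x[2 * k]),
                amp15=float(x[2 * k + 1]),
                baseline=base,
                residual_fraction=residual,
                snr=snr,
                overlapping=True,
            )
        )
    return fits


def fit_pairs(windows: Sequence[PairWindow]) -> list[PairFit]:
    """Fit every window; windows connected through shared observed
    centroids are solved jointly, all others independently.  Output
    order follows input order."""
    # union-find over windows via shared peak ids
    parent = list(range(len(windows)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    claimed: dict[int, int] = {}
    for wi, w in enumerate(windows):
        for pid in w.peak_ids:
            if pid < 0:
                continue
            pid = int(pid)
            if pid in claimed:
                ra, rb = find(claimed[pid]), find(wi)
                if ra != rb:
                    parent[rb] = ra
            else:
                claimed[pid] = wi
    groups: dict[int, list[int]] = {}
    for wi in range(len(windows)):
        groups.setdefault(find(wi), []).append(wi)
    fits: list[PairFit | None] = [None] * len(windows)
    for members in groups.values():
        if len(members) == 1:
            fits[members[0]] = fit_pair(windows[members[0]])
        else:
            for wi, f in zip(members, _joint_fit([windows[wi] for wi in members])):
                fits[wi] = f
    return fits  # type: ignore[return-value]


def filter_fits(
    fits: Sequence[PairFit],
    snr_min: float = DEFAULT_SNR_MIN,
    residual_max: float = DEFAULT_RESIDUAL_MAX,
) -> list[PairFit]:
    """Apply the signal-to-noise / fit-quality exclusion rule.

    Nothing is dropped: every fit is returned with ``accepted`` set, so
    rejected fits remain auditable.
    """
    if snr_min < 0 or residual_max < 0:
        raise ValueError("thresholds must be >= 0")
    out = []
    for f in fits:
        ok = (f.snr >= snr_min) and (f.residual_fraction <= residual_max)
        if f.amp14 == 0.0 and f.amp15 == 0.0 and f.residual_fraction >= 1.0:
            ok = False
        out.append(replace(f, accepted=ok))
    return out


def fits_to_dataframe(fits: Sequence[PairFit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein_id": [f.peptide.protein_id for f in fits],
            "peptide": [f.peptide.sequence for f in fits],
            "charge": [f.charge for f in fits],
            "amp14": [f.amp14 for f in fits],
            "amp15": [f.amp15 for f in fits],
            "ratio_raw": [f.amp14 / f.amp15 if f.amp15 > 0 else np.nan for f in fits],
            "snr": [f.snr for f in fits],
            "residual_fraction": [f.residual_fraction for f in fits],
            "accepted": [f.accepted for f in fits],
            "overlapping": [f.overlapping for f in fits],
        }
    )
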