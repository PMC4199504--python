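"""Peak-pair matching and non-negative envelope-amplitude fitting."""

import dataclasses

import numpy as np
import pytest

import ribospike as rs
from ribospike.fitting import PairFit, fit_pair, match_peak_pairs
from ribospike.synthetic import CentroidSpectrum


def generating_amps(design, truth, protein_id):
    amp14 = design.response_factor * (
        design.experimental_pmol * truth[protein_id] + design.spike14_pmol
    )
    amp15 = design.response_factor * design.spike15_pmol
    return amp14, amp15


class TestMatching:
    def test_closure_under_simulation(self, small_index, base_design):
        """Every (unique peptide, charge) the simulator emitted yields a window."""
        spec = rs.simulate_spike_alone(base_design, small_index)
        windows = match_peak_pairs(
            spec, small_index, charges=base_design.charges, enrichment=1.0
        )
        expected = len(small_index.unique_peptides) * len(base_design.charges)
        assert len(windows) == expected

    def test_tolerance_contract(self, small_index, base_design):
        """Shifting all peaks +50 ppm defeats a 10 ppm matching tolerance."""
        spec = rs.simulate_spike_alone(base_design, small_index)
        shifted = CentroidSpectrum(spec.mz * (1 + 50e-6), spec.intensity)
        windows = match_peak_pairs(
            shifted, small_index, charges=base_design.charges,
            tolerance_ppm=10.0, enrichment=1.0,
        )
        assert windows == []

    def test_empty_spectrum(self, small_index):
        spec = CentroidSpectrum(np.array([]), np.array([]))
        assert match_peak_pairs(spec, small_index, enrichment=1.0) == []

    def test_designed_collision_flags_overlap(self):
        """Two peptides engineered to share m/z positions (same composition,
        hence identical envelopes) must both be flagged overlapping."""
        # GAS and ASG: identical elemental composition, different proteins
        p1 = rs.ProteinRecord("A", "MVVVVKGASWIR")
        p2 = rs.ProteinRecord("B", "MLLLLKASGWIR")
        idx = rs.build_unique_peptide_index([p1, p2], max_missed=0, min_length=3)
        design = rs.SampleDesign(experimental_pmol=0.0, enrichment=1.0, charges=(1,), seed=0)
        spec = rs.simulate_spike_alone(design, idx)
        windows = match_peak_pairs(spec, idx, charges=(1,), enrichment=1.0)
        colliding = [w for w in windows if w.peptide.sequence in ("GASWIR", "ASGWIR")]
        assert len(colliding) == 2
        assert all(w.overlapping for w in colliding)


class TestFitting:
    def test_generative_recovery(self, small_index, base_design):
        """Noiseless amplitudes are recovered to <= 1e-6 relative error."""
        design = dataclasses.replace(base_design, experimental_pmol=20.0)
        truth = rs.OccupancyTruth()
        spec = rs.simulate_sample(design, truth, small_index)
        fits = rs.fit_spectrum(spec, small_index, rs.FitConfig.for_design(design))
        checked = 0
        for f in fits:
            if not f.accepted:
                continue
            amp14, amp15 = generating_amps(design, truth, f.peptide.protein_id)
            assert f.amp14 == pytest.approx(amp14, rel=1e-6)
            assert f.amp15 == pytest.approx(amp15, rel=1e-6)
            checked += 1
        assert checked >= 0.9 * len(fits)

    def test_channel_isolation(self, small_index):
        """A sample containing only the 15N spike fits amp14 = 0."""
        design = rs.SampleDesign(
            experimental_pmol=0.0, spike14_pmol=0.0, enrichment=1.0, charges=(2,), seed=0
        )
        spec = rs.simulate_spike_alone(design, small_index)
        fits = rs.accepted_fits(rs.fit_spectrum(spec, small_index, rs.FitConfig.for_design(design)))
        assert fits
        for f in fits:
            assert f.amp14 == pytest.approx(0.0, abs=1e-6 * f.amp15)
            assert f.amp15 > 0

    def test_all_zero_window_rejected(self, small_index, base_design):
        spec = rs.simulate_spike_alone(base_design, small_index)
        windows = match_peak_pairs(spec, small_index, charges=(1,), enrichment=1.0)
        w = windows[0]
        w.observed = np.zeros_like(w.observed)
        f = fit_pair(w)
        assert f.amp14 == 0.0 and f.amp15 == 0.0 and not f.accepted

    def test_overlapping_envelopes_vs_grid_oracle(self):
        """With a single nitrogen at charge 1 the 15N envelope sits only
        1 Da above the 14N one, so the channels interleave on the same
        comb of positions; the NNLS solution must still equal the
        generating amplitudes, cross-checked by an exhaustive
        2-parameter grid search."""
        from ribospike.chem import Composition
        from ribospike.fitting import PairWindow, _cluster_positions
        from ribospike.isotopes import LabelingState, isotope_pattern, pattern_to_mz

        comp = Composition(C=12, H=22, N=1, O=4)
        pat14 = isotope_pattern(comp, LabelingState.natural())
        pat15 = isotope_pattern(comp, LabelingState.nitrogen15(1.0))
        mz14, ab14 = map(np.array, zip(*pattern_to_mz(pat14, 1)))
        mz15, ab15 = map(np.array, zip(*pattern_to_mz(pat15, 1)))
        pos, t14, t15 = _cluster_positions(mz14, ab14, mz15, ab15)
        assert np.any((t14 > 0) & (t15 > 0))  # channels genuinely share peaks
        a14_true, a15_true = 2.0, 3.0
        pep = rs.PeptideSpecies(
            sequence="SYNTHETIC", protein_id="A", missed_cleavages=0,
            composition=comp, monoisotopic_mass=comp.monoisotopic_mass(),
        )
        w = PairWindow(
            peptide=pep, charge=1, positions=pos, template14=t14, template15=t15,
            peak_ids=np.arange(pos.size), observed=a14_true * t14 + a15_true * t15,
        )
        assert len(w) <= 12
        fit = fit_pair(w)
        assert fit.amp14 == pytest.approx(a14_true, rel=1e-6)
        assert fit.amp15 == pytest.approx(a15_true, rel=1e-6)
        # exhaustive grid around the generating point, step 1e-4 x amplitude
        step14, step15 = 1e-4 * a14_true, 1e-4 * a15_true
        g14 = a14_true + step14 * np.arange(-300, 301)
        g15 = a15_true + step15 * np.arange(-300, 301)
        y, t14, t15 = w.observed, w.template14, w.template15
        sse = (
            np.dot(y, y)
            - 2 * np.outer(g14, np.full_like(g15, 1.0)) * np.dot(y, t14)
            - 2 * np.outer(np.full_like(g14, 1.0), g15) * np.dot(y, t15)
            + np.outer(g14**2, np.full_like(g15, 1.0)) * np.dot(t14, t14)
            + np.outer(np.full_like(g14, 1.0), g15**2) * np.dot(t15, t15)
            + 2 * np.outer(g14, g15) * np.dot(t14, t15)
        )
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        assert abs(fit.amp14 - g14[i]) <= step14
        assert abs(fit.amp15 - g15[j]) <= step15

    def test_noiseless_recovery_many_random_samples(self, small_index):
        """Across many random designs and truths, noiseless fitted
        amplitudes match the generating amplitudes (max rel err < 1e-5)."""
        rng = np.random.default_rng(123)
        worst = 0.0
        for trial in range(30):
            design = rs.SampleDesign(
                experimental_pmol=float(rng.uniform(0, 40)),
                enrichment=1.0,
                charges=(2,),
                seed=int(rng.integers(1 << 16)),
            )
            truth = rs.OccupancyTruth(
                {p: float(rng.choice([0.25, 0.5, 1.0])) for p in ("L6", "L16")}
            )
            spec = rs.simulate_sample(design, truth, small_index)
            fits = rs.accepted_fits(rs.fit_spectrum(spec, small_index, rs.FitConfig.for_design(design)))
            for f in fits:
                a14, a15 = generating_amps(design, truth, f.peptide.protein_id)
                worst = max(worst, abs(f.amp14 - a14) / max(a14, 1e-12))
                worst = max(worst, abs(f.amp15 - a15) / a15)
        assert worst < 1e-5

    def test_noise_robustness(self, small_index):
        """At 5% multiplicative noise the median relative amplitude error
        of accepted fits stays below 5%."""
        design = rs.SampleDesign(
            experimental_pmol=20.0, enrichment=1.0, charges=(2,), noise_cv=0.05, seed=77
        )
        truth = rs.OccupancyTruth()
        spec = rs.simulate_sample(design, truth, small_index)
        fits = rs.accepted_fits(rs.fit_spectrum(spec, small_index, rs.FitConfig.for_design(design)))
        errs = []
        for f in fits:
            a14, _ = generating_amps(design, truth, f.peptide.protein_id)
            errs.append(abs(f.amp14 - a14) / a14)
        assert fits and float(np.median(errs)) < 0.05

    def test_non_negativity(self, small_index):
        """No fit returns a negative amplitude, even under heavy noise."""
        design = rs.SampleDesign(
            experimental_pmol=1.0, enrichment=1.0, charges=(2,),
            noise_cv=0.5, baseline=500.0, seed=5,
        )
        spec = rs.simulate_sample(design, rs.OccupancyTruth(), small_index)
        for f in rs.fit_spectrum(spec, small_index, rs.FitConfig.for_design(design)):
            assert f.amp14 >= 0 and f.amp15 >= 0


class TestFilter:
    def _mk(self, snr, residual):
        pep = rs.PeptideSpecies(
            sequence="GAVLIK", protein_id="L20", missed_cleavages=0,
            composition=rs.peptide_composition("GAVLIK"),
            monoisotopic_mass=rs.monoisotopic_mass(rs.peptide_composition("GAVLIK")),
        )
        return PairFit(
            peptide=pep, charge=2, amp14=1.0, amp15=1.0, baseline=0.0,
            residual_fraction=residual, snr=snr,
        )

    def test_thresholds(self):
        good = self._mk(snr=100.0, residual=0.01)
        low_snr = self._mk(snr=1.0, residual=0.01)
        bad_fit = self._mk(snr=100.0, residual=0.5)
        out = rs.filter_fits([good, low_snr, bad_fit], snr_min=3.0, residual_max=0.3)
        assert [f.accepted for f in out] == [True, False, False]

    def test_nothing_silently_dropped(self):
        fits = [self._mk(snr=s, residual=0.1) for s in (0.5, 2, 5, 50)]
        assert len(rs.filter_fits(fits)) == len(fits)
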