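# Methods

## Measurement model

Every sample analyzed is a three-part mixture: the ¹⁴N-labeled
experimental particles (amount `experimental_pmol`, nominally 20 pmol),
plus a "double spike" of ¹⁴N-labeled (10 pmol) and ¹⁵N-labeled
(30 pmol) mature 70S ribosomes. After tryptic digestion each
detectable peptide contributes two isotope envelopes to the MS¹
spectrum: a natural-abundance ¹⁴N envelope whose generating amplitude
is proportional to

    experimental_pmol × occupancy(protein) + spike14_pmol

and a ¹⁵N-enriched envelope proportional to `spike15_pmol`, offset by
(number of nitrogens × ≈0.997 Da)/charge. The pipeline inverts this
model: fit both amplitudes, divide by the ¹⁵N amplitude, subtract the
spike-alone ratio, and normalize to a stoichiometric reference
protein (L20 by default).

Assumptions: the ¹⁵N standard is present in every sample at a fixed
amount; ionization efficiency, losses during preparation, and the
total signal scale affect the two channels of a peptide equally (hence
cancel in the ratio); the reference protein is genuinely
stoichiometric in all samples (occupancy 1 is *defined* by it); and
the ¹⁵N enrichment is uniform across proteins.

## Digestion

Trypsin specificity: cleavage after K or R, suppressed when the next
residue is P (Mascot-style convention). Defaults: at most 1 missed
cleavage, peptide length 6–30 residues — a typical detectability
window for an ESI-TOF instrument; both are parameters.
Carbamidomethylation of cysteine (+C2H3NO) is the only fixed
modification, always on by default (iodoacetamide alkylation is part
of standard preparation); no variable modifications. Peptide
sequences shared by two proteins are kept in the index for audit but
flagged non-unique and excluded from quantitation. Atomic masses and
isotope abundances are an embedded constants table (six decimals) so
mass arithmetic does not depend on any external library's tables.

## Isotope envelopes

Envelopes are computed by direct convolution of per-atom isotope
distributions on a nominal-mass-offset grid (exponentiation-by-squaring
over atom counts), aggregating isotopologues with the same integer
offset into one centroid at the abundance-weighted mean mass. This is
mathematically the distribution-of-sums computation that
Fourier-transform-based envelope fitters realize; at peptide scale and
TOF resolution the direct convolution is exact and fast, and the
nominal-bin aggregation matches what a centroiding algorithm reports.
Peaks below 1e-4 of the base peak are pruned and the envelope is
renormalized to sum 1 (the tail is below instrument dynamic range;
pruning bounds envelope length). Tests verify the convolution against
exhaustive isotopologue enumeration to 1e-10 per aggregated peak.
¹⁵N enrichment defaults to 0.995 (typical for minimal-media metabolic
labeling; the achieved enrichment of any real standard should be
configured explicitly — validation tests pin 1.0).

## Synthetic spectra

The generator emits one summed centroid spectrum per sample rather
than an LC–MS map: quantitation operates per peptide on envelope
amplitudes, so a chromatographic dimension would add nothing the
pipeline consumes. For each unique peptide and charge in the design
it places both envelopes at their theoretical m/z (mass accuracy is
exact unless ppm-scale Gaussian jitter is enabled), merges centroids
within 0.005 m/z (below TOF peak spacing, above float noise), then
applies per-centroid multiplicative log-normal noise with the
configured CV (mean-1 parameterization) and a uniform additive
baseline floor. All randomness comes from one `numpy` generator
seeded from the design, so a fixed seed reproduces a spectrum
bit for bit.

What the simulator does *not* emulate: chromatographic coelution and
peak-shape interference, charge-state-dependent response, detector
saturation, chemical background, missing peptides (every unique
peptide is always detectable), and real enrichment heterogeneity.
Passing tests therefore demonstrate the correctness of the
quantitation arithmetic and its noise robustness — not immunity to
these instrument-level effects.

## Peak-pair fitting

For each unique peptide × charge the theoretical positions of both
envelopes (merged within the centroid bin, so interleaving channels
share positions) are matched to observed centroids within a 10 ppm
tolerance (default). A window is kept only if the top 3 peaks of at
least one channel are all matched, preventing one-peak "envelopes"
from passing. Amplitudes solve the non-negative least-squares problem

    observed ≈ amp14·template14 + amp15·template15 + baseline

with a per-window constant baseline estimated jointly (so the
simulator's additive floor cannot bias ratios). Windows of different
peptides that claim the same observed centroid are flagged
overlapping and solved jointly in one NNLS system with a shared
baseline, apportioning shared intensity instead of double-counting it;
overlapping fits are reported but excluded from summary statistics by
default. Signal-to-noise is defined as base-peak intensity over the
fitted baseline (infinite when the baseline fits to zero); the
exclusion rule is `snr ≥ 3 and residual_fraction ≤ 0.3` by default —
the thresholds are configuration, since only the existence of a
low-S/N exclusion step is fixed by the protocol. Rejected fits are
retained with `accepted=False` for audit.

## Quantitation

Spike subtraction acts on the ¹⁵N-normalized ratio scale, per peptide
matched by (sequence, charge): this ordering (normalize, then
subtract) is what makes the standard-curve arithmetic independent of
per-run intensity scale — e.g. 2 pmol gives 12/30 − 10/30 = 2/30
regardless of response factor. Peptides absent from the spike-alone
run fall back to their protein's median spike ratio and are flagged.
Negative corrected ratios are flagged, never clamped: clamping would
bias occupancy upward exactly in the depletion regime where the
biology lives. Per-protein aggregation uses the median across
peptides and charges (mean available); occupancy is the protein median
divided by the reference protein's median, may exceed 1, and values
below 0.1 are flagged as below the validated quantitation limit.
Whole-cell comparisons divide each protein's within-condition
L20-normalized level by its level in a chosen reference condition.
The standard-curve report fits an ordinary least-squares line of
median corrected ratio vs amount and converts each point to r-protein
equivalents via the `reference_amount / spike15_pmol` full-scale ratio.

## Numerical and design choices

- NNLS via `scipy.optimize.nnls`; tests cross-check against an
  exhaustive two-parameter grid search on small windows, including the
  degenerate single-nitrogen case where the channels interleave 1 Da
  apart.
- Centroid matching takes the nearest observed peak within tolerance;
  an empty spectrum yields an empty result, not an error.
- The all-zero window returns zero amplitudes with `accepted=False`.
- A missing reference protein is a hard error — silent renormalization
  to another protein would silently redefine every occupancy.
- L7/L12 exchanges rapidly during particle purification, so when a
  protein set includes it, recovery assertions should exclude it even
  though it is reported.

## Problem sizes

The bundled synthetic proteome draws 8 random ~130-residue proteins
(~150 unique peptides; random sequences with bacterial residue
frequencies stand in for the real r-protein sequences, which are not
bundled). Validation runs use charges {1, 2} and noiseless spectra;
property tests use a 3-protein subset for per-sample loops and 5%
noise where robustness is the claim. These sizes keep a full
digest→simulate→fit→report cycle around a second while exercising
every code path, and all of them scale linearly if larger studies are
configured.
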