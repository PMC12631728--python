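# Methods

## The problem

Stable isotope probing (SIP) feeds organisms isotopically heavy substrates
(¹³C, ¹⁵N, ²H, ¹⁸O, ³⁴S) and reads label incorporation out of mass spectra.
A peptide or metabolite whose carbon pool is, say, 50 atom % ¹³C no longer
shows the familiar natural-abundance isotope pattern: its envelope widens
and shifts by tens of neutrons, and a database-search or annotation tool
that assumes natural abundance cannot recognize it.  `sipsim` simulates
isotopic patterns of formulas and peptides at *any* atom-% enrichment,
scores peptide-spectrum matches (PSMs) against such theory, and estimates
the enrichment level of a PSM from the score-vs-enrichment profile.

## Models and algorithms

### Isotope bookkeeping

Each element carries a list of (nucleon number, exact mass, natural
abundance) from the NIST/CODATA atomic-mass evaluation, shipped as a
plain-text table (`sipsim/data/isotopes.tsv`) users can audit or override.
Natural ¹³C is fixed at 1.07 atom %.  An *enrichment spec* forces one heavy
isotope of one element to a chosen atom fraction; the remaining isotopes of
that element are rescaled in proportion to their natural ratios — the
standard convention for elements with three or more isotopes (O, S), where
the enrichment literature specifies only the labeled isotope's fraction.

The envelope anchor (the "monoisotopic" mass) is defined by composition —
all-lightest isotopes — not by probability, so envelope indexing stays
stable even when the heavy isotope dominates at high enrichment.

Charging uses the proton mass (1.007276466 Da) for [M+zH]z+ and [M−zH]z−;
whether one uses the proton or hydrogen-atom mass is a sub-ppm distinction
at the m/z values of interest, and the constant is exposed in
`sipsim.chem.PROTON_MASS`.

### Fine structure: Monte Carlo and exact enumeration

An isotopologue is identified by its full per-element isotope-count
composition; distinct compositions with nearly equal mass (¹³C vs ¹⁵N
substitutions) remain distinct species — resolving that distinction is the
point of fine structure.  The Monte Carlo generator draws, per simulated
molecule and per element, a multinomial(count, abundances) isotope split,
tallies identical compositions over `n_draws` draws (default 10⁶), and
prunes species below `prune_threshold` (default 1e-8).  A seed is part of
the API — there is no hidden global RNG, and the same seed reproduces the
spectrum bit for bit.

The exact enumerator lists every composition with its multinomial
probability (probabilities sum to 1 to ~1e-14 before pruning) and is the
oracle for both the Monte Carlo sampler and the FFT envelope; it refuses
composition spaces above a configurable cap (10⁶) rather than silently
thrashing.

For display, peaks closer than 0.03 Da are spread apart symmetrically about
their cluster mean (rank order preserved, probabilities and true masses
untouched) — purely a plotting transform, kept in a separate
`display_mass` field.

### Aggregate envelopes by FFT

The aggregate envelope ignores fine structure: it is the distribution of
the total extra-neutron count k.  Each element contributes its single-atom
neutron distribution raised to the count-th convolution power; the
molecular envelope is the product of elemental characteristic functions,
computed with one real FFT per element on a power-of-two grid that covers
the maximal reachable k (so the circular convolution is exact), one
pointwise product, and one inverse FFT.  Values below 1e-12 in magnitude
are clamped to zero to kill ringing; trailing probabilities below 1e-10 are
trimmed; explicit truncation (`max_k`) warns with the lost probability
mass.

Aggregate peaks are placed at the ¹³C–¹²C spacing of 1.003355 Da per
neutron by default, since CHNOPS envelopes are carbon-dominated; the
spacing is a parameter for users who prefer average-mass placement.

### Peptides: residue convolution

A peptide envelope is the convolution of its residue envelopes (dehydrated
compositions of the 20 canonical residues, `sipsim/data/residues.tsv`) plus
terminal H and OH.  Fragment series are built incrementally — b_i's
envelope is b_{i−1}'s convolved with one residue distribution, and likewise
for y from the C-terminus — so all n−1 prefix envelopes cost exactly n−1
convolutions (asserted by an operation counter in tests), not a quadratic
rebuild.  Neutral-fragment conventions: b_i = Σ residues 1..i, y_j = Σ last
j residues + H₂O, protons added only at charging; this makes
b_i + y_{n−i} = precursor exact in both element counts and monoisotopic
mass.  Only b/y series are modeled; a/c/x/z ions, neutral losses, and
variable modifications are out of scope (fixed per-residue formula deltas
can be expressed by editing the residue table).

### PSM scoring

All scorers consume theoretical stick spectra (max intensity 100 per
envelope) and a centroided observed scan.  Matching is greedy in descending
theoretical intensity with a 0.01 Da default tolerance (ppm mode
available); each observed peak is claimable once; ties break to the
smallest m/z error.  When the sticks' tolerance windows are pairwise
disjoint — always true within one envelope, where sticks are ≥ 1/z Da
apart — the greedy assignment decouples and is computed vectorized; the
equivalence with the plain greedy loop is property-tested.

* **WDP** (weighted dot product) scores each envelope as the cosine between
  its stick intensities and the matched observed intensities and sums over
  envelopes, so a proportional match of every stick scores 1 per envelope.
  Two choices matter and both were made for sharpness of the
  score-vs-enrichment profile, the quantity WDP exists to resolve:
  (i) observed intensities enter *linearly* (a matched filter on the
  envelope shape) — a sqrt variance-stabilizing transform is available but
  measurably widens the profile past XCorr's; (ii) cosine normalization
  rather than dividing by the theory self-product, because the latter
  rewards narrower envelopes and produces a deterministic one-grid-step
  argmax bias away from 50%, while by Cauchy–Schwarz the cosine's
  noise-free argmax sits exactly at the generating level.
* **XCorr** is the classic cross-correlation: both spectra binned at
  1.0005079 Da, observed intensities square-rooted and normalized to 50 in
  ten m/z regions, score = dot product at offset zero minus the mean over
  offsets ±75 bins (background subtraction), scaled by 1e-4.
* **MVH** partitions observed peaks into intensity classes (default 3,
  equal counts by rank) and treats matching as drawing one candidate m/z
  bin per theoretical stick without replacement; the score is −ln of the
  multivariate hypergeometric probability of the observed per-class match
  counts.  Candidate bins default to span/(2·tolerance).
* **Spectral entropy similarity** aligns the two spectra by tolerance,
  normalizes to sum 1, and returns 1 − (2·S_mix − S_a − S_b)/ln 4 ∈ [0, 1].

The denoiser keeps the top-N most intense peaks within a sliding m/z
window (defaults 100 Da / top 10) and is optional preprocessing before
visualization or scoring.

### Enrichment profiling

`score_profile` regenerates theoretical precursor + fragment spectra on an
atom-fraction grid (default 0 to 1, step 0.01) and scores each grid point;
`estimate_enrichment` returns the grid argmax (ties to the lowest
fraction) and the full width at half maximum of the min-max-normalized
curve, interpolated linearly between grid points.  FWHM of the normalized
curve is the package's operationalization of "peak width" as a resolution
diagnostic; it is invariant to affine rescaling of the scores.  Because
theory depends only on the peptide and the grid — not the observed scan —
`theoretical_library` can be computed once and scored against many scans.

## Synthetic data

`make_observed` jitters true sticks with Gaussian m/z noise (σ = 0.002 Da
default, well inside the 0.01 Da matching tolerance) and multiplicative
lognormal intensity noise (CV 10%; lognormal keeps intensities positive),
then adds 200 exponential-intensity noise peaks over 100–2000 Th.  The
standard PSM fixture uses the 15-residue peptide HYAHVDCPGHADYVK (76
carbons), precursor charge 2 with b/y fragments at charges 1–2, and
signal-to-noise 10 (noise scale = max stick intensity / 10).  `make_run`
simulates a DDA cycle (each MS1 triggers top-N MS2 scans on its own peaks,
monotone retention times) for run-summary and I/O round-trip testing.

What this emulates — and what it does not: the generator reproduces the
features the scorers are sensitive to (peak positions, envelope shapes,
intensity jitter, a noise floor) but not chromatographic peak shapes,
co-isolation chimeras, missing low-mass fragments, or detector saturation.
Passing recovery tests therefore demonstrates correctness of the estimator
under the stated noise model, not field performance on any particular
instrument.

## Numerical choices and problem sizes

Tolerances: FFT-vs-enumeration and convolution-vs-FFT agreement is asserted
at 1e-9 per envelope index (measured agreement ~1e-11, limited by the
1e-10 tail trim of cached residue envelopes); probability conservation at
1e-9 to 1e-10; monoisotopic complementarity at 1e-9 Da.  Monte Carlo
convergence is checked at 10⁶ draws (total variation vs exact ≈ 4e-4,
asserted < 5e-3).  Recovery experiments run 100 seeded replicates per
enrichment level in the test suite and 25 per level in the acceptance
script; profile-sharpness comparisons run 50 and 10 replicates
respectively — sizes chosen so the full pipeline re-runs comfortably on a
single CPU while keeping binomial uncertainty on the reported rates a few
percent.  All replicate seeds are fixed (tests) or derived from the single
`--seed` argument (acceptance script).

## Known limitations

* Formula strings accept no parenthesized groups, isotope prefixes, or
  charges; adducts other than (de)protonation are unsupported.
* The electron mass is subsumed into the proton-mass charging convention.
* mzML reading covers centroided spectra with the common CV terms (ms
  level, scan start time, selected ion, 32/64-bit float arrays, zlib); it
  is not a general-purpose mzML implementation.
* Enrichment profiling fits one element at a time; mixtures of two
  labeling states in one spectrum are not deconvolved.
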