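# sipsim

Isotopic pattern simulation, PSM scoring, and enrichment estimation for
stable isotope probing (SIP) mass spectrometry.

SIP experiments feed organisms isotopically heavy substrates (¹³C, ¹⁵N,
²H, …) and read label incorporation out of LC–MS/MS data.  A partially
labeled peptide or metabolite no longer shows its natural-abundance
isotope pattern — the envelope widens and shifts by many neutrons — so
annotating and validating such spectra requires simulating theory at
arbitrary atom-% enrichment.  `sipsim` is a Python library (with a thin
CLI) for proteomics and metabolomics researchers who need to:

* simulate **isotopic fine structures** (individual isotopologues with
  exact masses) by Monte Carlo multinomial sampling, with an exact
  enumeration oracle;
* compute **aggregate isotopic envelopes** of any formula at any
  enrichment by FFT convolution of elemental distributions;
* model **peptide precursor and b/y fragment envelopes** by sequential
  convolution of residue envelopes (n−1 convolutions for all n−1 prefix
  fragments);
* **score peptide-spectrum matches** with four functions — WDP (weighted
  dot product), XCorr (cross-correlation), MVH (multivariate
  hypergeometric), and spectral entropy similarity;
* **estimate the enrichment level** of a PSM from its score-vs-enrichment
  profile, with FWHM peak-width diagnostics;
* read/write **FT2, MGF, mzML** spectra and Sipros-style **PSM TSV**
  tables, summarize LC–MS/MS runs, and render mirror/fine-structure/run
  plots.

## The core model

For a formula with element counts n_e, the aggregate envelope is the
distribution of the total extra-neutron count
K = Σ_e Σ_{atoms} (A − A_lightest), the convolution of each element's
single-atom neutron distribution raised to the n_e-th convolution power —
computed as one inverse FFT of the product of elemental characteristic
functions.  Fine structure refines K into full isotopologue compositions
sampled per element from multinomial(n_e, abundances).  Enrichment at atom
fraction f replaces the heavy isotope's abundance with f and rescales the
rest proportionally.  A peptide is a convolution of residue envelopes, so
fragment envelopes come incrementally.  Scoring compares theory against a
centroided scan within a mass tolerance; scanning the theory over a 0–100%
enrichment grid and taking the score argmax estimates the label level.

## Worked example

```python
from sipsim import natural_table
from sipsim.profile import estimate_enrichment, score_profile
from sipsim.synthetic import standard_psm_fixture

peptide, observed, truth = standard_psm_fixture(enrichment=0.5, seed=11)
profile = score_profile(peptide, observed, natural_table(),
                        scorers=("wdp", "xcorr", "mvh", "entropy"))
for name in ("wdp", "xcorr", "mvh", "entropy"):
    estimate, fwhm = estimate_enrichment(profile, name)
    print(f"{name:>8}  estimate={estimate:.2f}  fwhm={fwhm:.3f}")
```

prints

```
     wdp  estimate=0.50  fwhm=0.291
   xcorr  estimate=0.50  fwhm=0.316
     mvh  estimate=0.50  fwhm=0.922
 entropy  estimate=0.50  fwhm=0.345
```

A synthetic MS2 scan was generated from the peptide HYAHVDCPGHADYVK at a
true ¹³C atom fraction of 0.50 (SNR 10, 200 noise peaks); every scoring
function's profile peaks at (or within one 0.01 grid step of) the truth,
and WDP shows the smallest full width at half maximum — it discriminates
nearby enrichment levels most sharply.  The `examples/` directory holds
one short script per capability (fine structure, FFT envelopes, fragments,
scoring, profiling, run summaries/I/O).

The CLI mirrors the library:

```sh
sipsim envelope --formula C6H12O6 --enrich C13=0.5 --mode neg --charge 1
sipsim fragments --seq HYAHVDCPGHADYVK --enrich C13=0.5 --charges 1,2
sipsim profile --seq HYAHVDCPGHADYVK --spectrum scan.mgf --element C
```

## Layout

* `src/sipsim/` — the library (`chem`, `fine_structure`, `envelope`,
  `peptides`, `scoring`, `profile`, `spectra_io`, `synthetic`, `viz`, `cli`)
* `docs/methods.md` — models, assumptions, parameter defaults, limitations
* `docs/ft2_format.md` — the pinned FT2 dialect with a worked example
* `examples/` — runnable narrative scripts
* `tests/` — pytest suite (unit, property-based, and end-to-end checks)
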