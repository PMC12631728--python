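"""Scoring a peptide-spectrum match with four scoring functions.

Generates a synthetic observed MS2 scan from the standard peptide at 50%
13C (SNR 10, 200 noise peaks), then scores it against theory generated at
the correct level (50%) and at two wrong levels.  The correct hypothesis
wins under every scoring function.
"""

import numpy as np

from sipsim import natural_table
from sipsim.profile import score_spectrum
from sipsim.synthetic import standard_psm_fixture, standard_theoretical

peptide, observed, truth = standard_psm_fixture(enrichment=0.5, seed=42)
print(f"observed scan: {len(observed)} peaks "
      f"(theory + {truth['noise_model'].n_noise_peaks} noise peaks, SNR {truth['snr']:.0f})")

print(f"\n{'theory':>14} {'WDP':>8} {'XCorr':>8} {'MVH':>9} {'entropy':>8}")
for hypothesis in (0.0107, 0.25, 0.5):
    envelopes = standard_theoretical(hypothesis)
    s = score_spectrum(envelopes, observed)
    print(f"{hypothesis:14.4f} {s['wdp']:8.2f} {s['xcorr']:8.2f} "
          f"{s['mvh']:9.1f} {s['entropy']:8.3f}")

# WDP counts (envelope-cosine) matches of every isotopic stick, XCorr is a
# binned cross-correlation with background subtraction, MVH the -ln
# probability of the match pattern, entropy a mixture-entropy similarity.
# All four peak at the generating level, 0.5.
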