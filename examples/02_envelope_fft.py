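"""Aggregate isotopic envelope of a metabolite via FFT convolution.

Computes the [M-H]- stick spectrum of glucose and the [M+H]+ spectrum of
gamma-aminobutyric acid (GABA) at natural abundance and at 50% 13C, and
prints the m/z grid with relative intensities.  The envelope centroid moves
up by ~ (number of carbons) x (atom fraction) neutrons as enrichment rises.
"""

from sipsim import IonSpec, EnrichmentSpec, natural_table, parse_formula
from sipsim.envelope import envelope_fft, envelope_to_sticks

table = natural_table()

cases = [
    ("glucose [M-H]-", "C6H12O6", IonSpec(charge=1, polarity="negative", adduct="deprotonation")),
    ("GABA [M+H]+", "C4H9NO2", IonSpec(charge=1)),
]

for name, text, ion in cases:
    formula = parse_formula(text)
    for label, fraction in [("1.07% 13C", 0.0107), ("50% 13C", 0.5)]:
        enriched = table.enrich(EnrichmentSpec("C", 13, fraction))
        env = envelope_fft(formula, enriched)
        sticks = envelope_to_sticks(env, ion)
        print(f"\n{name} at {label}  (mean extra neutrons = {env.mean_k():.3f})")
        for mz, inten in zip(sticks.mz, sticks.intensity):
            if inten >= 1.0:  # print peaks above 1% of the base peak
                print(f"  m/z {mz:10.4f}   {inten:6.1f}")

# At natural abundance the monoisotopic peak dominates; at 50% 13C the
# base peak sits near k = n_C/2 extra neutrons and the envelope is much
# wider -- the signature a SIP experiment looks for.
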