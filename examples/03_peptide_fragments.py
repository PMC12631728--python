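"""Precursor and b/y fragment envelopes of a SIP-labeled peptide.

Models the 15-residue peptide HYAHVDCPGHADYVK (76 carbons) at natural
abundance and 50% 13C: the +3 precursor envelope and a selection of b/y
fragment envelopes at charge 1.  Prints each envelope's base-peak m/z and
the number of sticks above 1% relative intensity.
"""

from sipsim import EnrichmentSpec, IonSpec, natural_table
from sipsim.peptides import Peptide, fragment_envelopes, peptide_formula, precursor_envelope

peptide = Peptide("HYAHVDCPGHADYVK")
table = natural_table()
print("peptide formula:", peptide_formula(peptide))

for label, fraction in [("1.07% 13C", 0.0107), ("50% 13C", 0.5)]:
    enriched = table.enrich(EnrichmentSpec("C", 13, fraction))
    prec = precursor_envelope(peptide, enriched, IonSpec(charge=3))
    base = prec.mz[prec.intensity.argmax()]
    print(f"\n{label}: precursor +3 base peak at m/z {base:.4f}, "
          f"{(prec.intensity >= 1).sum()} sticks >= 1%")

    frags = fragment_envelopes(peptide, enriched, charges=(1,))
    for series, index in [("b", 2), ("b", 7), ("y", 5), ("y", 12)]:
        fr = frags.get(series, index, 1)
        base = fr.sticks.mz[fr.sticks.intensity.argmax()]
        print(f"  {fr.label:>6}: base peak m/z {base:9.4f}, "
              f"{(fr.sticks.intensity >= 1).sum():2d} sticks >= 1%")

# Under enrichment every fragment's base peak shifts up in m/z by roughly
# (its carbon count) x (atom fraction) x 1.003355 / charge, and envelopes
# widen -- larger fragments shift more, which is how fragment envelopes
# pin down both the identification and the label level.
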