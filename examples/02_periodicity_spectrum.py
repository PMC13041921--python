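"""Tandem periodicity of a subterminal satellite array.

Builds a ~60 kb array of a single 171 bp monomer with 2% substitutions and
computes its k-mer recurrence-interval spectrum: the dominant period is the
monomer length, and the overtone at twice the period reflects k-mers broken
once per repeat unit.
"""

from satarch.periodicity import dominant_period, ntr_spectrum
from satarch.synthetic import ArraySpec, make_monomer_library, synthesize_array

lib = make_monomer_library(1, 171, 0.2, seed=42)
seq, truth = synthesize_array(lib, ArraySpec(("fam1",), 351, 0.02, 0.0, seed=42))
print(f"array length: {len(seq)} bp ({len(truth.records)} planted monomers)")

spectrum = ntr_spectrum(seq, k=21, max_period=3000)
print(f"k-mers with >=2 occurrences: {spectrum.n_kmers_used}")
print("top periods (bp -> interval count):")
for period, score in dominant_period(spectrum, 5):
    print(f"  {period}\t{score}")

top = dominant_period(spectrum, 1)[0][0]
print(f"\ndominant tandem period: {top} bp — the planted monomer unit length")
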