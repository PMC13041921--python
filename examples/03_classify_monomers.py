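"""Alpha-satellite monomer classification and array annotation.

Builds a centromere-like layout — an inactive flank of an older subfamily,
a large active dimeric array of two ~170 bp monomer types (S3/S4), and a
second inactive flank — then segments monomers, classifies them against
trained profiles, and merges same-family runs into layered arrays.
"""

import numpy as np

from satarch.periodicity import segment_monomers
from satarch.satclass import annotate_satellite_arrays, classify_monomers, train_profiles
from satarch.synthetic import ArraySpec, make_monomer_library, mutate_sequence, synthesize_array

rng = np.random.default_rng(5)
active_lib = make_monomer_library(2, 170, 0.20, seed=5, names=["S3", "S4"])
flank_lib = make_monomer_library(1, 170, 0.20, seed=6, names=["SF1-5"])

flank, _ = synthesize_array(flank_lib, ArraySpec(("SF1-5",), 30, 0.02, 0.0, seed=7))
core, _ = synthesize_array(active_lib, ArraySpec(("S3", "S4"), 100, 0.02, 0.0, seed=8))
chrom = flank + core + flank

training = {
    fam: [mutate_sequence(cons, 0.02, 0.001, rng) for _ in range(25)]
    for lib in (active_lib, flank_lib)
    for fam, cons in lib.families
}
profiles = train_profiles(training)

monomers = segment_monomers(chrom, 170, phase_anchor=active_lib.consensus("S3"),
                            sequence_name="chr17")
assignments = classify_monomers(monomers, profiles)
print(f"monomers segmented/classified: {len(assignments)}")

# merge at the subfamily level: S3+S4 alternate within one SF1-1-like array
grouped = [
    a.__class__(a.monomer, "SF1-1" if a.family in ("S3", "S4") else a.family,
                a.score, a.margin, a.strand)
    for a in assignments
]
arrays = annotate_satellite_arrays(grouped, min_array_monomers=10, max_gap=500)
print("annotated satellite arrays (family, span, monomers, layer):")
for arr in arrays:
    print(f"  {arr.family}\t{arr.start}-{arr.end}\t{arr.n_monomers}\t{arr.layer}")
# The large central array is the active centromere layer; the two flanking
# SF1-5 arrays are relics of an older centromere generation.
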