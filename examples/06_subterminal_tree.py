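"""Subterminal satellite homogenization across chromosomes.

Samples monomers from subterminal arrays on four chromosomes generated from
one shared 171 bp consensus, builds a neighbor-joining tree, and asks
whether monomers cluster by chromosome. Arrays homogenized independently
per chromosome would cluster (low p); arrays exchanging monomers through
ectopic recombination would not (high p).
"""

import numpy as np

from satarch.satclass import build_tree, homogenization_test
from satarch.synthetic import make_monomer_library, mutate_sequence

lib = make_monomer_library(1, 171, 0.2, seed=31)
consensus = lib.consensus("fam1")
rng = np.random.default_rng(31)

# all chromosomes draw monomers from the same consensus pool: the exchange
# (no per-chromosome homogenization) scenario
sequences, labels = [], {}
for chrom in ("chr14", "chr15", "chr17", "chr19"):
    for i in range(8):
        name = f"{chrom}_m{i}"
        sequences.append((name, mutate_sequence(consensus, 0.03, 0.001, rng)))
        labels[name] = chrom

tree = build_tree(sequences)
stat, p = homogenization_test(tree, labels, n_permutations=999, seed=32)
print(f"taxa: {len(sequences)} monomers from {len(set(labels.values()))} chromosomes")
print(f"nearest-neighbor label concordance: {stat:.3f}")
print(f"permutation p-value: {p:.3f}")
print(
    "\nhigh p: no detectable chromosome-specific homogenization — monomer"
    "\nvariants are shared across chromosomes, as expected under persistent"
    "\nectopic exchange between subterminal arrays"
)
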