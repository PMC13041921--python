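# satarch

Satellite-DNA and acrocentric-chromosome architecture toolkit for primate
genomes: tandem-repeat periodicity spectra, alpha-satellite monomer
classification, higher-order-repeat (HOR) detection, pseudo-homologous
region (PHR) calling, and rDNA copy-number/activity analysis — with a
synthetic-genome generator that plants ground truth for every stage.

## Who this is for

Researchers analyzing the repeat-rich compartments that telomere-to-telomere
assemblies finally make accessible: centromeric alpha-satellite arrays,
subterminal satellite blocks, and the satellite-rich short arms of
acrocentric chromosomes that carry ribosomal DNA (rDNA) arrays. The package
is organized around the repeat architecture of the common marmoset, a New
World monkey whose centromeres are built from dimers of two ~170 bp
alpha-satellite monomer types (S3/S4), whose chromosome ends carry a
conserved 171 bp subterminal satellite, and whose acrocentric short arms
share >99%-identity segments (PHRs) and variably host rDNA — but every
stage is parameterized and works on any FASTA.

## The methods at the core

**Periodicity spectrum.** For every k-mer occurring ≥ 2 times in a
sequence, the distances between consecutive occurrences are tallied into a
score per period p; a tandem array of unit length u piles counts onto u and
its multiples. The dominant period of an alpha dimer array is 2u (≈ 340 bp)
with a sub-peak at u; a monomeric subterminal array peaks at its 171 bp
unit. The spectrum is invariant under reverse complement.

**Monomer classification.** Monomers segmented from an array are scored
against position-specific log-odds profiles, one per satellite
family/subfamily: `S(m, f) = Σ_i log( P_f(i, m_i) / 0.25 )`, both strands,
with an assignment margin below which a monomer is "ambiguous". Runs of
same-family monomers merge into arrays; the largest array in the declared
centromere window is the active layer, the rest are inactive flanking
relics. Per-array dimer consensuses cluster (single linkage at ≥ 99%
identity) into centromere-specific dimer haplotypes (dimhaps), and
chromosome-specific k-mer signatures are the canonical k-mers exclusive to
one active array.

**HOR detection.** On the ordered class string of an array, a unit size
`u` is supported by the fraction of positions i with class[i] ==
class[i+u]; sizes reaching 0.8 support are reported unless they are
multiples of a smaller reported size. A dimer reports u = 2; the X-like
HOR array reports u = 28.

**PHR calling.** Windows of one arm are placed on the other by infix
alignment (both orientations); windows at ≥ 99% gap-inclusive identity are
chained when collinear, boundaries are refined by block extension, and
chains spanning ≥ 10 kb on both arms are PHRs. Pairwise sharing aggregates
into a network whose edges carry shared bp and bp-weighted identity.

**rDNA quantification.** With the diploid convention (a single-copy locus
= 2 copies per genome), the total copy number is
`2 × depth(rDNA) / depth(single-copy)`; integer copies per array follow
from fractional fluorescence intensities by largest-remainder rounding,
which conserves the rounded total exactly. Arrays are active when the
coding-region methylated fraction is below 0.5 (the intergenic spacer
stays methylated in both states); centromere dip regions (CDRs) are
sustained methylation dips inside active alpha arrays; sex differences in
diploid copy number are tested by a rank-sum statistic with a permutation
null.

## Worked example

`examples/05_rdna_copy_number.py` builds an acrocentric arm with 10 tandem
rDNA units (one degraded by a planted 400 bp insertion), simulates depth
and methylation tracks for a diploid total of 282 copies, and runs the
full rDNA analysis:

```
rDNA units detected: 10 (9 intact, 1 degraded)
estimated diploid total from depth ratio: 281.8 copies
copies allocated to the Y array: 38 (total conserved: 282)
activity call: active (coding methylation 0.10, IGS 0.80)
sex comparison: male mean 507 vs female mean 403, permutation p = 0.0001
```

Reading: unit detection recovered the planted composition including the
retroelement-like disruption; the depth-ratio estimate lands within 0.1%
of the planted 282; the array holding 13.5% of the fluorescence signal is
allocated 38 copies with the genome total conserved exactly; low coding
methylation (0.10) against a methylated IGS (0.80) marks the array
transcriptionally active; and the simulated cohort shows the male-biased
copy number that a Y-linked array produces. The other examples
(`examples/01`–`06`) walk through genome synthesis, periodicity,
classification/layering, PHR networks and the subterminal homogenization
test the same way.

A one-command pipeline over the default synthetic genome:

```sh
satarch run --outdir out --seed 1     # simulate → periodicity → classify → phr → rdna
satarch periodicity --fasta out/genome.fa
```

`out/report.json` records per-stage counts, parameters and the seed; a
rerun with the same seed reproduces byte-identical artifacts.

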