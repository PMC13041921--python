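# Methods

This note records the models, parameter choices and numerical decisions
behind each stage, what the synthetic data does and does not emulate, and
the known limitations.

## Synthetic genomes and planted truth

The generator is the package's experimental substrate: every analysis stage
is validated by recovering what the generator planted. A monomer library is
built by mutating a random ancestor once per family at a per-branch
substitution rate calibrated so the *expected* pairwise Hamming divergence
between families equals the request (each site differs if exactly one
branch mutates, or both mutate to different bases: solving
(4/3)r² − 2r + D = 0 for r). A bounded, seed-deterministic resampling loop
keeps the draw whose pairwise divergences deviate least from the target.
For two families the realized divergence lands within ±20% of the request
essentially always; for many families (e.g. 28 classes over 170 bp) single
pairs fluctuate by sampling noise and only the mean is guaranteed near the
target — a fundamental property of short monomers, not a tuning choice.

Arrays are emitted monomer by monomer: consensus, then per-base
substitutions, then single-base indels capped at ±3 bp net per monomer so
lengths stay near nominal and segmentation remains well-posed. Defaults —
2% substitutions, 0.2% indels — reflect the within-array divergence regime
of young, homogenized satellite arrays. Acrocentric arms are ordered
feature lists (telomere → centromere): subterminal satellite blocks,
transposable-element-like random spacers, shared-segment donors copied
verbatim and mutated at half the divergence per copy (two independently
mutated copies drift apart at twice the per-copy rate), and rDNA arrays of
coding + intergenic spacer (IGS) units with the promoter on the telomere
side so transcription points toward the centromere. Degraded units carry a
planted random insertion inside the coding region.

Depth and methylation tracks are binned Gaussians. The diploid convention
sets the single-copy baseline at 2 copies per genome, so rDNA-region bins
scale by `total_copies / 2` (standard deviation scales by the square root
of the factor, Poisson-like). Methylation bins fluctuate (σ = 0.05) around
a per-feature-class state; bin class assignment is by majority overlap with
ties resolved by the order classes are listed, letting a nested feature
(e.g. a planted CDR inside an alpha array) take precedence.

What the generator does **not** emulate: read-level noise (no FASTQ or
error models), GC or mappability bias in depth, satellite
higher-order-structure turnover, heterogeneous unit lengths within one
family beyond small indels, and rDNA promoter/28S/18S substructure. Tests
passing on this substrate therefore demonstrate algorithmic correctness
under the stated repeat architecture, not robustness to sequencing
artifacts of real data.

## Periodicity spectrum

For every k-mer with ≥ 2 occurrences, consecutive-occurrence distances up
to `max_period` are tallied (N-containing k-mers are excluded). Defaults
k = 21, max_period = 3000: k = 21 is specific enough that a 171 bp monomer
at 2% divergence still contributes (P(intact 21-mer) ≈ 0.98²¹ ≈ 0.65 per
copy) and 3000 bp spans monomer through multi-monomer periods; HOR search
operates on the class string, not the raw spectrum, so larger periods are
unnecessary. The spectrum is reverse-complement invariant by construction
(intervals of a k-mer in s equal intervals of its reverse complement in
the reverse complement of s).

## Monomer segmentation

Segmentation phases a cut grid on the repeat. Without an external
reference, the anchor is the k-mer recurring most often at the requested
period (±3 bp); gaps where divergence broke the anchor are split evenly
into round(gap/period) monomers; the grid is shifted so tiling starts at
the array origin (the anchor's offset within its monomer is arbitrary —
any rotation tiles equally well; ties prefer the earliest-starting
anchor). A leading/trailing partial unit shorter than period/2 is dropped.
With a known monomer as `phase_anchor`, the k-mer grid is replaced by the
anchor's actual placements from an iterated masked infix search, which is
dense even in multimeric arrays (where exact k-mers recurring at the
monomer period are rare) and puts cuts on true monomer boundaries —
required when classification must see unrotated monomers.

Consensus building is a star alignment to the longest monomer with
column-wise majority (alphabetical tie-break; a column is dropped only
when gaps strictly outnumber every base). This is adequate at the
divergences modeled; it is not a substitute for full multiple alignment at
high divergence.

## Classification, arrays, dimhaps, signatures

Profiles are ungapped position-specific log-odds matrices over a
median-length training reference with uniform background; small indels are
absorbed by projecting each monomer onto the reference through a global
alignment (deleted columns contribute the column's worst log-odds;
inserted bases are ignored). Pseudocount 0.01; with pseudocount 0 an
unseen base scores −∞, which is the documented smoothing boundary.
min_margin = 2.0 log-odds units separates confident calls from
"ambiguous"; classification is per-monomer and thus order-independent,
with lexicographic tie-breaks.

Array annotation merges same-family runs with inter-monomer gaps ≤ max_gap
(default 1000 bp) and drops runs below min_array_monomers (default 10).
Exactly one array per declared centromere window is labeled active (the
largest by monomer count); without a window the largest array on the
sequence is active. The pipeline additionally smooths isolated
single-monomer discordant calls between two same-group neighbors before
merging — a boundary-slip call would otherwise fragment one array.

Dimhaps are single-linkage clusters of per-array dimer consensuses at
≥ 99% gap-inclusive identity (the same identity scale as PHR calling);
specificity is the fraction of member arrays on the modal chromosome, and
the reported consensus is the cluster medoid. K-mer signatures use
canonical k-mers (k = 31, min_copies = 2) exclusive to one active array;
output sets are disjoint by construction and asserted on every run.

## Trees and the homogenization test

Tree distances are 1 − gap-inclusive global-alignment identity;
neighbor-joining (scikit-bio) with negative branch lengths clamped to
zero. NJ recovers the generating topology on additive matrices, which the
tests verify with mutation-disjoint synthetic clades.

The homogenization statistic is the fraction of taxa whose nearest
neighbor by patristic distance (ties broken by taxon name) shares the
chromosome label. The permutation p-value uses randomized tie-breaking:
equal statistic values are ordered through an auxiliary uniform draw. The
match fraction takes few distinct values, so without tie-breaking the
permutation p-value is conservative (super-uniform) and fails a
uniformity check under the null; the randomized form is exact. Null
calibration is verified over 200 simulations of 30 taxa / 3 chromosomes
with 199 permutations each — sizes chosen so the discrete statistic has
enough levels for the type-I band to be meaningful at small problem sizes.

## PHR calling

Identity is matches / aligned columns *including gap columns* everywhere —
the strictest reproducible definition. Windows (default 5 kb, step 2.5 kb;
both orientations) are placed by infix alignment. Calling filters windows
by identity **before** chaining: chaining first and filtering the chain
would let adjacent lower-identity repeat hits dilute a genuine ≥ 99%
segment below threshold, which loses true PHRs whenever they abut other
repeats. Passing windows merge when collinear within one window on both
sequences; merged spans must reach 10 kb on both arms (the 99%/10 kb rule).
Boundaries are then refined by 250 bp block extension — window
quantization otherwise clips up to half a window per end — where each
block is accepted at the identity threshold minus a two-sigma binomial
allowance (a 250 bp block is a noisy estimate of local identity; a
genuinely shared flank at threshold keeps extending while unrelated flank
sequence at ~50% identity stops immediately), and the final call's
identity is recomputed over its full span and re-filtered. Inverted
sharing is reported with orientation "−". The self-identity matrix applies
the same alignment contract to all pairs of non-overlapping windows of one
sequence.

## rDNA

Unit detection is two-phase: (1) iterated best-hit infix search for the
coding consensus (either strand) with masking, down to 80% identity; (2)
whole-unit re-alignment of coding + IGS over the region pinned between
consecutive coding hits, so an insertion inside the unit cannot be skipped
by a shifted placement. Disruptions are runs of aligned columns whose
51-column windowed match fraction stays below 0.7 (random insert sequence
aligned to consensus hovers near 50% through accidental matches; genuine
unit sequence stays above 90% at the divergences modeled); nearby dips
merge, the half-window smear is trimmed, and runs ≥ min_insertion
(default 100 bp) flag the unit degraded. Reported disruption spans bracket
the true insert within about one smoothing window per end.

Copy number is `2 × mean depth(rDNA) / mean depth(single-copy)` with ≥ 50
bins required per region; allocation is largest-remainder rounding
(remainder ties break by larger fraction, then array id), the unique
standard rule conserving the rounded total. Activity: coding methylated
fraction < 0.5 ⇒ active (the IGS stays methylated in both states and is
reported but unused). CDRs: an 11-bin moving mean seeds runs below
dip_factor × array mean (default 0.5), run edges are refined on the raw
bins because smoothing blurs dip boundaries by about half the smoothing
window, and refined runs ≥ 10 kb are reported. The sex comparison is a
centered rank-sum statistic with a two-sided permutation p-value; group
means report direction. Null calibration: 200 simulations of 12 vs 12,
199 permutations.

## Pipeline and problem sizes

The pipeline's default genome has four chromosomes (~320 kb total): two
acrocentric-like arms sharing a 15 kb segment at 99.5% identity (one with
an 8-unit rDNA array containing one degraded unit), one vacant arm, and an
X-like chromosome with a 28-class HOR array repeated 15 times. Test and
acceptance runs use array sizes of 50–350 units, 60 kb arms and 200-draw
calibration loops — sizes at which every recovery target is stable across
seeds while a full run stays interactive. All randomness flows from one
top-level seed; reruns are byte-identical.

## Known limitations

- The profile classifier is ungapped; it degrades for satellites with
  structural (indel-rich) family differences.
- Segmentation assumes a dominant period; nested or mixed-period arrays
  need per-block segmentation.
- PHR windowed placement reports one best location per window; dispersed
  multi-copy sharing within one arm is summarized, not enumerated.
- The depth model has no GC/mappability structure, so the copy-number
  estimator's real-data accuracy is bounded by biases the simulation does
  not contain.
- Insertion positions inside degraded rDNA units are resolved to ~50 bp,
  not base pair, precision.
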