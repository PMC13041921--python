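"""Synthetic chromosomes and arms with planted satellite/rDNA ground truth.

Every downstream stage of the toolkit (periodicity, classification, PHR
calling, rDNA quantification) is exercised against genomes produced here, so
the generator emits, alongside each sequence, a :class:`SyntheticTruth` table
recording every planted monomer, rDNA unit, shared segment and spacer.

The defaults emulate the repeat architecture of a New World monkey genome:
dimeric centromeric alpha-satellite arrays built from two ~170 bp monomer
types with layered inactive flanks, a 28-monomer higher-order repeat array,
subterminal arrays of a 171 bp monomer interspersed with transposable-
element-like spacers, acrocentric short arms sharing high-identity segments,
and tandem rDNA units (coding + intergenic spacer) oriented from telomere
toward centromere, including degraded units carrying retroelement-like
insertions.

Coordinates are 0-based half-open (BED convention) everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._align import revcomp
from .errors import ParameterError, PlanError

BASES = np.array(list("ACGT"))

__all__ = [
    "MonomerLibrary",
    "ArraySpec",
    "TruthRecord",
    "SyntheticTruth",
    "TrackSpec",
    "SatelliteFeature",
    "RdnaUnitModel",
    "RdnaFeature",
    "PhrDonorFeature",
    "SpacerFeature",
    "ChromosomePlan",
    "GenomePlan",
    "make_monomer_library",
    "synthesize_array",
    "synthesize_acrocentric_arm",
    "synthesize_genome",
    "simulate_depth_track",
    "random_dna",
    "mutate_sequence",
    "default_genome_plan",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class MonomerLibrary:
    """Named monomer consensus sequences (one per satellite family)."""

    families: tuple[tuple[str, str], ...]  # (family_name, consensus)
    seed: int

    def __post_init__(self) -> None:
        names = [n for n, _ in self.families]
        if len(set(names)) != len(names):
            raise ParameterError("family names must be unique")
        for name, cons in self.families:
            if set(cons) - set("ACGT"):
                raise ParameterError(f"family {name}: consensus alphabet must be ACGT")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.families]

    def consensus(self, name: str) -> str:
        for n, c in self.families:
            if n == name:
                return c
        raise LookupError(f"unknown monomer family: {name!r}")


@dataclass(frozen=True)
class ArraySpec:
    """Recipe for one tandem satellite array.

    unit_pattern lists the family names of one repeat unit in order — e.g.
    ``["S3", "S4"]`` for a dimer or 28 names for a higher-order repeat unit.
    """

    unit_pattern: tuple[str, ...]
    n_units: int
    substitution_rate: float = 0.02
    indel_rate: float = 0.002
    strand: str = "+"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.unit_pattern:
            raise ParameterError("unit_pattern must be non-empty")
        if self.n_units < 1:
            raise ParameterError("n_units must be >= 1")
        for rate in (self.substitution_rate, self.indel_rate):
            if not 0.0 <= rate <= 0.25:
                raise ParameterError("rates must lie in [0, 0.25]")
        if self.strand not in ("+", "-"):
            raise ParameterError("strand must be '+' or '-'")


@dataclass(frozen=True)
class TruthRecord:
    sequence_name: str
    start: int
    end: int
    feature_class: str
    strand: str = "+"
    attributes: tuple[tuple[str, str], ...] = ()

    def attr(self, key: str, default: str | None = None) -> str | None:
        return dict(self.attributes).get(key, default)


@dataclass
class SyntheticTruth:
    """Planted annotations, sorted by (sequence_name, start)."""

    records: list[TruthRecord] = field(default_factory=list)

    def sort(self) -> None:
        self.records.sort(key=lambda r: (r.sequence_name, r.start, r.end))

    def validate(self, seq_lengths: dict[str, int] | None = None) -> None:
        self.sort()
        last_end: dict[tuple[str, str], int] = {}
        for r in self.records:
            if not 0 <= r.start < r.end:
                raise PlanError(f"bad interval {r}")
            if seq_lengths is not None and r.end > seq_lengths[r.sequence_name]:
                raise PlanError(f"record beyond sequence end: {r}")
            key = (r.sequence_name, r.feature_class)
            if r.start < last_end.get(key, 0):
                raise PlanError(f"overlapping records of class {r.feature_class}")
            last_end[key] = r.end

    def of_class(self, feature_class: str) -> list[TruthRecord]:
        return [r for r in self.records if r.feature_class == feature_class]

    def shifted(self, offset: int, sequence_name: str | None = None) -> "SyntheticTruth":
        return SyntheticTruth(
            [
                TruthRecord(
                    sequence_name if sequence_name is not None else r.sequence_name,
                    r.start + offset,
                    r.end + offset,
                    r.feature_class,
                    r.strand,
                    r.attributes,
                )
                for r in self.records
            ]
        )


@dataclass(frozen=True)
class TrackSpec:
    """Parameters of simulated depth and methylation tracks.

    mean_depth is the single-copy (diploid, 2-copies-per-genome) read depth;
    methylation_states maps a truth feature class to the methylated fraction
    its bins fluctuate around (e.g. ``{"rdna_coding": 0.1, "rdna_igs": 0.8}``).
    """

    mean_depth: float = 30.0
    noise_sd: float = 2.0
    methylation_states: tuple[tuple[str, float], ...] = ()
    bin_size: int = 500
    background_methylation: float = 0.5
    methylation_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ParameterError("mean_depth must be > 0")
        if self.bin_size < 1:
            raise ParameterError("bin_size must be >= 1")
        for cls, frac in self.methylation_states:
            if not 0.0 <= frac <= 1.0:
                raise ParameterError(f"methylation fraction for {cls} outside [0,1]")


# ---------------------------------------------------------------------------
# plan features for acrocentric arms / whole chromosomes


@dataclass(frozen=True)
class SatelliteFeature:
    """A tandem satellite array block (per-monomer truth plus a block record)."""

    label: str
    library: str  # name of a library in the genome plan
    spec: ArraySpec


@dataclass(frozen=True)
class RdnaUnitModel:
    coding: str
    igs: str

    def __post_init__(self) -> None:
        if not self.coding or not self.igs:
            raise ParameterError("rDNA unit model consensuses must be non-empty")

    @property
    def unit_length(self) -> int:
        return len(self.coding) + len(self.igs)


@dataclass(frozen=True)
class RdnaFeature:
    """A tandem rDNA array: n_units × (coding + IGS), telomere-side promoter.

    degraded maps unit index -> (offset within coding, insertion length);
    those units receive a random insertion and are flagged intact=False.
    """

    label: str
    model: RdnaUnitModel
    n_units: int
    substitution_rate: float = 0.005
    degraded: tuple[tuple[int, tuple[int, int]], ...] = ()

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ParameterError("rDNA array needs >= 1 unit")
        for idx, (off, length) in self.degraded:
            if not 0 <= idx < self.n_units:
                raise PlanError(f"degraded unit index {idx} out of range")
            if not 0 <= off < len(self.model.coding) or length < 1:
                raise PlanError("degraded insertion outside coding region")


@dataclass(frozen=True)
class PhrDonorFeature:
    """A segment copied verbatim from a donor then mutated to a target identity.

    Planting the same donor on two arms creates a pseudo-homologous region
    whose pairwise identity is ~``2×(1−identity)`` below 1 if both copies are
    mutated, so the per-copy rate is halved to hit the requested value.
    """

    label: str
    donor: str
    identity: float = 0.995

    def __post_init__(self) -> None:
        if not 0.5 <= self.identity <= 1.0:
            raise ParameterError("PHR identity must lie in [0.5, 1]")
        if not self.donor:
            raise ParameterError("PHR donor sequence must be non-empty")


@dataclass(frozen=True)
class SpacerFeature:
    """Random non-satellite spacer (transposable-element-like interruption)."""

    length: int
    label: str = "spacer"

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ParameterError("spacer length must be >= 1")


Feature = SatelliteFeature | RdnaFeature | PhrDonorFeature | SpacerFeature


@dataclass(frozen=True)
class ChromosomePlan:
    """Ordered features, telomere -> centromere (left to right)."""

    name: str
    features: tuple[Feature, ...]


@dataclass(frozen=True)
class GenomePlan:
    libraries: tuple[tuple[str, MonomerLibrary], ...]
    chromosomes: tuple[ChromosomePlan, ...]
    seed: int = 0

    def library(self, name: str) -> MonomerLibrary:
        for n, lib in self.libraries:
            if n == name:
                return lib
        raise LookupError(f"plan references undefined monomer library: {name!r}")


# ---------------------------------------------------------------------------
# primitives


def random_dna(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(BASES, size=length))


def _substitute(seq: str, positions: np.ndarray, rng: np.random.Generator) -> str:
    arr = np.array(list(seq))
    for p in positions:
        choices = [b for b in "ACGT" if b != arr[p]]
        arr[p] = choices[rng.integers(3)]
    return "".join(arr)


def mutate_sequence(
    seq: str,
    substitution_rate: float,
    indel_rate: float,
    rng: np.random.Generator,
    max_net_indel: int | None = 3,
) -> str:
    """Apply per-base substitutions then single-base indels.

    Indels are single-base insertions/deletions; the net length change is
    capped at ±max_net_indel so monomer lengths stay near nominal.
    """
    n = len(seq)
    if substitution_rate > 0:
        hits = np.flatnonzero(rng.random(n) < substitution_rate)
        if hits.size:
            seq = _substitute(seq, hits, rng)
    if indel_rate > 0:
        out = []
        net = 0
        for ch in seq:
            if rng.random() < indel_rate:
                if rng.random() < 0.5:  # insertion before this base
                    if max_net_indel is None or net < max_net_indel:
                        out.append(str(rng.choice(BASES)))
                        net += 1
                    out.append(ch)
                else:  # deletion of this base
                    if max_net_indel is None or net > -max_net_indel:
                        net -= 1
                    else:
                        out.append(ch)
            else:
                out.append(ch)
        seq = "".join(out)
    return seq


def _hamming_divergence(a: str, b: str) -> float:
    return sum(x != y for x, y in zip(a, b)) / len(a)


def _branch_rate(divergence: float) -> float:
    """Per-branch substitution rate whose expected pairwise divergence between
    two independent descendants equals `divergence`.

    Sites differ when exactly one branch mutates (prob 2r(1−r)) or both mutate
    to different bases (prob r²·2/3); solving (4/3)r² − 2r + D = 0 for the
    smaller root.
    """
    return (2.0 - math.sqrt(4.0 - 16.0 * divergence / 3.0)) / (8.0 / 3.0)


def make_monomer_library(
    n_families: int,
    monomer_length: int,
    inter_family_divergence: float,
    seed: int,
    names: list[str] | None = None,
) -> MonomerLibrary:
    """Generate n_families monomer consensuses at a target pairwise divergence.

    All families descend from one random ancestor, each mutated at a
    back-mutation-corrected branch rate so the expected pairwise Hamming
    divergence equals the request. A bounded resampling loop keeps the draw
    whose pairwise divergences deviate least from the target.
    """
    if n_families < 1:
        raise ParameterError("n_families must be >= 1")
    if monomer_length < 1:
        raise ParameterError("monomer_length must be >= 1")
    if not 0.0 < inter_family_divergence < 0.5:
        raise ParameterError("inter_family_divergence must lie in (0, 0.5)")
    if names is not None and len(names) != n_families:
        raise ParameterError("names must match n_families")

    rng = np.random.default_rng(seed)
    ancestor = random_dna(monomer_length, rng)
    if n_families == 1:
        fams = ((names[0] if names else "fam1", ancestor),)
        return MonomerLibrary(families=fams, seed=seed)

    rate = _branch_rate(inter_family_divergence)
    n_mut = rate * monomer_length
    best: list[str] | None = None
    best_dev = math.inf
    for _ in range(25):
        cands = []
        for _i in range(n_families):
            k = int(round(rng.normal(n_mut, math.sqrt(n_mut * (1 - rate)))))
            k = min(max(k, 0), monomer_length)
            pos = rng.choice(monomer_length, size=k, replace=False)
            cands.append(_substitute(ancestor, pos, rng))
        devs = [
            abs(_hamming_divergence(a, b) - inter_family_divergence)
            for i, a in enumerate(cands)
            for b in cands[i + 1 :]
        ]
        dev = max(devs)
        if dev < best_dev:
            best_dev, best = dev, cands
        if dev <= 0.2 * inter_family_divergence:
            break
    assert best is not None
    fam_names = names if names else [f"fam{i + 1}" for i in range(n_families)]
    return MonomerLibrary(families=tuple(zip(fam_names, best)), seed=seed)


# ---------------------------------------------------------------------------
# array / arm / genome synthesis


def synthesize_array(
    library: MonomerLibrary,
    spec: ArraySpec,
    sequence_name: str = "array",
) -> tuple[str, SyntheticTruth]:
    """Emit a tandem array of the unit pattern with per-monomer truth records.

    Each monomer is the family consensus mutated independently at the ArraySpec's
    substitution/indel rates. strand='-' reverse-complements the emitted
    sequence; truth coordinates refer to the emitted sequence with strand '-'.
    """
    consensuses = {name: library.consensus(name) for name in spec.unit_pattern}
    rng = np.random.default_rng(spec.seed)
    parts: list[str] = []
    records: list[TruthRecord] = []
    pos = 0
    for unit_idx in range(spec.n_units):
        for fam in spec.unit_pattern:
            mono = mutate_sequence(
                consensuses[fam], spec.substitution_rate, spec.indel_rate, rng
            )
            records.append(
                TruthRecord(
                    sequence_name,
                    pos,
                    pos + len(mono),
                    fam,
                    "+",
                    (("unit", str(unit_idx)),),
                )
            )
            parts.append(mono)
            pos += len(mono)
    seq = "".join(parts)
    if spec.strand == "-":
        total = len(seq)
        seq = revcomp(seq)
        records = [
            TruthRecord(
                r.sequence_name, total - r.end, total - r.start, r.feature_class,
                "-", r.attributes,
            )
            for r in records
        ]
    truth = SyntheticTruth(records)
    truth.sort()
    return seq, truth


def _emit_satellite(
    feat: SatelliteFeature, plan: GenomePlan, seed: int, name: str
) -> tuple[str, SyntheticTruth]:
    lib = plan.library(feat.library)
    spec = ArraySpec(
        unit_pattern=feat.spec.unit_pattern,
        n_units=feat.spec.n_units,
        substitution_rate=feat.spec.substitution_rate,
        indel_rate=feat.spec.indel_rate,
        strand=feat.spec.strand,
        seed=seed,
    )
    seq, truth = synthesize_array(lib, spec, sequence_name=name)
    truth.records.append(TruthRecord(name, 0, len(seq), feat.label, "+"))
    truth.sort()
    return seq, truth


def _emit_rdna(
    feat: RdnaFeature, rng: np.random.Generator, name: str
) -> tuple[str, SyntheticTruth]:
    degraded = dict(feat.degraded)
    parts: list[str] = []
    records: list[TruthRecord] = []
    pos = 0
    for i in range(feat.n_units):
        coding = mutate_sequence(feat.model.coding, feat.substitution_rate, 0.0, rng)
        insertions: list[tuple[int, int]] = []
        if i in degraded:
            off, length = degraded[i]
            off = min(off, len(coding) - 1)
            coding = coding[:off] + random_dna(length, rng) + coding[off:]
            insertions.append((off, length))
        igs = mutate_sequence(feat.model.igs, feat.substitution_rate, 0.0, rng)
        # promoter/coding at the telomere side: transcription points toward
        # the centromere, matching telomere->centromere rDNA orientation
        unit = coding + igs
        intact = not insertions
        attrs = [("intact", str(intact).lower()), ("unit", str(i))]
        for off, length in insertions:
            attrs.append(("insertion", f"{off}:{length}"))
        records.append(
            TruthRecord(name, pos, pos + len(unit), "rdna_unit", "+", tuple(attrs))
        )
        records.append(TruthRecord(name, pos, pos + len(coding), "rdna_coding", "+"))
        records.append(
            TruthRecord(name, pos + len(coding), pos + len(unit), "rdna_igs", "+")
        )
        parts.append(unit)
        pos += len(unit)
    seq = "".join(parts)
    records.append(TruthRecord(name, 0, len(seq), feat.label, "+"))
    truth = SyntheticTruth(records)
    truth.sort()
    return seq, truth


def _emit_phr_donor(
    feat: PhrDonorFeature, rng: np.random.Generator, name: str
) -> tuple[str, SyntheticTruth]:
    # halve the per-copy divergence: two independently mutated copies drift
    # apart at twice the per-copy rate
    per_copy = (1.0 - feat.identity) / 2.0
    n = len(feat.donor)
    k = int(round(per_copy * n))
    pos = rng.choice(n, size=k, replace=False) if k else np.array([], dtype=int)
    seq = _substitute(feat.donor, pos, rng)
    truth = SyntheticTruth(
        [
            TruthRecord(
                name, 0, len(seq), feat.label, "+",
                (("identity", f"{feat.identity:.4f}"),),
            )
        ]
    )
    return seq, truth


def synthesize_acrocentric_arm(
    arm_plan: list[Feature] | tuple[Feature, ...],
    seed: int,
    name: str = "arm",
    plan: GenomePlan | None = None,
) -> tuple[str, SyntheticTruth]:
    """Assemble an arm from ordered features (telomere -> centromere).

    Satellite features may reference libraries of `plan`; if no GenomePlan is
    given, SatelliteFeature.library may instead be a MonomerLibrary instance.
    """
    labels = [f.label for f in arm_plan if not isinstance(f, SpacerFeature)]
    if len(set(labels)) != len(labels):
        raise PlanError("duplicate feature labels would create overlapping truth")
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    truth = SyntheticTruth()
    pos = 0
    for i, feat in enumerate(arm_plan):
        sub_seed = int(rng.integers(2**31))
        if isinstance(feat, SatelliteFeature):
            if plan is None:
                if not isinstance(feat.library, MonomerLibrary):
                    raise LookupError(
                        "SatelliteFeature.library must be a MonomerLibrary when "
                        "no GenomePlan is supplied"
                    )
                lib_plan = GenomePlan(
                    libraries=(("_inline", feat.library),), chromosomes=()
                )
                feat = SatelliteFeature("_tmp", "_inline", feat.spec)
                seq, sub = _emit_satellite(feat, lib_plan, sub_seed, name)
                # restore the user's label on the block record
                sub.records = [
                    TruthRecord(r.sequence_name, r.start, r.end,
                                arm_plan[i].label if r.feature_class == "_tmp"
                                else r.feature_class,
                                r.strand, r.attributes)
                    for r in sub.records
                ]
            else:
                seq, sub = _emit_satellite(feat, plan, sub_seed, name)
        elif isinstance(feat, RdnaFeature):
            seq, sub = _emit_rdna(feat, rng, name)
        elif isinstance(feat, PhrDonorFeature):
            seq, sub = _emit_phr_donor(feat, rng, name)
        elif isinstance(feat, SpacerFeature):
            seq = random_dna(feat.length, rng)
            sub = SyntheticTruth(
                [TruthRecord(name, 0, len(seq), f"{feat.label}_{i}", "+")]
            )
        else:  # pragma: no cover - exhaustive over Feature
            raise PlanError(f"unknown feature type: {feat!r}")
        truth.records.extend(sub.shifted(pos).records)
        parts.append(seq)
        pos += len(seq)
    seq = "".join(parts)
    truth.validate({name: len(seq)})
    return seq, truth


def synthesize_genome(
    plan: GenomePlan,
) -> tuple[dict[str, str], SyntheticTruth]:
    """Emit every chromosome of the plan; deterministic for a fixed plan seed."""
    rng = np.random.default_rng(plan.seed)
    seqs: dict[str, str] = {}
    truth = SyntheticTruth()
    for chrom in plan.chromosomes:
        arm_seed = int(rng.integers(2**31))
        seq, sub = synthesize_acrocentric_arm(
            chrom.features, arm_seed, name=chrom.name, plan=plan
        )
        seqs[chrom.name] = seq
        truth.records.extend(sub.records)
    truth.validate({n: len(s) for n, s in seqs.items()})
    return seqs, truth


# ---------------------------------------------------------------------------
# depth / methylation tracks


def simulate_depth_track(
    seq_lengths: dict[str, int],
    truth: SyntheticTruth,
    track_spec: TrackSpec,
    rdna_total_copies: int,
    seed: int = 0,
    rdna_class: str = "rdna_unit",
):
    """Simulate binned depth and methylation tracks over the genome.

    Depth over bins covered by `rdna_class` truth records is scaled by
    rdna_total_copies / 2 (diploid convention: single-copy baseline = 2
    copies per genome), emulating collapsed-reference short-read mapping of a
    tandem array present at the given genome-wide copy number. Methylation
    bins fluctuate around the per-feature-class state in the TrackSpec.

    Returns two pandas DataFrames (chrom, bin_start, value).
    """
    import pandas as pd

    if rdna_total_copies < 0:
        raise ParameterError("rdna_total_copies must be >= 0")
    rng = np.random.default_rng(seed)
    bs = track_spec.bin_size
    states = dict(track_spec.methylation_states)
    depth_rows = []
    meth_rows = []
    for chrom, length in seq_lengths.items():
        if not isinstance(length, (int, np.integer)):
            length = len(length)  # accept a sequences dict directly
        n_bins = max(1, length // bs)
        starts = np.arange(n_bins) * bs
        scale = np.ones(n_bins)
        meth_mu = np.full(n_bins, track_spec.background_methylation)
        # per-bin assignment: a bin takes the class covering most of it
        cover: dict[int, dict[str, int]] = {}
        for r in truth.records:
            if r.sequence_name != chrom:
                continue
            interesting = r.feature_class == rdna_class or r.feature_class in states
            if not interesting:
                continue
            first = r.start // bs
            last = min((r.end - 1) // bs, n_bins - 1)
            for b in range(first, last + 1):
                b0, b1 = b * bs, b * bs + bs
                ov = min(r.end, b1) - max(r.start, b0)
                cover.setdefault(b, {})[r.feature_class] = (
                    cover.get(b, {}).get(r.feature_class, 0) + ov
                )
        for b, classes in cover.items():
            if rdna_class in classes and classes[rdna_class] >= bs // 2:
                scale[b] = rdna_total_copies / 2.0
            meth_classes = {c: v for c, v in classes.items() if c in states}
            if meth_classes:
                # coverage decides; ties go to the class listed earlier in
                # methylation_states (lets callers prioritize nested features)
                prio = {c: i for i, (c, _) in enumerate(track_spec.methylation_states)}
                best = min(
                    meth_classes, key=lambda c: (-meth_classes[c], prio.get(c, 99))
                )
                meth_mu[b] = states[best]
        mu = track_spec.mean_depth * scale
        sd = track_spec.noise_sd * np.sqrt(np.maximum(scale, 0.0))
        depth = np.clip(rng.normal(mu, np.where(sd > 0, sd, 1e-12)), 0.0, None)
        depth[scale == 0.0] = 0.0
        meth = np.clip(rng.normal(meth_mu, track_spec.methylation_sd), 0.0, 1.0)
        for s, d, m in zip(starts, depth, meth):
            depth_rows.append((chrom, int(s), float(d)))
            meth_rows.append((chrom, int(s), float(m)))
    cols = ["chrom", "bin_start", "value"]
    return pd.DataFrame(depth_rows, columns=cols), pd.DataFrame(meth_rows, columns=cols)


# ---------------------------------------------------------------------------
# default study-condition genome


def default_genome_plan(seed: int = 0, scale: float = 1.0) -> GenomePlan:
    """A compact genome exercising every stage of the pipeline.

    Three acrocentric-like arms (two sharing a high-identity segment, one
    carrying an rDNA array with one degraded unit), plus an X-like chromosome
    whose centromere is a 28-monomer higher-order repeat array. Monomer
    lengths follow the marmoset constants: 170 bp alpha-satellite monomers
    (S3/S4-like dimer), 171 bp subterminal monomers, 28-class HOR unit.
    `scale` multiplies array unit counts (lower for quick smoke runs).
    """
    rng = np.random.default_rng(seed)

    def s(n: int) -> int:
        return max(2, int(round(n * scale)))

    alpha = make_monomer_library(2, 170, 0.20, int(rng.integers(2**31)),
                                 names=["S3", "S4"])
    subterm = make_monomer_library(1, 171, 0.10, int(rng.integers(2**31)),
                                   names=["MSAT"])
    hor = make_monomer_library(28, 170, 0.10, int(rng.integers(2**31)))
    donor = random_dna(15000, rng)
    model = RdnaUnitModel(
        coding=random_dna(2000, rng), igs=random_dna(1500, rng)
    )

    def subterm_feat() -> SatelliteFeature:
        return SatelliteFeature(
            "subterminal_array", "subterm",
            ArraySpec(("MSAT",), s(120), 0.02, 0.002),
        )

    def alpha_feat() -> SatelliteFeature:
        return SatelliteFeature(
            "alpha_array", "alpha", ArraySpec(("S3", "S4"), s(100), 0.02, 0.002)
        )

    chroms = (
        ChromosomePlan(
            "chr17",
            (
                subterm_feat(),
                SpacerFeature(4000),
                PhrDonorFeature("phr_shared", donor, 0.995),
                RdnaFeature("rdna_array", model, s(8), degraded=((2, (900, 300)),)),
                alpha_feat(),
            ),
        ),
        ChromosomePlan(
            "chr19",
            (
                subterm_feat(),
                SpacerFeature(6000),
                PhrDonorFeature("phr_shared", donor, 0.995),
                SpacerFeature(3000),
                alpha_feat(),
            ),
        ),
        ChromosomePlan(
            "chr20",
            (
                subterm_feat(),
                SpacerFeature(8000),
                alpha_feat(),
            ),
        ),
        ChromosomePlan(
            "chrX",
            (
                SpacerFeature(5000),
                SatelliteFeature(
                    "hor_array", "hor",
                    ArraySpec(tuple(hor.names), s(15), 0.01, 0.001),
                ),
            ),
        ),
    )
    return GenomePlan(
        libraries=(("alpha", alpha), ("subterm", subterm), ("hor", hor)),
        chromosomes=chroms,
        seed=seed,
    )
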