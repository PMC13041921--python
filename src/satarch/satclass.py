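"""Alpha-satellite monomer classification and downstream array annotation.

Monomers are scored against position-specific log-odds profiles (one per
satellite family/subfamily), assignments are merged into annotated arrays
with active/inactive layer status, centromere-specific dimer haplotypes
(dimhaps) and chromosome-specific k-mer signatures are derived from array
consensuses, and monomer/dimer phylogenies support a permutation test for
differential homogenization across chromosomes.

Profiles are ungapped log-odds matrices rather than profile HMMs: monomer
lengths are nearly constant at the divergences modeled here, and the
subfamily scheme is defined by substitution variants, not indel structure.
Small indels are absorbed by projecting each monomer onto the profile's
training reference via a global alignment.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from ._align import global_identity, map_to_reference, revcomp
from .errors import InputError, StatTestError, TrainingError
from .periodicity import Monomer

__all__ = [
    "ProfileSet",
    "MonomerAssignment",
    "SatelliteArrayAnnotation",
    "Dimhap",
    "KmerSignature",
    "train_profiles",
    "classify_monomers",
    "annotate_satellite_arrays",
    "call_dimhaps",
    "kmer_signatures",
    "build_tree",
    "homogenization_test",
]

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
AMBIGUOUS = "ambiguous"


@dataclass
class Profile:
    family: str
    reference: str  # training reference the matrix columns index
    log_odds: np.ndarray  # (length, 4)
    training_count: int

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in np.argmax(self.log_odds, axis=1))


@dataclass
class ProfileSet:
    profiles: dict[str, Profile] = field(default_factory=dict)

    @property
    def families(self) -> list[str]:
        return sorted(self.profiles)

    def low_confidence(self) -> set[str]:
        """Families trained from fewer than 5 monomers."""
        return {f for f, p in self.profiles.items() if p.training_count < 5}


@dataclass(frozen=True)
class MonomerAssignment:
    monomer: Monomer
    family: str
    score: float
    margin: float
    strand: str

    @property
    def start(self) -> int:
        return self.monomer.start

    @property
    def end(self) -> int:
        return self.monomer.end

    @property
    def sequence_name(self) -> str:
        return self.monomer.sequence_name


@dataclass(frozen=True)
class SatelliteArrayAnnotation:
    sequence_name: str
    start: int
    end: int
    family: str
    layer: str  # "active" | "inactive"
    n_monomers: int


@dataclass(frozen=True)
class Dimhap:
    dimhap_id: str
    member_arrays: tuple[tuple[str, str], ...]  # (sequence_name, array_id)
    consensus_dimer: str
    specificity: float


@dataclass(frozen=True)
class KmerSignature:
    sequence_name: str
    kmers: frozenset[str]
    k: int


# ---------------------------------------------------------------------------
# profile training and scoring


def _as_seq(m: Monomer | str) -> str:
    return m.sequence if isinstance(m, Monomer) else m


def train_profiles(
    labeled_monomers: dict[str, list[Monomer | str]],
    pseudocount: float = 0.01,
) -> ProfileSet:
    """Train one position-specific log-odds profile per family.

    Monomers of each family are projected onto a median-length training
    reference; column base frequencies (plus pseudocount) against a uniform
    background give the log-odds matrix. pseudocount=0 leaves unseen bases at
    -inf, making any monomer carrying one unscorable by that profile.
    """
    if not labeled_monomers:
        raise TrainingError("at least one family required")
    out = ProfileSet()
    for family, monomers in labeled_monomers.items():
        seqs = [_as_seq(m).upper() for m in monomers]
        if not seqs:
            raise TrainingError(f"family {family!r} has no training monomers")
        lengths = sorted(len(s) for s in seqs)
        if lengths[-1] > 1.1 * lengths[0] + 1:
            raise TrainingError(
                f"family {family!r}: monomer lengths vary by more than 10%"
            )
        ref = sorted(seqs, key=len)[len(seqs) // 2]
        counts = np.zeros((len(ref), 4), dtype=float)
        for s in seqs:
            cols = list(s) if s == ref else map_to_reference(ref, s)
            for i, b in enumerate(cols):
                if b in _BASE_IDX:
                    counts[i, _BASE_IDX[b]] += 1
        counts += pseudocount
        with np.errstate(divide="ignore"):
            probs = counts / counts.sum(axis=1, keepdims=True)
            log_odds = np.log(probs) - np.log(0.25)
        out.profiles[family] = Profile(family, ref, log_odds, len(seqs))
    return out


def _score(profile: Profile, seq: str) -> float:
    """Sum of per-column log-odds of seq projected onto the profile.

    Columns where seq has a deletion contribute the column's worst log-odds;
    insertions relative to the reference are ignored.
    """
    if len(seq) == len(profile.reference):
        cols: list[str | None] = list(seq)
    else:
        cols = map_to_reference(profile.reference, seq)
    total = 0.0
    lo = profile.log_odds
    for i, b in enumerate(cols):
        if b in _BASE_IDX:
            total += lo[i, _BASE_IDX[b]]
        else:
            total += lo[i].min()
    return float(total)


def score_monomer(profiles: ProfileSet, seq: str) -> dict[tuple[str, str], float]:
    """Score seq against every (family, strand) pair."""
    seq = seq.upper()
    rc = revcomp(seq)
    return {
        (fam, strand): _score(profiles.profiles[fam], s)
        for fam in profiles.families
        for strand, s in (("+", seq), ("-", rc))
    }


def classify_monomers(
    monomers: list[Monomer],
    profiles: ProfileSet,
    min_margin: float = 2.0,
) -> list[MonomerAssignment]:
    """Assign each monomer to its best-scoring (family, strand).

    The margin is the score gap to the best other family (best strand each);
    assignments below min_margin are labeled "ambiguous". Each monomer is
    scored independently, so results do not depend on input order.
    """
    if not profiles.profiles:
        raise InputError("profile set is empty")
    out: list[MonomerAssignment] = []
    for m in monomers:
        table = score_monomer(profiles, m.sequence)
        per_family = {
            fam: max(table[(fam, "+")], table[(fam, "-")])
            for fam in profiles.families
        }
        best_fam = min(per_family, key=lambda f: (-per_family[f], f))
        strand = "+" if table[(best_fam, "+")] >= table[(best_fam, "-")] else "-"
        score = per_family[best_fam]
        others = [v for f, v in per_family.items() if f != best_fam]
        margin = score - max(others) if others else float("inf")
        family = best_fam if margin >= min_margin else AMBIGUOUS
        out.append(MonomerAssignment(m, family, score, max(margin, 0.0), strand))
    return out


# ---------------------------------------------------------------------------
# array annotation


def annotate_satellite_arrays(
    assignments: list[MonomerAssignment],
    min_array_monomers: int = 10,
    max_gap: int = 1000,
    centromere_windows: dict[str, tuple[int, int]] | None = None,
) -> list[SatelliteArrayAnnotation]:
    """Merge same-family monomer runs into arrays and set layer status.

    Runs of consecutive same-family assignments with inter-monomer gaps
    <= max_gap merge into one array; runs shorter than min_array_monomers are
    dropped. Per sequence, the largest array overlapping the declared
    centromere window (or the largest overall, if no window is declared) is
    the active layer; all other arrays are inactive flank layers.
    """
    for a, b in zip(assignments, assignments[1:]):
        if (a.sequence_name, a.start) > (b.sequence_name, b.start):
            raise InputError("assignments must be sorted by (sequence, start)")
    arrays: list[SatelliteArrayAnnotation] = []
    run: list[MonomerAssignment] = []

    def flush() -> None:
        if len(run) >= min_array_monomers:
            arrays.append(
                SatelliteArrayAnnotation(
                    run[0].sequence_name,
                    run[0].start,
                    run[-1].end,
                    run[0].family,
                    "inactive",
                    len(run),
                )
            )
        run.clear()

    for a in assignments:
        if a.family == AMBIGUOUS:
            flush()
            continue
        if run and (
            a.sequence_name != run[-1].sequence_name
            or a.family != run[-1].family
            or a.start - run[-1].end > max_gap
        ):
            flush()
        run.append(a)
    flush()

    out: list[SatelliteArrayAnnotation] = []
    by_seq: dict[str, list[SatelliteArrayAnnotation]] = {}
    for arr in arrays:
        by_seq.setdefault(arr.sequence_name, []).append(arr)
    for seq_name, seq_arrays in by_seq.items():
        window = (centromere_windows or {}).get(seq_name)
        if window is not None:
            w0, w1 = window
            eligible = [
                a for a in seq_arrays if min(a.end, w1) - max(a.start, w0) > 0
            ]
        else:
            eligible = seq_arrays
        active = (
            max(eligible, key=lambda a: (a.n_monomers, -a.start)) if eligible else None
        )
        for arr in seq_arrays:
            layer = "active" if arr is active else "inactive"
            out.append(
                SatelliteArrayAnnotation(
                    arr.sequence_name, arr.start, arr.end, arr.family, layer,
                    arr.n_monomers,
                )
            )
    out.sort(key=lambda a: (a.sequence_name, a.start))
    return out


# ---------------------------------------------------------------------------
# dimhaps and k-mer signatures


def call_dimhaps(
    array_dimer_consensuses: dict[tuple[str, str], str],
    link_identity: float = 0.99,
) -> list[Dimhap]:
    """Single-linkage clustering of per-array dimer consensuses.

    Keys are (sequence_name, array_id). Clusters linked at >= link_identity
    pairwise identity become dimhaps; specificity is the fraction of member
    arrays residing on the modal chromosome. The cluster's medoid (highest
    mean identity to the other members) is the consensus dimer.
    """
    keys = sorted(array_dimer_consensuses)
    if not keys:
        return []
    n = len(keys)
    ident = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            ident[i, j] = ident[j, i] = global_identity(
                array_dimer_consensuses[keys[i]], array_dimer_consensuses[keys[j]]
            )
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if ident[i, j] >= link_identity:
                parent[find(i)] = find(j)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    out: list[Dimhap] = []
    ordered = sorted(clusters.values(), key=lambda c: (-len(c), keys[c[0]]))
    for idx, members in enumerate(ordered, start=1):
        chroms = Counter(keys[i][0] for i in members)
        specificity = max(chroms.values()) / len(members)
        medoid = max(members, key=lambda i: (ident[i, members].mean(), keys[i]))
        out.append(
            Dimhap(
                dimhap_id=f"dimhap{idx}",
                member_arrays=tuple(keys[i] for i in members),
                consensus_dimer=array_dimer_consensuses[keys[medoid]],
                specificity=specificity,
            )
        )
    return out


def _canonical_kmers(seq: str, k: int) -> Counter[str]:
    seq = seq.upper()
    counts: Counter[str] = Counter()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if "N" in km:
            continue
        counts[min(km, revcomp(km))] += 1
    return counts


def kmer_signatures(
    active_arrays: dict[str, str],
    k: int = 31,
    min_copies: int = 2,
) -> list[KmerSignature]:
    """Chromosome-specific canonical k-mers of each active array.

    A k-mer belongs to a chromosome's signature when it occurs >= min_copies
    times in that chromosome's active array and never in any other. Output
    sets are pairwise disjoint by construction (asserted).
    """
    if len(active_arrays) < 2:
        raise InputError("need >= 2 active arrays")
    if any(len(s) < k for s in active_arrays.values()):
        raise InputError("k exceeds the shortest array")
    counts = {name: _canonical_kmers(seq, k) for name, seq in active_arrays.items()}
    out: list[KmerSignature] = []
    for name in sorted(counts):
        own = counts[name]
        exclusive = {
            km
            for km, c in own.items()
            if c >= min_copies
            and all(km not in counts[o] for o in counts if o != name)
        }
        out.append(KmerSignature(name, frozenset(exclusive), k))
    seen: set[str] = set()
    for sig in out:
        assert not (sig.kmers & seen), "signature sets must be pairwise disjoint"
        seen |= sig.kmers
    return out


# ---------------------------------------------------------------------------
# trees and the homogenization test


def build_tree(sequences: list[tuple[str, str]], method: str = "nj"):
    """Neighbor-joining tree from pairwise alignment distances.

    Distance is 1 - gap-inclusive global-alignment identity. Returns a
    scikit-bio TreeNode (serialize with ``str(tree)`` for Newick). On an
    additive distance matrix NJ recovers the generating topology.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if method != "nj":
        raise InputError(f"unsupported tree method: {method!r}")
    if len(sequences) < 3:
        raise InputError("tree building needs >= 3 sequences")
    names = [n for n, _ in sequences]
    if len(set(names)) != len(names):
        raise InputError("duplicate taxon names")
    n = len(sequences)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - global_identity(sequences[i][1], sequences[j][1])
            dm[i, j] = dm[j, i] = d
    tree = nj(DistanceMatrix(dm, ids=names))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def homogenization_test(
    monomer_tree,
    chromosome_labels: dict[str, str],
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Test whether tree neighbors share chromosomes more than chance.

    The statistic is the fraction of taxa whose nearest tree neighbor (by
    patristic distance, ties broken by taxon name) carries the same
    chromosome label. The p-value is (1 + #permuted >= observed) /
    (1 + n_permutations) under random label shuffles, with uniform random
    tie-breaking between equal statistic values: the match fraction takes
    few distinct values, and without tie-breaking the permutation p-value
    is super-uniform (conservative) rather than uniform under the null. A
    low p indicates chromosome-specific homogenization; a high p is
    consistent with the exchange of monomers between chromosomes.
    """
    if n_permutations < 1:
        raise StatTestError("n_permutations must be >= 1")
    tips = sorted(t.name for t in monomer_tree.tips())
    labels = [chromosome_labels[t] for t in tips]
    if len(set(labels)) < 2:
        raise StatTestError("need >= 2 chromosomes represented")
    if len(tips) <= 3:
        warnings.warn(
            "homogenization test on <= 3 taxa is degenerate: very few "
            "distinct label shuffles exist",
            stacklevel=2,
        )
    dm = monomer_tree.tip_tip_distances(endpoints=tips)
    dist = dm.data
    n = len(tips)
    nearest = np.empty(n, dtype=int)
    for i in range(n):
        d = dist[i].copy()
        d[i] = np.inf
        m = d.min()
        nearest[i] = min(j for j in range(n) if d[j] == m)  # name-order tie-break

    lab = np.array(labels)

    def stat(values: np.ndarray) -> float:
        return float(np.mean(values == values[nearest]))

    observed = stat(lab)
    rng = np.random.default_rng(seed)
    u_obs = rng.random()
    count = 0
    for _ in range(n_permutations):
        s = stat(rng.permutation(lab))
        if s > observed or (s == observed and rng.random() >= u_obs):
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return observed, p
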