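"""Tandem-repeat periodicity: k-mer interval spectra, monomer segmentation,
consensus building and higher-order-repeat (HOR) detection.

The spectrum follows the k-mer recurrence-interval idea used for satellite
periodicity analysis: for every k-mer occurring at least twice, the distances
between consecutive occurrences are tallied; a tandem array of unit length p
piles counts onto period p (and, for multimeric units, onto the unit
multiple). Spectra are invariant under reverse complement because consecutive
occurrence intervals of a k-mer in s equal those of its reverse complement in
revcomp(s).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, ParameterError

__all__ = [
    "PeriodSpectrum",
    "Monomer",
    "HORCall",
    "ntr_spectrum",
    "dominant_period",
    "segment_monomers",
    "build_consensus",
    "detect_hor",
]


@dataclass
class PeriodSpectrum:
    k: int
    max_period: int
    score_per_period: dict[int, int] = field(default_factory=dict)
    n_kmers_used: int = 0

    def total_score(self) -> int:
        return sum(self.score_per_period.values())


@dataclass(frozen=True)
class Monomer:
    sequence_name: str
    start: int
    end: int
    strand: str
    sequence: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise InputError("monomer span and sequence length disagree")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class HORCall:
    unit_size: int
    support: float
    unit_class_sequence: tuple[str, ...]


def _kmer_positions(sequence: str, k: int) -> dict[str, list[int]]:
    """Positions of every k-mer; k-mers containing N are excluded."""
    pos: dict[str, list[int]] = defaultdict(list)
    n_ok = 0  # index past the last ambiguous base
    for i in range(len(sequence) - k + 1):
        km = sequence[i : i + k]
        if "N" in km or "n" in km:
            continue
        pos[km].append(i)
        n_ok += 1
    return pos


def ntr_spectrum(sequence: str, k: int = 21, max_period: int = 3000) -> PeriodSpectrum:
    """Tally consecutive-occurrence intervals of every recurring k-mer.

    Intervals larger than max_period are discarded. Deterministic.
    """
    if k < 2:
        raise ParameterError("k must be >= 2")
    if len(sequence) <= 2 * k:
        raise InputError("sequence must be longer than 2k")
    if max_period < 1:
        raise ParameterError("max_period must be >= 1")
    sequence = sequence.upper()
    spectrum: Counter[int] = Counter()
    used = 0
    for positions in _kmer_positions(sequence, k).values():
        if len(positions) < 2:
            continue
        used += 1
        for a, b in zip(positions, positions[1:]):
            d = b - a
            if d <= max_period:
                spectrum[d] += 1
    return PeriodSpectrum(
        k=k,
        max_period=max_period,
        score_per_period=dict(spectrum),
        n_kmers_used=used,
    )


def dominant_period(spectrum: PeriodSpectrum, n_top: int = 1) -> list[tuple[int, int]]:
    """Top-n periods by score, descending; ties broken by the smaller period."""
    items = sorted(spectrum.score_per_period.items(), key=lambda kv: (-kv[1], kv[0]))
    return items[:n_top]


def _phase_anchor(sequence: str, period: int, k: int) -> tuple[str, list[int]]:
    """The k-mer contributing the most recurrence intervals near `period`,
    and its occurrence positions. Intervals within ±3 bp of the period count,
    tolerating small indel drift."""
    best_km, best_score, best_pos = "", -1, []
    for km, positions in _kmer_positions(sequence, k).items():
        if len(positions) < 2:
            continue
        score = sum(
            1 for a, b in zip(positions, positions[1:]) if abs((b - a) - period) <= 3
        )
        # ties prefer the earliest-starting anchor (phases the tiling at the
        # array start), then the lexicographically smaller k-mer
        better = score > best_score or (
            score == best_score
            and (
                not best_pos
                or positions[0] < best_pos[0]
                or (positions[0] == best_pos[0] and km < best_km)
            )
        )
        if better:
            best_km, best_score, best_pos = km, score, positions
    return best_km, best_pos


def _anchor_occurrences(
    sequence: str, anchor: str, min_identity: float = 0.75
) -> list[int]:
    """Start positions of every decent placement of `anchor` in `sequence`,
    found by iterated best-hit search with masking (dense even where the
    repeat has diverged too far for exact k-mer anchors)."""
    import edlib

    from ._align import cigar_stats

    work = list(sequence)
    starts: list[int] = []
    while True:
        res = edlib.align(anchor, "".join(work), mode="HW", task="path")
        m, cols = cigar_stats(res["cigar"])
        if cols == 0 or m / cols < min_identity:
            break
        s, e = res["locations"][0]
        s = s or 0
        starts.append(s)
        for i in range(s, e + 1):
            work[i] = "\0"  # matches nothing
    return sorted(starts)


def segment_monomers(
    array_sequence: str,
    period: int,
    k: int = 21,
    sequence_name: str = "array",
    phase_anchor: str | None = None,
) -> list[Monomer]:
    """Cut a tandem array into monomers phased on its dominant repeat.

    The phase anchor is the k-mer recurring most often at the requested
    period; anchor occurrences set monomer boundaries, and stretches between
    non-adjacent anchors (where divergence broke the anchor k-mer) are split
    evenly into round(gap/period) monomers. A trailing/leading partial unit
    shorter than period/2 is dropped.

    Without an external reference the rotation of the cut grid within the
    repeat unit is arbitrary (any rotation tiles the array equally well),
    and in multimeric arrays exact k-mer anchors recurring at the monomer
    period can be sparse. Passing a known monomer as `phase_anchor` replaces
    the k-mer grid with the anchor's actual placements (iterated masked
    infix search), so cuts fall on true monomer boundaries — required when
    downstream classification must see unrotated monomers.
    """
    if period < 10:
        raise ParameterError("period must be >= 10")
    if len(array_sequence) < 2 * period:
        raise InputError("array must span at least two periods")
    seq = array_sequence.upper()
    k = min(k, period // 2)
    if phase_anchor is not None:
        anchors = _anchor_occurrences(seq, phase_anchor.upper())
    else:
        _, anchors = _phase_anchor(seq, period, k)
    # keep only occurrences consistent with the period grid: successive
    # anchor gaps must sit within a small tolerance of a period multiple
    phased: list[int] = []
    for p in anchors:
        if not phased:
            phased.append(p)
            continue
        gap = p - phased[-1]
        mult = max(1, round(gap / period))
        if abs(gap - mult * period) <= max(3, 3 * mult):
            phased.append(p)
    if len(phased) < 2:
        phased = list(range(0, len(seq) - period + 1, period))
    elif phase_anchor is None:
        # shift the grid so tiling starts at the array origin: the k-mer
        # anchor's offset within its monomer is arbitrary, the relative
        # phase is not (external anchors already mark true starts)
        offset = phased[0] % period
        phased = [p - offset for p in phased]
    # extend to the sequence ends at the nominal period
    first, last = phased[0], phased[-1]
    head = [first - j * period for j in range(first // period, 0, -1)]
    n_tail = (len(seq) - last) // period
    tail = [last + j * period for j in range(1, n_tail + 1)]
    boundaries = head + phased + tail
    cuts: list[int] = [boundaries[0]]
    for a, b in zip(boundaries, boundaries[1:]):
        gap = b - a
        n = max(1, int(round(gap / period)))
        for j in range(1, n + 1):
            cuts.append(a + int(round(j * gap / n)))
    monomers: list[Monomer] = []
    if cuts and cuts[0] >= period // 2:  # leading partial unit kept if long enough
        cuts.insert(0, max(0, cuts[0] - period))
    if cuts and len(seq) - cuts[-1] >= period // 2:
        cuts.append(len(seq))
    for a, b in zip(cuts, cuts[1:]):
        if period / 2 <= b - a <= 2 * period:
            monomers.append(Monomer(sequence_name, a, b, "+", seq[a:b]))
    return monomers


def build_consensus(monomers: list[Monomer | str]) -> str:
    """Column-wise majority consensus over a star alignment to the longest
    monomer; base ties break alphabetically; a column is dropped only when
    gaps strictly outnumber every base."""
    from ._align import map_to_reference

    seqs = [m.sequence if isinstance(m, Monomer) else m for m in monomers]
    if len(seqs) < 2:
        raise InputError("consensus needs >= 2 monomers")
    ref = max(seqs, key=len)
    counts = np.zeros((len(ref), 5), dtype=int)  # A C G T gap
    order = {"A": 0, "C": 1, "G": 2, "T": 3}
    for s in seqs:
        if s == ref:
            cols: list[str | None] = list(s)
        else:
            cols = map_to_reference(ref, s)
        for i, b in enumerate(cols):
            counts[i, order.get(b, 4) if b is not None else 4] += 1
    out = []
    for row in counts:
        best_base = int(np.argmax(row[:4]))  # argmax takes the alphabetically
        if row[4] > row[best_base]:  # first of tied bases (A<C<G<T)
            continue
        out.append("ACGT"[best_base])
    return "".join(out)


def detect_hor(
    class_string: list[str] | tuple[str, ...],
    max_unit: int = 60,
    min_support: float = 0.8,
) -> list[HORCall]:
    """Detect higher-order repeat unit sizes from an ordered class string.

    For each candidate unit size u, support is the fraction of positions i
    with class[i] == class[i+u]. Units reaching min_support are reported
    unless their size is a multiple of a smaller reported unit; results are
    sorted by support (descending), ties by smaller unit.
    """
    labels = list(class_string)
    n = len(labels)
    if n < 4:
        return []
    candidates: list[tuple[int, float]] = []
    for u in range(2, min(max_unit, n // 2) + 1):
        m = n - u
        support = sum(labels[i] == labels[i + u] for i in range(m)) / m
        if support >= min_support:
            candidates.append((u, support))
    kept: list[tuple[int, float]] = []
    for u, support in sorted(candidates):
        if any(u % ku == 0 for ku, _ in kept):
            continue
        kept.append((u, support))
    kept.sort(key=lambda t: (-t[1], t[0]))
    return [
        HORCall(unit_size=u, support=s, unit_class_sequence=tuple(labels[:u]))
        for u, s in kept
    ]
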