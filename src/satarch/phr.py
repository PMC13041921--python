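"""Pseudo-homologous regions (PHRs) between heterologous chromosome arms.

Acrocentric short arms can share long, nearly identical segments despite
residing on different chromosomes; such segments recombine ectopically and
redistribute rDNA arrays. Detection here is windowed: fixed-size windows of
one arm are placed on the other by infix alignment, collinear same-
orientation hits are chained across gaps of up to one window, and chains are
filtered by the identity/span rule (default: >= 99% identity over >= 10 kb,
the threshold used for primate acrocentric comparisons). Identity is gap-
inclusive (matches / aligned columns). Both orientations are searched;
inverted sharing is reported with orientation '-'.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._align import cigar_stats, global_identity, infix_hit, revcomp
from .errors import InputError, ParameterError

__all__ = [
    "IdentitySegment",
    "PHRSegment",
    "PHRNetwork",
    "windowed_identity",
    "call_phrs",
    "phr_network",
    "self_identity_matrix",
    "SelfIdentityMatrix",
]


@dataclass(frozen=True)
class IdentitySegment:
    seq_a: str
    start_a: int
    end_a: int
    seq_b: str
    start_b: int
    end_b: int
    identity: float
    orientation: str  # "+" | "-"

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise InputError("identity must lie in [0, 1]")
        if self.end_a <= self.start_a or self.end_b <= self.start_b:
            raise InputError("segment spans must be positive")

    @property
    def span_a(self) -> int:
        return self.end_a - self.start_a

    @property
    def span_b(self) -> int:
        return self.end_b - self.start_b


@dataclass(frozen=True)
class PHRSegment(IdentitySegment):
    merged: bool = False


@dataclass
class PHRNetwork:
    """Undirected chromosome-sharing graph."""

    nodes: dict[str, bool] = field(default_factory=dict)  # name -> acrocentric
    edges: list[tuple[str, str, int, float]] = field(default_factory=list)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for name, acro in self.nodes.items():
            g.add_node(name, acrocentric=acro)
        for a, b, bp, ident in self.edges:
            g.add_edge(a, b, shared_bp=bp, mean_identity=ident)
        return g


def _window_starts(length: int, window: int, step: int) -> list[int]:
    if length <= window:
        return [0]
    starts = list(range(0, length - window + 1, step))
    if starts[-1] != length - window:
        starts.append(length - window)
    return starts


def windowed_identity(
    seq_a: str,
    seq_b: str,
    window: int = 5000,
    step: int = 2500,
    min_hit_identity: float = 0.8,
    chain: bool = True,
) -> list[IdentitySegment]:
    """High-identity segments between two sequences by windowed placement.

    Each window of A is placed on B by infix alignment in both orientations;
    hits above min_hit_identity are chained when collinear within one window
    on both sequences (``chain=False`` returns the raw per-window hits
    instead). Chain identity is the aligned-column-weighted mean of
    member-hit identities (overlapping windows weight shared columns twice;
    with step = window/2 the effect is symmetric along the chain).
    """
    if not seq_a or not seq_b:
        raise InputError("sequences must be non-empty")
    if window < 1000:
        raise ParameterError("window must be >= 1000")
    if step < 1 or step > window:
        raise ParameterError("step must lie in [1, window]")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    hits: dict[str, list[tuple[int, int, int, int, float, int]]] = {"+": [], "-": []}
    for wa in _window_starts(len(seq_a), window, step):
        win = seq_a[wa : wa + window]
        for orient in ("+", "-"):
            query = win if orient == "+" else revcomp(win)
            sb, eb, ident, cigar = infix_hit(query, seq_b)
            if ident >= min_hit_identity:
                _, cols = cigar_stats(cigar)
                hits[orient].append((wa, wa + len(win), sb, eb, ident, cols))
    segments: list[IdentitySegment] = []
    if not chain:
        for orient, rows in hits.items():
            for wa, ea, sb, eb, ident, _cols in rows:
                segments.append(
                    IdentitySegment("A", wa, ea, "B", sb, eb, min(ident, 1.0), orient)
                )
        segments.sort(key=lambda s: (s.start_a, s.start_b))
        return segments
    for orient, rows in hits.items():
        rows.sort()
        chain: list[tuple[int, int, int, int, float, int]] = []

        def flush() -> None:
            if not chain:
                return
            sa = min(r[0] for r in chain)
            ea = max(r[1] for r in chain)
            sb = min(r[2] for r in chain)
            eb = max(r[3] for r in chain)
            cols = sum(r[5] for r in chain)
            ident = sum(r[4] * r[5] for r in chain) / cols
            segments.append(
                IdentitySegment(
                    "A", sa, ea, "B", sb, eb, min(ident, 1.0), orient
                )
            )
            chain.clear()

        for row in rows:
            if chain:
                prev = chain[-1]
                gap_a = row[0] - prev[1]
                if orient == "+":
                    gap_b = row[2] - prev[3]
                else:
                    gap_b = prev[2] - row[3]
                collinear = gap_a <= window and -window <= gap_b <= window
                if not collinear:
                    flush()
            chain.append(row)
        flush()
    segments.sort(key=lambda s: (s.start_a, s.start_b))
    return segments


def call_phrs(
    segments: list[IdentitySegment],
    min_identity: float = 0.99,
    min_span: int = 10000,
    names: tuple[str, str] | None = None,
    merge_gap: int = 5000,
) -> list[PHRSegment]:
    """Apply the PHR identity/span rule to identity segments.

    Segments below min_identity are discarded first, so a high-identity
    shared region is never diluted by adjacent lower-identity repeat hits;
    the survivors are merged when overlapping/abutting (within merge_gap on
    both sequences, same pair and orientation, span-weighted identity), and
    merged spans shorter than min_span on either sequence are dropped.
    Output is sorted by (seq_a, start_a). `names` optionally relabels the
    generic A/B sequence names from windowed_identity.
    """
    groups: dict[tuple[str, str, str], list[IdentitySegment]] = {}
    for s in segments:
        if names is not None:
            s = IdentitySegment(
                names[0], s.start_a, s.end_a, names[1], s.start_b, s.end_b,
                s.identity, s.orientation,
            )
        if s.identity >= min_identity:
            groups.setdefault((s.seq_a, s.seq_b, s.orientation), []).append(s)
    out: list[PHRSegment] = []
    for (qa, qb, orient), group in groups.items():
        group.sort(key=lambda s: (s.start_a, s.start_b))
        clusters: list[list[IdentitySegment]] = []
        for s in group:
            placed = False
            if clusters:
                cluster = clusters[-1]
                ea = max(c.end_a for c in cluster)
                sb = min(c.start_b for c in cluster)
                eb = max(c.end_b for c in cluster)
                near_a = s.start_a <= ea + merge_gap
                near_b = s.start_b <= eb + merge_gap and s.end_b >= sb - merge_gap
                if near_a and near_b:
                    cluster.append(s)
                    placed = True
            if not placed:
                clusters.append([s])
        for cluster in clusters:
            sa = min(s.start_a for s in cluster)
            ea = max(s.end_a for s in cluster)
            sb = min(s.start_b for s in cluster)
            eb = max(s.end_b for s in cluster)
            w = sum(s.span_a for s in cluster)
            ident = sum(s.identity * s.span_a for s in cluster) / w
            span = min(ea - sa, eb - sb)
            if span >= min_span:
                out.append(
                    PHRSegment(
                        qa, sa, ea, qb, sb, eb, ident, orient,
                        merged=len(cluster) > 1,
                    )
                )
    out.sort(key=lambda s: (s.seq_a, s.start_a))
    return out


def _refine_boundaries(
    seq_a: str,
    seq_b: str,
    phr: PHRSegment,
    min_identity: float,
    block: int = 250,
) -> PHRSegment:
    """Extend a PHR outward in small blocks while identity holds.

    Window quantization clips up to ~window/2 from each true boundary; this
    walks outward in `block`-bp steps. A block's identity is a noisy
    small-sample estimate of the local identity, so each step is accepted at
    min_identity minus a two-sigma binomial allowance — a genuinely shared
    flank at the threshold keeps extending, while unrelated flanking
    sequence (~50% identity) stops immediately. The caller re-checks the
    whole-span identity afterwards.
    """
    allowance = 2.0 * ((min_identity * (1.0 - min_identity)) / block) ** 0.5
    min_identity = min_identity - allowance
    sa, ea, sb, eb = phr.start_a, phr.end_a, phr.start_b, phr.end_b
    forward = phr.orientation == "+"

    def block_ident(a0: int, a1: int, b0: int, b1: int) -> float:
        if a0 < 0 or b0 < 0 or a1 > len(seq_a) or b1 > len(seq_b) or a0 >= a1 or b0 >= b1:
            return -1.0
        wa = seq_a[a0:a1]
        wb = seq_b[b0:b1]
        if not forward:
            wb = revcomp(wb)
        return global_identity(wa, wb)

    while True:  # extend left on A (left on B if "+", right on B if "-")
        if forward:
            ident = block_ident(sa - block, sa, sb - block, sb)
        else:
            ident = block_ident(sa - block, sa, eb, eb + block)
        if ident < min_identity:
            break
        sa -= block
        if forward:
            sb -= block
        else:
            eb += block
    while True:  # extend right on A
        if forward:
            ident = block_ident(ea, ea + block, eb, eb + block)
        else:
            ident = block_ident(ea, ea + block, sb - block, sb)
        if ident < min_identity:
            break
        ea += block
        if forward:
            eb += block
        else:
            sb -= block
    return PHRSegment(
        phr.seq_a, sa, ea, phr.seq_b, sb, eb, phr.identity, phr.orientation,
        merged=phr.merged,
    )


def find_phrs(
    seq_a: str,
    seq_b: str,
    window: int = 5000,
    step: int = 2500,
    min_identity: float = 0.99,
    min_span: int = 10000,
    names: tuple[str, str] = ("A", "B"),
) -> list[PHRSegment]:
    """End-to-end PHR detection between two sequences.

    Raw per-window hits -> identity filter -> collinear merge -> span filter
    -> alignment-refined boundaries. The refinement recomputes each call's
    identity over its final span so reported identities are exact.
    """
    raw = windowed_identity(seq_a, seq_b, window=window, step=step, chain=False)
    calls = call_phrs(
        raw, min_identity=min_identity, min_span=min_span, names=names,
        merge_gap=window,
    )
    out: list[PHRSegment] = []
    for phr in calls:
        refined = _refine_boundaries(seq_a, seq_b, phr, min_identity)
        sub_b = seq_b[refined.start_b : refined.end_b]
        if refined.orientation == "-":
            sub_b = revcomp(sub_b)
        ident = global_identity(seq_a[refined.start_a : refined.end_a], sub_b)
        out.append(
            PHRSegment(
                refined.seq_a, refined.start_a, refined.end_a,
                refined.seq_b, refined.start_b, refined.end_b,
                ident, refined.orientation, merged=refined.merged,
            )
        )
    # refined identity can dip below threshold at ragged ends; re-filter
    out = [p for p in out if p.identity >= min_identity
           and min(p.span_a, p.span_b) >= min_span]
    out.sort(key=lambda s: (s.seq_a, s.start_a))
    return out


def phr_network(
    phrs: list[PHRSegment],
    acrocentric_names: set[str] | frozenset[str] = frozenset(),
) -> PHRNetwork:
    """Aggregate PHR segments into one undirected edge per chromosome pair.

    shared_bp sums min(span_a, span_b) over the pair's PHRs; mean identity
    is bp-weighted. Self-pairs are excluded.
    """
    net = PHRNetwork()
    acc: dict[tuple[str, str], tuple[int, float]] = {}
    for s in phrs:
        for name in (s.seq_a, s.seq_b):
            net.nodes.setdefault(name, name in acrocentric_names)
        if s.seq_a == s.seq_b:
            continue
        key = tuple(sorted((s.seq_a, s.seq_b)))
        bp = min(s.span_a, s.span_b)
        prev_bp, prev_sum = acc.get(key, (0, 0.0))
        acc[key] = (prev_bp + bp, prev_sum + s.identity * bp)
    for name in acrocentric_names:
        net.nodes.setdefault(name, True)
    for (a, b), (bp, ident_sum) in sorted(acc.items()):
        net.edges.append((a, b, bp, ident_sum / bp))
    return net


@dataclass
class SelfIdentityMatrix:
    """Pairwise identity of non-overlapping windows of one sequence."""

    sequence_name: str
    window: int
    n_windows: int
    cells: dict[tuple[int, int], float] = field(default_factory=dict)  # i <= j

    def identity(self, i: int, j: int) -> float:
        if i > j:
            i, j = j, i
        return self.cells[(i, j)]

    def to_dataframe(self):
        import pandas as pd

        rows = [(i, j, v) for (i, j), v in sorted(self.cells.items())]
        return pd.DataFrame(rows, columns=["i", "j", "identity"])

    def to_array(self) -> np.ndarray:
        m = np.ones((self.n_windows, self.n_windows))
        for (i, j), v in self.cells.items():
            m[i, j] = m[j, i] = v
        return m


def self_identity_matrix(
    sequence: str,
    window: int = 5000,
    sequence_name: str = "seq",
) -> SelfIdentityMatrix:
    """Global-alignment identity of every pair of non-overlapping windows.

    The trailing partial window (< window bp) is dropped. Diagonal cells are
    1.0 by definition; only i <= j is stored.
    """
    if len(sequence) < 2 * window:
        raise InputError("sequence must span at least two windows")
    sequence = sequence.upper()
    n = len(sequence) // window
    wins = [sequence[i * window : (i + 1) * window] for i in range(n)]
    out = SelfIdentityMatrix(sequence_name, window, n)
    for i in range(n):
        out.cells[(i, i)] = 1.0
        for j in range(i + 1, n):
            out.cells[(i, j)] = global_identity(wins[i], wins[j])
    return out
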