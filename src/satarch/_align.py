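"""Thin wrappers around edlib used by every alignment-bearing stage.

Identity is defined gap-inclusively throughout the package:
``identity = matches / aligned columns`` where aligned columns count match,
mismatch, insertion and deletion columns alike. This is the strictest
reproducible definition and is applied identically in PHR calling,
self-identity matrices, dimhap linkage and tree distances.
"""

from __future__ import annotations

import re

import edlib

_CIGAR_RE = re.compile(r"(\d+)([=XID])")

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement (N-preserving)."""
    return seq.translate(_COMP)[::-1]


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    """Extended-CIGAR string -> list of (length, op) with ops in {=, X, I, D}."""
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def cigar_stats(cigar: str) -> tuple[int, int]:
    """Return (matches, aligned_columns) for an extended CIGAR."""
    matches = 0
    cols = 0
    for n, op in parse_cigar(cigar):
        cols += n
        if op == "=":
            matches += n
    return matches, cols


def global_identity(a: str, b: str) -> float:
    """Gap-inclusive identity of the optimal global (NW) alignment of a and b."""
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    res = edlib.align(a, b, mode="NW", task="path")
    m, cols = cigar_stats(res["cigar"])
    return m / cols


def infix_hit(query: str, target: str) -> tuple[int, int, float, str]:
    """Best infix (HW) placement of query inside target.

    Returns (start, end, identity, cigar) with end exclusive, in target
    coordinates. Identity is gap-inclusive over the aligned span.
    """
    if not query or not target:
        raise ValueError("cannot align empty sequences")
    res = edlib.align(query, target, mode="HW", task="path")
    start, end_incl = res["locations"][0]
    if start is None:  # edlib may report None when hit starts at 0
        start = 0
    m, cols = cigar_stats(res["cigar"])
    return start, end_incl + 1, m / cols, res["cigar"]


def map_to_reference(ref: str, seq: str) -> list[str | None]:
    """Project seq onto ref columns via a global alignment.

    Returns one entry per ref position: the seq base aligned there, or None
    where seq has a deletion. Bases of seq inserted relative to ref are
    dropped (star-alignment convention).
    """
    res = edlib.align(ref, seq, mode="NW", task="path")
    out: list[str | None] = []
    i = 0  # position in seq
    for n, op in parse_cigar(res["cigar"]):
        if op in ("=", "X"):
            out.extend(seq[i : i + n])
            i += n
        elif op == "D":  # extra bases in seq relative to ref
            i += n
        else:  # "I": ref column with no seq base
            out.extend([None] * n)
    return out
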