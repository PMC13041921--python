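"""rDNA arrays: unit detection, copy-number estimation and allocation,
transcriptional-activity classification, CDR calling, and the sex-difference
test.

Copy numbers follow the diploid convention throughout: a single-copy locus
is present at 2 copies per genome, so the total rDNA copy number is
``2 × depth(rDNA) / depth(single-copy)``. Per-array integer copies are
allocated from fractional FISH intensities by largest-remainder rounding,
the unique standard rule that conserves the rounded total exactly.

An rDNA unit is coding (45S-like) plus intergenic spacer (IGS). Active
arrays have unmethylated promoters/coding regions while the IGS stays
methylated in both states, so activity is called from the coding-region
methylated fraction alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._align import parse_cigar, revcomp
from .errors import (
    ClassificationError,
    EstimationError,
    InputError,
    ParameterError,
    StatTestError,
)

__all__ = [
    "RdnaUnit",
    "CopyAllocation",
    "MethylationSummary",
    "CDRCall",
    "find_rdna_units",
    "estimate_total_copies",
    "allocate_array_copies",
    "classify_activity",
    "call_cdrs",
    "compare_sex_copy_number",
]


@dataclass(frozen=True)
class RdnaUnit:
    sequence_name: str
    start: int
    end: int
    orientation: str  # "+" | "-"
    intact: bool
    insertions: tuple[tuple[int, int, str], ...]  # (pos within unit, len, class)
    coding_start: int
    coding_end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise InputError("unit span must be positive")
        if self.intact != (not self.insertions):
            raise InputError("intact flag must match the insertion list")


@dataclass(frozen=True)
class CopyAllocation:
    total_copies: float
    arrays: tuple[tuple[str, float, int], ...]  # (array_id, fraction, copies)

    def copies(self, array_id: str) -> int:
        for a, _, c in self.arrays:
            if a == array_id:
                return c
        raise KeyError(array_id)


@dataclass(frozen=True)
class MethylationSummary:
    array_id: str
    coding_mean: float
    igs_mean: float
    state: str  # "active" | "silent"


@dataclass(frozen=True)
class CDRCall:
    sequence_name: str
    start: int
    end: int
    mean_methylation_inside: float
    flank_mean: float


# ---------------------------------------------------------------------------
# unit detection


def find_rdna_units(
    sequence: str,
    unit_model: tuple[str, str],
    min_hit_identity: float = 0.8,
    min_insertion: int = 100,
    sequence_name: str = "seq",
) -> list[RdnaUnit]:
    """Locate rDNA units and flag retroelement-like disruptions.

    Detection is two-phase. First, coding-consensus placements are found by
    iterated best-hit infix search with masking (either strand), down to
    min_hit_identity. Second, each unit is re-aligned as a whole: the full
    unit model (coding + IGS, in transcription orientation) is placed over
    the region pinned between consecutive coding hits, so an insertion
    inside the unit cannot be skipped by a shifted placement. Runs of
    alignment columns whose windowed match fraction collapses (junk aligned
    to consensus stays near 50% by accidental matches; genuine unit sequence
    stays above 90% at the divergences modeled) spanning >= min_insertion
    are reported as insertions; any insertion marks the unit degraded.
    Units are returned sorted by coordinate.
    """
    import edlib

    coding, igs = unit_model
    if not coding or not igs:
        raise InputError("unit model consensuses must be non-empty")
    seq = sequence.upper()
    coding = coding.upper()
    igs = igs.upper()
    unit_len = len(coding) + len(igs)

    # phase 1: coding-consensus placements by masked iterated search
    work = list(seq)
    queries = {"+": coding, "-": revcomp(coding)}
    hits: list[tuple[int, int, str]] = []  # (start, end, orientation)
    while True:
        target = "".join(work)
        best = None
        for orient, q in queries.items():
            res = edlib.align(q, target, mode="HW", task="path")
            m, cols = 0, 0
            for n, op in parse_cigar(res["cigar"]):
                cols += n
                if op == "=":
                    m += n
            ident = m / cols if cols else 0.0
            if best is None or ident > best[0]:
                best = (ident, orient, res)
        ident, orient, res = best
        if ident < min_hit_identity:
            break
        start, end_incl = res["locations"][0]
        start = start or 0
        hits.append((start, end_incl + 1, orient))
        for i in range(start, end_incl + 1):
            work[i] = "N"
    hits.sort()

    # phase 2: whole-unit re-alignment between pinned neighbors
    found: list[RdnaUnit] = []
    for idx, (cs, ce, orient) in enumerate(hits):
        if orient == "+":
            region_lo = cs
            region_hi = (
                hits[idx + 1][0]
                if idx + 1 < len(hits) and hits[idx + 1][0] > cs
                else min(len(seq), cs + unit_len + 10 * min_insertion)
            )
            query = coding + igs
        else:
            region_hi = ce
            region_lo = (
                hits[idx - 1][1]
                if idx > 0 and hits[idx - 1][1] < ce
                else max(0, ce - unit_len - 10 * min_insertion)
            )
            query = revcomp(coding + igs)
        region = seq[region_lo:region_hi]
        res = edlib.align(query, region, mode="HW", task="path")
        loc_start, loc_end_incl = res["locations"][0]
        loc_start = loc_start or 0
        insertions = _mask_insertions(res["cigar"], min_insertion)
        # positions are relative to the aligned span; express them relative
        # to the unit start on the forward strand
        if orient == "-":
            span = loc_end_incl + 1 - loc_start
            insertions = [(span - (p + ln), ln, c) for p, ln, c in insertions]
        unit_start = region_lo + loc_start
        unit_end = region_lo + loc_end_incl + 1
        found.append(
            RdnaUnit(
                sequence_name,
                unit_start,
                unit_end,
                orient,
                intact=not insertions,
                insertions=tuple(sorted(insertions)),
                coding_start=cs,
                coding_end=ce,
            )
        )
    found.sort(key=lambda u: u.start)
    return found


def _mask_insertions(
    cigar: str, min_insertion: int, window: int = 51, dip: float = 0.7
) -> list[tuple[int, int, str]]:
    """Insertion-like disruptions from an extended CIGAR.

    Builds a per-target-column match mask and reports maximal runs whose
    centered windowed match fraction stays below `dip`, trimmed by the
    half-window smear, when the trimmed run is >= min_insertion columns.
    """
    ops = parse_cigar(cigar)
    span = sum(n for n, op in ops if op in ("=", "X", "D"))
    mask = np.zeros(span, dtype=float)
    tpos = 0
    for n, op in ops:
        if op == "=":
            mask[tpos : tpos + n] = 1.0
            tpos += n
        elif op in ("X", "D"):
            tpos += n
    if span == 0:
        return []
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(mask)])
    lo = np.maximum(np.arange(span) - half, 0)
    hi = np.minimum(np.arange(span) + half + 1, span)
    local = (csum[hi] - csum[lo]) / (hi - lo)
    below = local < dip
    runs: list[tuple[int, int]] = []
    i = 0
    while i < span:
        if not below[i]:
            i += 1
            continue
        j = i
        while j + 1 < span and below[j + 1]:
            j += 1
        # accidental matches fragment one disruption into several dips;
        # nearby runs belong to the same insertion
        if runs and i - runs[-1][1] <= 2 * window:
            runs[-1] = (runs[-1][0], j)
        else:
            runs.append((i, j))
        i = j + 1
    out: list[tuple[int, int, str]] = []
    for i, j in runs:
        run = j - i + 1
        lo_t = i + half if run > window else i
        hi_t = j - half if run > window else j
        if (hi_t - lo_t + 1) >= 0.7 * min_insertion:
            out.append((lo_t, hi_t - lo_t + 1, "insertion"))
    return out


# ---------------------------------------------------------------------------
# copy number


def _region_mean(depth_df, region: tuple[str, int, int], min_bins: int) -> float:
    chrom, start, end = region
    sel = depth_df[
        (depth_df["chrom"] == chrom)
        & (depth_df["bin_start"] >= start)
        & (depth_df["bin_start"] < end)
    ]
    if len(sel) < min_bins:
        raise InputError(
            f"region {chrom}:{start}-{end} covered by {len(sel)} bins "
            f"(need >= {min_bins})"
        )
    return float(sel["value"].mean())


def estimate_total_copies(
    depth_track,
    rdna_region: tuple[str, int, int],
    single_copy_region: tuple[str, int, int],
    min_bins: int = 50,
) -> float:
    """Diploid rDNA copy number from the depth ratio to a single-copy region.

    copies = 2 × mean_depth(rDNA) / mean_depth(single-copy). Linear in rDNA
    depth; rounding is left to the caller.
    """
    rdna_mean = _region_mean(depth_track, rdna_region, min_bins)
    single_mean = _region_mean(depth_track, single_copy_region, min_bins)
    if single_mean <= 0:
        raise EstimationError("single-copy region has zero depth")
    return 2.0 * rdna_mean / single_mean


def allocate_array_copies(
    total: float,
    fractions: dict[str, float],
) -> CopyAllocation:
    """Integer copies per array from fractional intensities.

    Fractions must be non-negative and sum to 1 within ±0.02 (renormalized).
    Largest-remainder rounding guarantees the allocated copies sum exactly
    to round(total); remainder ties break by larger fraction, then array id.
    """
    if not fractions:
        raise InputError("no arrays to allocate to")
    for a, f in fractions.items():
        if f < 0:
            raise InputError(f"negative fraction for array {a!r}")
    s = sum(fractions.values())
    if not 0.98 <= s <= 1.02:
        raise InputError(f"fractions sum to {s:.4f}, outside [0.98, 1.02]")
    target = int(round(total))
    norm = {a: f / s for a, f in fractions.items()}
    raw = {a: target * f for a, f in norm.items()}
    base = {a: math.floor(v) for a, v in raw.items()}
    remainder = target - sum(base.values())
    order = sorted(
        norm, key=lambda a: (-(raw[a] - base[a]), -norm[a], a)
    )
    for a in order[:remainder]:
        base[a] += 1
    arrays = tuple((a, norm[a], base[a]) for a in sorted(norm))
    assert sum(c for _, _, c in arrays) == target
    return CopyAllocation(total_copies=total, arrays=arrays)


# ---------------------------------------------------------------------------
# methylation: activity and CDRs


def _bins_in(track, chrom: str, intervals: list[tuple[int, int]], bin_size: int):
    sel = track[track["chrom"] == chrom]
    if sel.empty or not intervals:
        return sel.iloc[0:0]
    starts = sel["bin_start"].to_numpy()
    mask = np.zeros(len(sel), dtype=bool)
    for s, e in intervals:
        mask |= (starts + bin_size > s) & (starts < e)
    return sel[mask]


def _infer_bin_size(track) -> int:
    starts = np.sort(track["bin_start"].unique())
    if len(starts) < 2:
        return 1
    return int(np.diff(starts).min())


def group_units_into_arrays(
    units: list[RdnaUnit], max_gap: int | None = None
) -> dict[str, list[RdnaUnit]]:
    """Cluster units into arrays: same sequence, gaps <= 2 unit lengths."""
    arrays: dict[str, list[RdnaUnit]] = {}
    by_seq: dict[str, list[RdnaUnit]] = {}
    for u in sorted(units, key=lambda u: (u.sequence_name, u.start)):
        by_seq.setdefault(u.sequence_name, []).append(u)
    for seq_name, seq_units in by_seq.items():
        idx = 0
        current: list[RdnaUnit] = []
        for u in seq_units:
            gap_limit = max_gap if max_gap is not None else 2 * (u.end - u.start)
            if current and u.start - current[-1].end > gap_limit:
                arrays[f"{seq_name}_array{idx}"] = current
                idx += 1
                current = []
            current.append(u)
        if current:
            arrays[f"{seq_name}_array{idx}"] = current
    return arrays


def classify_activity(
    methylation_track,
    units: list[RdnaUnit],
    threshold: float = 0.5,
) -> list[MethylationSummary]:
    """Per-array activity call from coding-region methylation.

    coding_mean < threshold -> active, else silent. The IGS mean is reported
    for completeness but not used for the call (it stays methylated in both
    states).
    """
    if not units:
        raise ClassificationError("no rDNA units supplied")
    bin_size = _infer_bin_size(methylation_track)
    out: list[MethylationSummary] = []
    for array_id, members in sorted(group_units_into_arrays(units).items()):
        chrom = members[0].sequence_name
        coding_iv = [(u.coding_start, u.coding_end) for u in members]
        igs_iv = []
        for u in members:
            if u.orientation == "+":
                igs_iv.append((u.coding_end, u.end))
            else:
                igs_iv.append((u.start, u.coding_start))
        coding_bins = _bins_in(methylation_track, chrom, coding_iv, bin_size)
        igs_bins = _bins_in(methylation_track, chrom, igs_iv, bin_size)
        if coding_bins.empty:
            raise ClassificationError(
                f"array {array_id}: no methylation bins overlap coding regions"
            )
        coding_mean = float(coding_bins["value"].mean())
        igs_mean = float(igs_bins["value"].mean()) if not igs_bins.empty else float("nan")
        out.append(
            MethylationSummary(
                array_id,
                coding_mean,
                igs_mean,
                "active" if coding_mean < threshold else "silent",
            )
        )
    return out


def call_cdrs(
    methylation_track,
    active_array: tuple[str, int, int],
    min_cdr_span: int = 10000,
    dip_factor: float = 0.5,
    smooth_bins: int = 11,
) -> list[CDRCall]:
    """Centromere dip regions: sustained methylation dips in an active array.

    Bins inside the array are smoothed with a centered moving mean; maximal
    runs of bins below dip_factor × array mean seed the calls, and each
    run's edges are then refined outward/inward on the raw bins (smoothing
    blurs dip boundaries by ~half the smoothing window, which would erode
    genuine dips below min_cdr_span). Runs spanning >= min_cdr_span are
    reported with their inside/flank methylation means.
    """
    if not 0 < dip_factor < 1:
        raise ParameterError("dip_factor must lie in (0, 1)")
    chrom, start, end = active_array
    sel = methylation_track[
        (methylation_track["chrom"] == chrom)
        & (methylation_track["bin_start"] >= start)
        & (methylation_track["bin_start"] < end)
    ].sort_values("bin_start")
    if sel.empty:
        raise InputError("active array not covered by the methylation track")
    bin_size = _infer_bin_size(methylation_track)
    vals = sel["value"].to_numpy(dtype=float)
    starts = sel["bin_start"].to_numpy(dtype=int)
    half = smooth_bins // 2
    smooth = np.array(
        [vals[max(0, i - half) : i + half + 1].mean() for i in range(len(vals))]
    )
    cutoff = dip_factor * vals.mean()
    below = smooth < cutoff
    out: list[CDRCall] = []
    i = 0
    while i < len(below):
        if not below[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(below) and below[j + 1]:
            j += 1
        # refine the run on raw bins: the smoothed signal blurs edges
        lo, hi = i, j
        while lo > 0 and vals[lo - 1] < cutoff:
            lo -= 1
        while lo <= hi and vals[lo] >= cutoff:
            lo += 1
        while hi + 1 < len(vals) and vals[hi + 1] < cutoff:
            hi += 1
        while hi >= lo and vals[hi] >= cutoff:
            hi -= 1
        if hi < lo:
            i = j + 1
            continue
        i, j = lo, hi
        span_start = int(starts[i])
        span_end = int(starts[j]) + bin_size
        if span_end - span_start >= min_cdr_span:
            inside = vals[i : j + 1].mean()
            flank_vals = np.concatenate([vals[:i], vals[j + 1 :]])
            flank = flank_vals.mean() if flank_vals.size else float("nan")
            out.append(
                CDRCall(chrom, span_start, span_end, float(inside), float(flank))
            )
        i = j + 1
    return out


# ---------------------------------------------------------------------------
# sex comparison


def compare_sex_copy_number(
    samples: list[tuple[str, str, float]],
    n_permutations: int = 9999,
    seed: int = 0,
) -> tuple[float, float, dict[str, float]]:
    """Two-sided rank-sum permutation test for sex-dimorphic rDNA copy number.

    samples are (id, sex, diploid_copies) with sex in {"M", "F"}. The
    statistic is the male rank sum centered at its null expectation; the
    p-value is the permutation tail probability of |statistic|. Group means
    report the direction.
    """
    from scipy.stats import rankdata

    males = [c for _, s, c in samples if s.upper().startswith("M")]
    females = [c for _, s, c in samples if s.upper().startswith("F")]
    if len(males) < 2 or len(females) < 2:
        raise StatTestError("need >= 2 samples of each sex")
    if len(males) + len(females) != len(samples):
        raise StatTestError("sex labels must be M or F")
    values = np.array([c for _, _, c in samples], dtype=float)
    is_male = np.array([s.upper().startswith("M") for _, s, _ in samples])
    ranks = rankdata(values)
    n_m = is_male.sum()
    expected = n_m * (len(values) + 1) / 2.0
    observed = float(ranks[is_male].sum() - expected)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(values))
        stat = ranks[perm[:n_m]].sum() - expected
        if abs(stat) >= abs(observed) - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    means = {
        "male_mean": float(np.mean(males)),
        "female_mean": float(np.mean(females)),
    }
    return observed, p, means
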