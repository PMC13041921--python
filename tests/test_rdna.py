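"""rDNA unit detection, copy-number estimation/allocation, activity calls,
CDR detection and the sex-difference permutation test."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from satarch._align import revcomp
from satarch.errors import (
    ClassificationError,
    EstimationError,
    InputError,
    StatTestError,
)
from satarch.rdna import (
    allocate_array_copies,
    call_cdrs,
    classify_activity,
    compare_sex_copy_number,
    estimate_total_copies,
    find_rdna_units,
)
from satarch.synthetic import (
    RdnaFeature,
    RdnaUnitModel,
    SpacerFeature,
    TrackSpec,
    simulate_depth_track,
    synthesize_acrocentric_arm,
)
from tests.conftest import make_random_dna


@pytest.fixture(scope="module")
def unit_model():
    return RdnaUnitModel(
        coding=make_random_dna(2000, seed=100), igs=make_random_dna(1500, seed=101)
    )


class TestFindUnits:
    def test_intact_tandem_units(self, unit_model):
        seq = (unit_model.coding + unit_model.igs) * 5
        units = find_rdna_units(seq, (unit_model.coding, unit_model.igs))
        assert len(units) == 5
        assert all(u.intact for u in units)
        assert all(u.orientation == "+" for u in units)
        assert [u.start for u in units] == [i * 3500 for i in range(5)]
        assert all(u.coding_end - u.coding_start == 2000 for u in units)

    def test_insertion_flags_degraded(self, unit_model):
        insert = make_random_dna(300, seed=102)
        broken = unit_model.coding[:900] + insert + unit_model.coding[900:]
        seq = (
            unit_model.coding + unit_model.igs
            + broken + unit_model.igs
            + unit_model.coding + unit_model.igs
        )
        units = find_rdna_units(seq, (unit_model.coding, unit_model.igs))
        assert len(units) == 3
        flags = [u.intact for u in units]
        assert flags == [True, False, True]
        (pos, length, cls) = units[1].insertions[0]
        assert cls == "insertion"
        # the windowed disruption detector brackets the true insert within
        # about one smoothing window (51 columns) at each end
        assert abs(length - 300) <= 75
        assert abs(pos - 900) <= 60

    def test_mixed_orientation_recovered(self, unit_model):
        unit = unit_model.coding + unit_model.igs
        seq = unit + revcomp(unit) + unit
        units = find_rdna_units(seq, (unit_model.coding, unit_model.igs))
        assert [u.orientation for u in units] == ["+", "-", "+"]

    def test_no_hits_empty(self, unit_model):
        seq = make_random_dna(10000, seed=103)
        assert find_rdna_units(seq, (unit_model.coding, unit_model.igs)) == []


def _track(values_by_region, bin_size=100, chrom="chrA"):
    rows = []
    pos = 0
    for value, n_bins in values_by_region:
        for _ in range(n_bins):
            rows.append((chrom, pos, value))
            pos += bin_size
    return pd.DataFrame(rows, columns=["chrom", "bin_start", "value"])


class TestEstimateCopies:
    def test_depth_ratio_formula(self):
        track = _track([(1000.0, 60), (20.0, 60)])
        copies = estimate_total_copies(
            track, ("chrA", 0, 6000), ("chrA", 6000, 12000)
        )
        assert copies == pytest.approx(100.0)  # 2 × 1000 / 20

    def test_zero_rdna_depth_zero_copies(self):
        track = _track([(0.0, 60), (20.0, 60)])
        assert estimate_total_copies(
            track, ("chrA", 0, 6000), ("chrA", 6000, 12000)
        ) == 0.0

    def test_zero_single_copy_depth_rejected(self):
        track = _track([(1000.0, 60), (0.0, 60)])
        with pytest.raises(EstimationError):
            estimate_total_copies(track, ("chrA", 0, 6000), ("chrA", 6000, 12000))

    def test_insufficient_bins_rejected(self):
        track = _track([(1000.0, 10), (20.0, 60)])
        with pytest.raises(InputError):
            estimate_total_copies(track, ("chrA", 0, 1000), ("chrA", 1000, 7000))

    def test_linearity_on_noiseless_track(self):
        one = _track([(500.0, 60), (25.0, 60)])
        two = _track([(1000.0, 60), (25.0, 60)])
        c1 = estimate_total_copies(one, ("chrA", 0, 6000), ("chrA", 6000, 12000))
        c2 = estimate_total_copies(two, ("chrA", 0, 6000), ("chrA", 6000, 12000))
        assert c2 == pytest.approx(2 * c1)

    def test_generator_roundtrip(self, unit_model):
        plan = [
            SpacerFeature(20000, label="single_copy"),
            RdnaFeature("rdna_array", unit_model, 12),
        ]
        seq, truth = synthesize_acrocentric_arm(plan, seed=9, name="chrA")
        spec = TrackSpec(mean_depth=30, noise_sd=2, bin_size=100)
        depth, _ = simulate_depth_track({"chrA": seq}, truth, spec, 100, seed=9)
        block = truth.of_class("rdna_array")[0]
        est = estimate_total_copies(
            depth, ("chrA", block.start, block.end), ("chrA", 0, 20000)
        )
        assert abs(est - 100) <= 5


def _largest_remainder_oracle(total, fractions):
    """Independent allocation oracle: enumerate floor + remainder ordering."""
    s = sum(fractions.values())
    norm = {a: f / s for a, f in fractions.items()}
    raw = {a: total * f for a, f in norm.items()}
    base = {a: math.floor(v) for a, v in raw.items()}
    rem = total - sum(base.values())
    ranked = sorted(norm, key=lambda a: (base[a] - raw[a], -norm[a], a))
    for a in ranked[:rem]:
        base[a] += 1
    return base


class TestAllocation:
    def test_single_array_takes_all(self):
        alloc = allocate_array_copies(100, {"a": 1.0})
        assert alloc.copies("a") == 100

    def test_exact_quarters(self):
        alloc = allocate_array_copies(100, {"a": 0.25, "b": 0.75})
        assert (alloc.copies("a"), alloc.copies("b")) == (25, 75)

    def test_y_linked_share_of_male_total(self):
        # a diploid total of 282 with the Y array contributing 13.5% of
        # fluorescence: expected Y copy number 38, total conserved exactly
        fractions = {"y": 0.135}
        for i in range(9):
            fractions[f"a{i}"] = 0.865 / 9
        alloc = allocate_array_copies(282, fractions)
        assert alloc.copies("y") == 38
        assert sum(c for _, _, c in alloc.arrays) == 282
        assert {a: c for a, _, c in alloc.arrays} == _largest_remainder_oracle(
            282, fractions
        )

    def test_negative_fraction_rejected(self):
        with pytest.raises(InputError):
            allocate_array_copies(100, {"a": -0.1, "b": 1.1})

    def test_bad_fraction_sum_rejected(self):
        with pytest.raises(InputError):
            allocate_array_copies(100, {"a": 0.5, "b": 0.4})

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0.01, 1.0), min_size=1, max_size=12),
        st.integers(0, 1000),
    )
    def test_total_conserved_for_any_fractions(self, weights, total):
        fractions = {f"a{i}": w / sum(weights) for i, w in enumerate(weights)}
        alloc = allocate_array_copies(float(total), fractions)
        assert sum(c for _, _, c in alloc.arrays) == round(total)


class TestActivity:
    def _meth_track(self, coding_value, igs_value):
        # 3 units of 2000 coding + 1500 IGS
        rows = []
        for u in range(3):
            base = u * 3500
            for b in range(0, 2000, 100):
                rows.append(("chrA", base + b, coding_value))
            for b in range(2000, 3500, 100):
                rows.append(("chrA", base + b, igs_value))
        return pd.DataFrame(rows, columns=["chrom", "bin_start", "value"])

    def _units(self, unit_model):
        seq = (unit_model.coding + unit_model.igs) * 3
        return find_rdna_units(seq, (unit_model.coding, unit_model.igs),
                               sequence_name="chrA")

    def test_low_coding_methylation_active(self, unit_model):
        out = classify_activity(self._meth_track(0.1, 0.8), self._units(unit_model))
        assert len(out) == 1
        assert out[0].state == "active"
        assert out[0].coding_mean == pytest.approx(0.1)
        assert out[0].igs_mean == pytest.approx(0.8)

    def test_high_coding_methylation_silent(self, unit_model):
        out = classify_activity(self._meth_track(0.9, 0.8), self._units(unit_model))
        assert out[0].state == "silent"

    def test_missing_bins_rejected(self, unit_model):
        empty = pd.DataFrame(
            [("chrZ", 0, 0.5)], columns=["chrom", "bin_start", "value"]
        )
        with pytest.raises(ClassificationError):
            classify_activity(empty, self._units(unit_model))

    def test_generator_roundtrip_active_array(self, unit_model):
        plan = [RdnaFeature("rdna_array", unit_model, 8)]
        seq, truth = synthesize_acrocentric_arm(plan, seed=12, name="chrA")
        spec = TrackSpec(
            mean_depth=30, noise_sd=2, bin_size=100,
            methylation_states=(("rdna_coding", 0.1), ("rdna_igs", 0.8)),
        )
        _, meth = simulate_depth_track({"chrA": seq}, truth, spec, 100, seed=12)
        units = find_rdna_units(seq, (unit_model.coding, unit_model.igs),
                                sequence_name="chrA")
        out = classify_activity(meth, units)
        assert out[0].state == "active"
        assert abs(out[0].igs_mean - 0.8) <= 0.05


class TestCDR:
    def _meth(self, pattern, bin_size=500):
        rows = []
        for i, v in enumerate(pattern):
            rows.append(("chrA", i * bin_size, v))
        return pd.DataFrame(rows, columns=["chrom", "bin_start", "value"])

    def test_uniform_methylation_no_cdr(self):
        track = self._meth([0.8] * 100)
        assert call_cdrs(track, ("chrA", 0, 50000)) == []

    def test_planted_dip_recovered_within_one_bin(self):
        # 20 kb dip to 0.1 inside a 0.8 background (bins of 500 bp)
        pattern = [0.8] * 40 + [0.1] * 40 + [0.8] * 40
        track = self._meth(pattern)
        cdrs = call_cdrs(track, ("chrA", 0, 60000))
        assert len(cdrs) == 1
        c = cdrs[0]
        assert abs(c.start - 40 * 500) <= 500
        assert abs(c.end - 80 * 500) <= 500
        assert c.mean_methylation_inside < c.flank_mean

    def test_two_separated_dips(self):
        pattern = (
            [0.8] * 30 + [0.1] * 25 + [0.8] * 20 + [0.1] * 25 + [0.8] * 30
        )
        cdrs = call_cdrs(self._meth(pattern), ("chrA", 0, 65000))
        assert len(cdrs) == 2
        assert cdrs[0].end <= cdrs[1].start

    def test_short_dip_below_span_dropped(self):
        pattern = [0.8] * 50 + [0.1] * 10 + [0.8] * 50  # 5 kb < 10 kb
        assert call_cdrs(self._meth(pattern), ("chrA", 0, 55000)) == []

    def test_uncovered_array_rejected(self):
        with pytest.raises(InputError):
            call_cdrs(self._meth([0.8] * 10), ("chrB", 0, 5000))


class TestSexComparison:
    def test_identical_groups_high_p_vs_exact_enumeration(self):
        values = [10.0, 11.0, 12.0, 13.0, 14.0, 10.5, 11.5, 12.5, 13.5, 14.5]
        samples = [(f"m{i}", "M", values[i]) for i in range(5)] + [
            (f"f{i}", "F", values[5 + i]) for i in range(5)
        ]
        stat, p, means = compare_sex_copy_number(samples, n_permutations=9999, seed=4)
        # exact oracle: enumerate all C(10,5) male-label placements
        from scipy.stats import rankdata

        ranks = rankdata(values)
        expected = 5 * 11 / 2
        obs = abs(ranks[:5].sum() - expected)
        count = sum(
            abs(ranks[list(combo)].sum() - expected) >= obs - 1e-12
            for combo in itertools.combinations(range(10), 5)
        )
        exact_p = count / 252
        assert p == pytest.approx(exact_p, abs=0.05)
        assert p > 0.5

    def test_dimorphic_copy_number_detected(self):
        rng = np.random.default_rng(6)
        samples = [("m%d" % i, "M", float(rng.normal(500, 20))) for i in range(30)] + [
            ("f%d" % i, "F", float(rng.normal(400, 20))) for i in range(30)
        ]
        stat, p, means = compare_sex_copy_number(samples, n_permutations=999, seed=6)
        assert p < 0.01
        assert means["male_mean"] > means["female_mean"]

    def test_single_male_rejected(self):
        samples = [("m0", "M", 500.0)] + [
            (f"f{i}", "F", 400.0 + i) for i in range(5)
        ]
        with pytest.raises(StatTestError):
            compare_sex_copy_number(samples)

    def test_agrees_with_scipy_on_continuous_data(self):
        # independent cross-check: large-sample permutation p vs the
        # asymptotic rank-sum p on the same data
        from scipy.stats import ranksums

        rng = np.random.default_rng(8)
        m = rng.normal(0.6, 1.0, 20)
        f = rng.normal(0.0, 1.0, 20)
        samples = [(f"m{i}", "M", float(v)) for i, v in enumerate(m)] + [
            (f"f{i}", "F", float(v)) for i, v in enumerate(f)
        ]
        _, p_perm, _ = compare_sex_copy_number(samples, n_permutations=19999, seed=8)
        p_asym = ranksums(m, f).pvalue
        assert p_perm == pytest.approx(p_asym, abs=0.02)
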