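import numpy as np
import pytest

from clupaq.clupa import (
    REF,
    TARGET,
    AlignmentParams,
    MergedPeakList,
    align_set,
    apply_shift,
    build_cluster_tree,
    clupa_align,
    cut_tree_two,
    find_shift_region,
    find_shift_step,
    pairwise_correlation_map,
    satisfied_condition,
)
from clupaq.io import SpectrumSet
from clupaq.peaks import PeakDetectionParams, PeakList, detect_peaks_set
from clupaq.reference import select_reference
from clupaq.simulate import Peak, make_misaligned_cohort, make_spectrum


def _merged(ref_pos, tgt_pos):
    pos = np.concatenate([ref_pos, tgt_pos])
    owners = np.array([REF] * len(ref_pos) + [TARGET] * len(tgt_pos))
    return MergedPeakList(pos, owners, np.ones(pos.size))


class TestFindShiftRegion:
    def test_flat_flanks_take_earliest_minimum(self):
        x = np.zeros(100)
        x[50] = 10
        # all-equal flanks: earliest index wins on both sides, so the region
        # starts at outer.start and ends just past the first point right of
        # the peak
        assert find_shift_region(x, np.array([50]), (0, 100)) == (0, 52)

    def test_valley_left_of_peaks_bounds_region(self):
        x = np.full(100, 5.0)
        x[30] = 0.1  # quietest point left of the leftmost peak
        x[50] = 10
        x[80] = 0.2
        start, end = find_shift_region(x, np.array([50, 60]), (0, 100))
        assert start == 30 and end == 81

    def test_peaks_spanning_outer_gives_outer(self):
        x = np.full(40, 1.0)
        assert find_shift_region(x, np.array([0, 39]), (0, 40)) == (0, 40)

    def test_region_contains_all_peaks(self):
        rng = np.random.default_rng(1)
        x = rng.random(500)
        pos = np.sort(rng.choice(400, 8, replace=False)) + 50
        start, end = find_shift_region(x, pos, (0, 500))
        assert start <= pos.min() and pos.max() < end


class TestFindShiftStep:
    def test_identical_segments_lag_zero(self):
        x = np.sin(np.linspace(0, 20, 256)) + 1
        assert find_shift_step(x, x, 50) == 0

    def test_delayed_target_moves_left(self):
        """lag is the displacement added to target indices: a target delayed
        by k points yields -k."""
        x = np.zeros(512)
        x[200:210] = 100.0
        for k in (3, 17, 60):
            assert find_shift_step(x, np.roll(x, k), 100) == -k

    def test_all_zero_segment_is_uninformative(self):
        assert find_shift_step(np.zeros(64), np.arange(64.0), 10) == 0

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            n = int(rng.integers(64, 512))
            a, b = rng.random(n), rng.random(n)
            m = min(100, n - 1)
            lag = find_shift_step(a, b, m)
            aa, bb = a - a.min(), b - b.min()
            scores = {s: float(np.dot(aa, np.roll(bb, s))) for s in range(-m, m + 1)}
            best = max(sorted(scores, key=lambda k: (abs(k), k)), key=scores.get)
            assert lag == best


class TestApplyShift:
    def test_zero_lag_is_identity(self):
        x = np.arange(30.0)
        m = _merged([5], [12])
        y, m2, clamped = apply_shift(x, m, 0, (0, 30))
        np.testing.assert_array_equal(y, x)
        np.testing.assert_array_equal(m2.positions, m.positions)
        assert clamped == 0

    def test_ramp_slides_left_with_boundary_fill(self):
        x = np.arange(30.0)
        y, _, _ = apply_shift(x, _merged([], []), -2, (10, 20))
        np.testing.assert_array_equal(y[10:18], np.arange(12.0, 20.0))
        assert y[18] == y[19] == 19.0  # vacated points take the edge value
        np.testing.assert_array_equal(y[:10], x[:10])
        np.testing.assert_array_equal(y[20:], x[20:])

    def test_reference_peaks_untouched_target_peaks_move(self):
        x = np.zeros(50)
        m = _merged([15], [14])
        y, m2, _ = apply_shift(x, m, 3, (10, 30))
        assert m2.positions[m2.owners == REF][0] == 15
        assert m2.positions[m2.owners == TARGET][0] == 17

    def test_outside_region_intensity_sum_invariant(self):
        rng = np.random.default_rng(5)
        x = rng.random(100)
        y, _, _ = apply_shift(x, _merged([], []), 4, (20, 60))
        assert np.sum(y[:20]) == np.sum(x[:20])
        assert np.sum(y[60:]) == np.sum(x[60:])

    def test_peak_pushed_out_is_clamped_and_counted(self):
        m = _merged([], [28])
        _, m2, clamped = apply_shift(np.zeros(40), m, 5, (10, 30))
        assert clamped == 1
        assert m2.positions[0] == 29  # region edge


class TestClusterTree:
    def test_hand_agglomeration(self):
        m = _merged([0, 100], [1])
        tree = build_cluster_tree(m, "average")
        left, right = cut_tree_two(tree, 3)
        np.testing.assert_array_equal(np.sort(m.positions[left]), [0, 1])
        np.testing.assert_array_equal(m.positions[right], [100])

    def test_two_leaves_cut_to_singletons(self):
        m = _merged([10], [90])
        left, right = cut_tree_two(build_cluster_tree(m), 2)
        assert left.sum() == right.sum() == 1

    def test_single_entry_errors(self):
        with pytest.raises(ValueError):
            build_cluster_tree(_merged([5], []))

    def test_cut_partitions_leaves(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            pos = rng.integers(0, 1000, size=int(rng.integers(2, 30)))
            m = MergedPeakList(pos, rng.integers(0, 2, pos.size), np.ones(pos.size))
            left, right = cut_tree_two(build_cluster_tree(m), len(m))
            assert left.any() and right.any()
            assert not np.any(left & right)
            assert np.all(left | right)

    def test_average_linkage_heights_match_bruteforce(self):
        """Merge heights from scipy agree with a from-scratch agglomerative
        oracle on random 1-D points."""
        rng = np.random.default_rng(13)
        pts = np.sort(rng.choice(10_000, 20, replace=False)).astype(float)
        tree = build_cluster_tree(MergedPeakList(pts, np.zeros(20), np.ones(20)))

        clusters = [[p] for p in pts]
        heights = []
        while len(clusters) > 1:
            best = (np.inf, None)
            for i in range(len(clusters)):
                for j in range(i + 1, len(clusters)):
                    d = np.mean([abs(a - b) for a in clusters[i] for b in clusters[j]])
                    if d < best[0]:
                        best = (d, (i, j))
            d, (i, j) = best
            heights.append(d)
            clusters[i] = clusters[i] + clusters[j]
            del clusters[j]
        np.testing.assert_allclose(np.sort(tree[:, 2]), np.sort(heights), rtol=1e-10)


class TestSatisfiedCondition:
    def test_single_owner_never_recurses(self):
        params = AlignmentParams()
        assert not satisfied_condition(_merged([1, 5, 9], []), params)

    def test_two_peaks_total_stops(self):
        assert not satisfied_condition(_merged([1], [5]), AlignmentParams())

    def test_mixed_three_peaks_recurses(self):
        assert satisfied_condition(_merged([1, 9], [5]), AlignmentParams())


class TestClupaAlign:
    def test_identical_spectra_all_lags_zero(self):
        s = make_spectrum(1024, [Peak(200, 80, 6), Peak(700, 90, 7)])
        m = _merged([200, 700], [200, 700])
        aligned, trace = clupa_align(s, s, m, AlignmentParams(max_shift=50))
        np.testing.assert_array_equal(aligned, s.intensities)
        assert all(sh.lag == 0 for sh in trace.shifts)

    def test_single_peak_offset_recovered(self):
        ref = make_spectrum(1024, [Peak(400, 100, 6)])
        tgt = make_spectrum(1024, [Peak(430, 100, 6)])
        m = _merged([400], [430])
        aligned, trace = clupa_align(ref, tgt, m, AlignmentParams(max_shift=60))
        apex = int(np.argmax(aligned))
        assert abs(apex - 400) <= 1
        assert trace.max_abs_lag <= 60

    def test_two_region_opposite_shifts_need_recursion(self):
        """Opposite local shifts (+k, -k) in well-separated clusters: a single
        rigid shift cannot fix both, recursion does."""
        k = 25
        apexes = [(300, 380), (1500, 1580)]
        ref_peaks = [Peak(a, 100, 6) for pair in apexes for a in pair]
        tgt_peaks = [Peak(300 + k, 100, 6), Peak(380 + k, 100, 6),
                     Peak(1500 - k, 100, 6), Peak(1580 - k, 100, 6)]
        ref = make_spectrum(2048, ref_peaks)
        tgt = make_spectrum(2048, tgt_peaks)
        m = _merged([a for p in apexes for a in p], [p.apex for p in tgt_peaks])

        full, _ = clupa_align(ref, tgt, m, AlignmentParams(max_shift=100))
        flat, _ = clupa_align(ref, tgt, m, AlignmentParams(max_shift=100, max_depth=0))

        def residuals(x):
            return [
                abs(int(np.argmax(x[a - 15 : a + 16])) - 15)
                for pair in apexes
                for a in pair
            ]

        assert max(residuals(full)) <= 1
        assert max(residuals(flat)) > 1

    def test_mass_conserved_with_zero_flanks(self):
        # compactly supported bumps: the edge-fill value is exactly zero, so
        # total intensity is conserved exactly
        bump = np.hanning(21) * 100
        ref = np.zeros(512)
        tgt = np.zeros(512)
        ref[240:261] = bump
        tgt[260:281] = bump
        m = _merged([250], [270])
        aligned, _ = clupa_align(ref, tgt, m, AlignmentParams(max_shift=40))
        assert aligned.sum() == tgt.sum()
        assert abs(int(np.argmax(aligned)) - 250) <= 1

    def test_exclude_mask_freezes_region(self):
        ref = make_spectrum(512, [Peak(250, 100, 5)])
        tgt = make_spectrum(512, [Peak(270, 100, 5)])
        m = _merged([250], [270])
        aligned, trace = clupa_align(
            ref, tgt, m, AlignmentParams(max_shift=40, exclude_mask=((0, 512),))
        )
        np.testing.assert_array_equal(aligned, tgt.intensities)
        assert all(sh.lag == 0 for sh in trace.shifts)


@pytest.fixture(scope="module")
def aligned_cohort(misaligned_cohort, detect_params):
    sset, truth = misaligned_cohort
    peaklists = detect_peaks_set(sset, detect_params)
    ref_index = select_reference(peaklists).selected_index
    aligned, traces = align_set(sset, peaklists, ref_index, AlignmentParams(max_shift=100))
    return sset, truth, aligned, traces, ref_index


class TestAlignSet:
    def test_identical_cohort_unchanged(self):
        x = make_spectrum(512, [Peak(100, 50, 5), Peak(300, 70, 6)]).intensities
        sset = SpectrumSet(np.vstack([x, x, x]))
        pls = [PeakList(f"S{i}", np.array([100, 300]), x[[100, 300]]) for i in range(3)]
        aligned, _ = align_set(sset, pls, 0, AlignmentParams())
        np.testing.assert_array_equal(aligned.intensities, sset.intensities)

    def test_global_shifts_recovered(self, aligned_cohort):
        sset, truth, aligned, traces, ri = aligned_cohort
        residuals = []
        for i in range(sset.n_spectra):
            if i == ri:
                continue
            for a in truth.apexes[ri]:
                w = aligned.intensities[i][a - 8 : a + 9]
                residuals.append(abs(int(np.argmax(w)) - 8))
        assert np.mean(residuals) <= 1.0

    def test_correlation_strictly_increases(self, aligned_cohort):
        sset, _, aligned, _, _ = aligned_cohort
        _, before = pairwise_correlation_map(sset)
        _, after = pairwise_correlation_map(aligned)
        assert after > before

    def test_every_lag_within_bound(self, aligned_cohort):
        traces = aligned_cohort[3]
        assert max(t.max_abs_lag for t in traces if t is not None) <= 100

    def test_realignment_is_near_idempotent(self, aligned_cohort, detect_params):
        _, _, aligned, _, ri = aligned_cohort
        peaklists = detect_peaks_set(aligned, detect_params)
        again, traces = align_set(aligned, peaklists, ri, AlignmentParams(max_shift=100))
        lags = [abs(s.lag) for t in traces if t is not None for s in t.shifts]
        assert np.mean(lags) <= 1.0

    def test_reference_row_returned_unchanged(self, aligned_cohort):
        sset, _, aligned, _, ri = aligned_cohort
        np.testing.assert_array_equal(aligned.intensities[ri], sset.intensities[ri])

    def test_peakless_spectrum_passed_through(self):
        x = make_spectrum(512, [Peak(100, 50, 5)]).intensities
        sset = SpectrumSet(np.vstack([x, x + 1]))
        pls = [
            PeakList("S0", np.array([100]), x[[100]]),
            PeakList("S1", np.array([], dtype=int), np.array([])),
        ]
        aligned, traces = align_set(sset, pls, 0)
        np.testing.assert_array_equal(aligned.intensities[1], sset.intensities[1])
        assert traces[1] is None


class TestPairwiseCorrelation:
    def test_duplicated_spectra_all_ones(self):
        x = np.random.default_rng(0).random(64)
        corr, mean = pairwise_correlation_map(SpectrumSet(np.vstack([x, x, x])))
        np.testing.assert_allclose(corr, 1.0)
        assert mean == pytest.approx(1.0)

    def test_matches_direct_covariance_formula(self):
        rng = np.random.default_rng(2)
        X = rng.random((5, 80))
        corr, mean = pairwise_correlation_map(SpectrumSet(X))
        for i in range(5):
            for j in range(5):
                a, b = X[i] - X[i].mean(), X[j] - X[j].mean()
                expected = np.dot(a, b) / np.sqrt(np.dot(a, a) * np.dot(b, b))
                assert corr[i, j] == pytest.approx(expected, abs=1e-12)
        off = corr[~np.eye(5, dtype=bool)]
        assert mean == pytest.approx(off.mean(), abs=1e-12)

    def test_zero_variance_spectrum_zeroed(self):
        X = np.vstack([np.ones(50), np.random.default_rng(1).random(50)])
        corr, _ = pairwise_correlation_map(SpectrumSet(X))
        assert corr[0, 1] == 0.0 and corr[1, 0] == 0.0
        assert corr[0, 0] == 1.0
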