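import numpy as np
import pytest

import stridedtw as st
from stridedtw.msdtw import (
    SegmentationConfig,
    StrideSegment,
    WarpingPath,
    accumulate_costs,
    apply_constraints,
    backtrack,
    combine_distances,
    distance_function,
    distance_matrix,
    find_endpoints,
    segment_strides,
)
from stridedtw.signal_core import AXES, MultiAxisSignal
from stridedtw.template import StrideTemplate


class TestDistanceMatrix:
    def test_identical_traces_zero_diagonal(self):
        t = np.array([0.1, -0.4, 0.7, 0.2])
        D = distance_matrix(t, t)
        np.testing.assert_array_equal(np.diag(D), 0.0)
        assert np.all(D >= 0)

    def test_hand_computed_example(self):
        D = distance_matrix(np.array([0.0, 1.0]), np.array([2.0, 0.0, 1.0]))
        np.testing.assert_array_equal(D, [[4.0, 0.0, 1.0], [1.0, 1.0, 0.0]])

    def test_joint_scaling_is_quadratic(self):
        rng = np.random.default_rng(10)
        t, s = rng.normal(size=5), rng.normal(size=9)
        np.testing.assert_allclose(
            distance_matrix(2 * t, 2 * s), 4 * distance_matrix(t, s), atol=1e-12
        )

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            distance_matrix(np.array([]), np.array([1.0]))


class TestCombineDistances:
    def test_single_matrix_unchanged(self):
        D = np.arange(6.0).reshape(2, 3)
        np.testing.assert_array_equal(combine_distances([D]), D)

    def test_elementwise_sum(self):
        assert combine_distances([np.array([[1.0]]), np.array([[2.0]])]) == np.array(
            [[3.0]]
        )
        np.testing.assert_array_equal(
            combine_distances([np.zeros((2, 2)), np.zeros((2, 2))]), np.zeros((2, 2))
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            combine_distances([np.zeros((2, 3)), np.zeros((3, 2))])
        with pytest.raises(ValueError):
            combine_distances([])


class TestAccumulateCosts:
    def test_recurrence_holds_everywhere(self):
        rng = np.random.default_rng(11)
        D = rng.integers(0, 9, size=(6, 10)).astype(float)
        C = accumulate_costs(D)
        np.testing.assert_array_equal(C[0, :], D[0, :])
        np.testing.assert_allclose(C[:, 0], np.cumsum(D[:, 0]))
        for m in range(1, 6):
            for n in range(1, 10):
                assert C[m, n] == D[m, n] + min(
                    C[m - 1, n - 1], C[m - 1, n], C[m, n - 1]
                )

    def test_all_zero_distances(self):
        np.testing.assert_array_equal(accumulate_costs(np.zeros((4, 7))), 0.0)

    def test_first_column_running_sum(self):
        D = np.zeros((3, 4))
        D[:, 0] = [1.0, 2.0, 3.0]
        C = accumulate_costs(D)
        np.testing.assert_array_equal(C[:, 0], [1.0, 3.0, 6.0])

    def test_cost_dominates_distance(self):
        rng = np.random.default_rng(12)
        D = rng.random((8, 15))
        assert np.all(accumulate_costs(D) >= D)


class TestDistanceFunction:
    def test_top_row_returned(self):
        C = np.arange(12.0).reshape(3, 4)
        np.testing.assert_array_equal(distance_function(C), [8.0, 9.0, 10.0, 11.0])

    def test_single_row_template(self):
        D = np.array([[3.0, 0.0, 2.0]])
        C = accumulate_costs(D)
        np.testing.assert_array_equal(distance_function(C), D[0])


class TestFindEndpoints:
    def test_no_minima_below_tau(self):
        assert find_endpoints(np.array([5.0, 1.0, 5.0]), 1.0) == []

    def test_single_minimum(self):
        delta = np.array([5.0, 1.0, 5.0, 2.0, 5.0])
        assert find_endpoints(delta, 1.5) == [1]

    def test_two_minima_ascending_cost_order(self):
        delta = np.array([5.0, 2.0, 5.0, 1.0, 5.0])
        assert find_endpoints(delta, 3.0) == [3, 1]

    def test_plateau_collapses_to_leftmost(self):
        delta = np.array([5.0, 1.0, 1.0, 1.0, 5.0])
        assert find_endpoints(delta, 2.0) == [1]

    def test_boundaries_eligible(self):
        assert find_endpoints(np.array([1.0, 5.0, 0.5]), 2.0) == [2, 0]

    def test_interior_plateau_not_a_minimum_when_one_side_lower(self):
        delta = np.array([0.0, 1.0, 1.0, 5.0])
        assert find_endpoints(delta, 2.0) == [0]

    def test_tau_monotonicity(self):
        rng = np.random.default_rng(13)
        delta = rng.random(300) * 10
        counts = [len(find_endpoints(delta, tau)) for tau in np.arange(0.5, 10.5, 0.5)]
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            find_endpoints(np.array([1.0]), 0.0)


class TestBacktrack:
    def test_exact_match_gives_diagonal_path(self):
        rng = np.random.default_rng(14)
        t = rng.normal(size=6)
        s = np.concatenate([rng.normal(size=5) + 3, t, rng.normal(size=4) + 3])
        C = accumulate_costs(distance_matrix(t, s))
        path = backtrack(C, endpoint=10)  # embedded copy spans columns 5..10
        assert path.cost == pytest.approx(0.0)
        assert len(path) == 6
        assert path.points[0] == (5, 10) and path.points[-1] == (0, 5)
        deltas = {
            (a[0] - b[0], a[1] - b[1])
            for a, b in zip(path.points, path.points[1:])
        }
        assert deltas == {(1, 1)}

    def test_single_row_template_path(self):
        C = accumulate_costs(np.array([[1.0, 0.5, 2.0]]))
        path = backtrack(C, 1)
        assert path.points == ((0, 1),)

    def test_step_set_and_boundary_rows(self):
        rng = np.random.default_rng(15)
        D = rng.integers(0, 5, size=(5, 9)).astype(float)
        C = accumulate_costs(D)
        for endpoint in range(9):
            path = backtrack(C, endpoint)
            assert path.points[0] == (4, endpoint)
            assert path.points[-1][0] == 0
            for a, b in zip(path.points, path.points[1:]):
                assert (a[0] - b[0], a[1] - b[1]) in {(1, 0), (0, 1), (1, 1)}

    def test_path_cost_equals_summed_distances(self, brute_delta):
        rng = np.random.default_rng(16)
        D = rng.integers(0, 7, size=(4, 8)).astype(float)
        C = accumulate_costs(D)
        delta = distance_function(C)
        for endpoint in range(8):
            path = backtrack(C, endpoint)
            assert sum(D[m, n] for m, n in path.points) == pytest.approx(
                delta[endpoint]
            )

    def test_matches_brute_force_minimum(self, brute_delta):
        rng = np.random.default_rng(17)
        D = rng.integers(0, 9, size=(4, 8)).astype(float)
        delta = distance_function(accumulate_costs(D))
        np.testing.assert_allclose(delta, brute_delta(D))


def _path(start_col, end_col):
    # straight vertical path stub: only the endpoint columns matter here
    points = tuple((m, end_col) for m in range(1, -1, -1))
    points = ((1, end_col), (0, start_col))
    return WarpingPath(points=points, cost=0.0)


class TestApplyConstraints:
    def config(self, **kw):
        return SegmentationConfig(tau=10.0, axes=("GZ",), **kw)

    def test_too_short_candidate_rejected(self):
        fs = 102.4
        cand = [(_path(0, 10), 1.0)]  # 10 samples ~ 98 ms
        assert apply_constraints(cand, fs, self.config()) == []

    def test_plausible_candidate_kept(self):
        fs = 102.4
        cand = [(_path(0, 102), 1.0)]  # ~996 ms
        kept = apply_constraints(cand, fs, self.config())
        assert [(s.start, s.end) for s in kept] == [(0, 102)]

    def test_overlapping_costlier_candidate_dropped(self):
        fs = 102.4
        # ~1000 ms each, sharing ~150 ms
        a = (_path(0, 102), 3.0)
        b = (_path(87, 189), 5.0)
        kept = apply_constraints([b, a], fs, self.config())
        assert [(s.start, s.end) for s in kept] == [(0, 102)]
        assert kept[0].cost == 3.0

    def test_shared_border_sample_admissible(self):
        fs = 102.4
        a = (_path(0, 102), 1.0)
        b = (_path(102, 204), 2.0)  # one shared sample ~ 9.8 ms
        kept = apply_constraints([a, b], fs, self.config())
        assert len(kept) == 2

    def test_output_sorted_by_start(self):
        fs = 102.4
        cands = [(_path(300, 402), 1.0), (_path(0, 102), 2.0)]
        kept = apply_constraints(cands, fs, self.config())
        assert [s.start for s in kept] == [0, 300]

    def test_too_long_candidate_rejected(self):
        fs = 102.4
        cand = [(_path(0, 210), 1.0)]  # ~2051 ms
        assert apply_constraints(cand, fs, self.config()) == []


def make_template_signal(template_data, copies, fs=102.4):
    """Concatenate exact copies of a (M, 6) stride block into a signal."""
    data = np.vstack([template_data] * copies)
    return MultiAxisSignal(data, fs=fs, normalized=True)


class TestSegmentStrides:
    def test_flat_sequence_yields_nothing(self, canonical_template_norm, zero_signal):
        config = SegmentationConfig(tau=0.5, axes=("GY", "GZ"))
        assert segment_strides(zero_signal, canonical_template_norm, config) == []

    def test_exact_copies_recovered_at_boundaries(self, canonical_template_norm):
        block = canonical_template_norm.data  # 200-sample stride, all axes
        sig = make_template_signal(block, copies=5)
        config = SegmentationConfig(tau=0.5, axes=("GY", "GZ"))
        segs = segment_strides(sig, canonical_template_norm, config)
        assert [(s.start, s.end) for s in segs] == [
            (200 * k, 200 * k + 199) for k in range(5)
        ]
        assert all(s.cost == pytest.approx(0.0, abs=1e-20) for s in segs)

    def test_mild_jitter_walk_fully_recovered(self, mild_walk, canonical_template_norm):
        signal, labels = mild_walk
        nsig = st.normalize_signal(signal)
        config = SegmentationConfig(tau=5.0, axes=("GY", "GZ"))
        segs = segment_strides(nsig, canonical_template_norm, config)
        metrics = st.compute_metrics(st.match_strides(segs, labels, signal.fs))
        assert metrics.f_measure == 1.0

    def test_unnormalized_inputs_rejected(self, canonical_template_norm):
        raw = MultiAxisSignal(np.zeros((300, 6)), normalized=False)
        config = SegmentationConfig(tau=1.0, axes=("GZ",))
        with pytest.raises(ValueError):
            segment_strides(raw, canonical_template_norm, config)
        norm = MultiAxisSignal(np.zeros((300, 6)), normalized=True)
        raw_tmpl = st.canonical_template()
        with pytest.raises(ValueError):
            segment_strides(norm, raw_tmpl, config)

    def test_missing_axis_rejected(self, zero_signal):
        tmpl = StrideTemplate(np.zeros((10, 1)), axes=("GZ",), normalized=True)
        config = SegmentationConfig(tau=1.0, axes=("GY", "GZ"))
        with pytest.raises(ValueError):
            segment_strides(zero_signal, tmpl, config)


class TestScaleAndAdditivityProperties:
    def test_joint_scaling_scales_costs_quadratically(self):
        rng = np.random.default_rng(18)
        t, s = rng.normal(size=12), rng.normal(size=40)
        k = 3.0
        D1 = distance_matrix(t, s)
        D2 = distance_matrix(k * t, k * s)
        np.testing.assert_allclose(D2, k**2 * D1, atol=1e-10)
        np.testing.assert_allclose(
            accumulate_costs(D2), k**2 * accumulate_costs(D1), atol=1e-10
        )
        np.testing.assert_allclose(
            distance_function(accumulate_costs(D2)),
            k**2 * distance_function(accumulate_costs(D1)),
            atol=1e-10,
        )

    def test_multi_axis_delta_from_summed_matrix(self):
        rng = np.random.default_rng(19)
        t = rng.normal(size=(15, 2))
        s = rng.normal(size=(60, 2))
        per_axis = [distance_matrix(t[:, j], s[:, j]) for j in range(2)]
        combined = combine_distances(per_axis)
        delta_combined = distance_function(accumulate_costs(combined))
        # Delta on the summed matrix is the definition of multi-axis msDTW;
        # it differs in general from the sum of per-axis Deltas.
        delta_sum_of_axes = sum(
            distance_function(accumulate_costs(D)) for D in per_axis
        )
        assert not np.allclose(delta_combined, delta_sum_of_axes)

    def test_perfect_subsequence_gives_zero_delta(self):
        rng = np.random.default_rng(20)
        t = rng.normal(size=10)
        j = 17
        s = np.concatenate([rng.normal(size=j) + 5, t, rng.normal(size=8) + 5])
        delta = distance_function(accumulate_costs(distance_matrix(t, s)))
        assert delta[j + 10 - 1] == pytest.approx(0.0)


class TestSegmentationConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SegmentationConfig(tau=0.0)
        with pytest.raises(ValueError):
            SegmentationConfig(tau=1.0, min_stride_ms=500, max_stride_ms=400)
        with pytest.raises(ValueError):
            SegmentationConfig(tau=1.0, max_overlap_ms=-1)

    def test_axes_parsed(self):
        assert SegmentationConfig(tau=1.0, axes="GYGZ").axes == ("GY", "GZ")
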