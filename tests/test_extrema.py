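import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edgedyn import (
    TroughCriterion,
    apply_magnitude_criterion,
    detect_base_extrema,
    detect_extrema,
    peak_heights,
    summarize_subject,
    trough_durations,
)
from conftest import make_rss
from _oracles import adjacent_peak_max_subsets, interval_max_peaks, troughs_neighbor_scan


class TestCriterion:
    @pytest.mark.parametrize("theta", [-0.1, 0.5, 0.7])
    def test_theta_out_of_range(self, theta):
        with pytest.raises(ValueError):
            TroughCriterion(theta)

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            TroughCriterion(0.01, "nearest-peak")


class TestBaseDetection:
    def test_hand_series(self):
        res = detect_base_extrema(make_rss([3, 1, 2, 1, 3], tr=1.0))
        assert list(res.trough_indices) == [1, 3]
        assert list(res.peak_indices) == [2]
        assert list(res.peak_heights) == [2]
        assert list(res.durations_seconds) == [2.0]

    def test_monotone_series_has_no_extrema(self):
        res = detect_base_extrema(make_rss(np.arange(10.0)))
        assert res.n_troughs == 0
        assert res.n_peaks == 0
        assert len(res.durations_seconds) == 0

    def test_plateau_ties_disqualify(self):
        # equal neighbour => not strictly lower
        res = detect_base_extrema(make_rss([3, 1, 1, 3, 0.5, 3]))
        assert list(res.trough_indices) == [4]

    def test_matches_neighbor_scan_oracle(self, rng):
        v = rng.random(500) * 10
        res = detect_base_extrema(make_rss(v))
        assert list(res.trough_indices) == troughs_neighbor_scan(v)

    def test_endpoints_never_extrema(self, rng):
        for _ in range(20):
            v = rng.random(30)
            res = detect_base_extrema(make_rss(v))
            for arr in (res.trough_indices, res.peak_indices):
                assert 0 not in arr
                assert len(v) - 1 not in arr

    def test_too_short(self):
        with pytest.raises(ValueError):
            detect_base_extrema(make_rss([1, 2]))


class TestMagnitudeCriterion:
    def test_theta_zero_is_identity(self, rng):
        rss = make_rss(rng.random(100))
        base = detect_base_extrema(rss)
        out = apply_magnitude_criterion(base, rss, TroughCriterion(0.0, "adjacent-peak"))
        assert np.array_equal(out.trough_indices, base.trough_indices)
        assert np.array_equal(out.peak_indices, base.peak_indices)

    def test_boundary_inclusive_at_exact_percent(self):
        rss = make_rss([3.0, 2.97, 3.0])
        base = detect_base_extrema(rss)
        kept = apply_magnitude_criterion(base, rss, TroughCriterion(0.01, "adjacent-sample"))
        assert list(kept.trough_indices) == [1]
        removed = apply_magnitude_criterion(base, rss, TroughCriterion(0.02, "adjacent-sample"))
        assert removed.n_troughs == 0

    def test_adjacent_sample_literal_rule(self, rng):
        v = rng.random(200) * 5 + 1
        rss = make_rss(v)
        base = detect_base_extrema(rss)
        theta = 0.05
        out = apply_magnitude_criterion(base, rss, TroughCriterion(theta, "adjacent-sample"))
        expected = [
            t
            for t in base.trough_indices
            if v[t] <= (1 - theta) * v[t - 1] and v[t] <= (1 - theta) * v[t + 1]
        ]
        assert list(out.trough_indices) == expected

    def test_adjacent_peak_matches_exhaustive_subset_oracle(self):
        checked = 0
        seed = 9000
        while checked < 40:
            seed += 1
            rng = np.random.default_rng(seed)
            v = rng.random(30) * 10 + 1
            rss = make_rss(v)
            base = detect_base_extrema(rss)
            if base.n_troughs > 12:  # keep the 2^k enumeration feasible
                continue
            theta = float(rng.choice([0.02, 0.05, 0.1, 0.2]))
            res = apply_magnitude_criterion(base, rss, TroughCriterion(theta, "adjacent-peak"))
            best = adjacent_peak_max_subsets(v, base.trough_indices.tolist(), theta)
            assert tuple(res.trough_indices.tolist()) in best
            checked += 1

    def test_nesting_across_thetas_adjacent_sample(self, rng):
        v = rng.random(300) * 4 + 1
        rss = make_rss(v)
        base = detect_base_extrema(rss)
        sets = [
            set(
                apply_magnitude_criterion(
                    base, rss, TroughCriterion(th, "adjacent-sample")
                ).trough_indices.tolist()
            )
            for th in (0.0, 0.01, 0.02, 0.05)
        ]
        assert sets[3] <= sets[2] <= sets[1] <= sets[0]

    @pytest.mark.parametrize("mode", ["adjacent-sample", "adjacent-peak"])
    def test_monotone_in_theta(self, rng, mode):
        v = rng.random(400) * 4 + 1
        rss = make_rss(v, tr=0.72)
        counts, durs = [], []
        for th in (0.0, 0.01, 0.02, 0.05):
            res = detect_extrema(rss, TroughCriterion(th, mode))
            counts.append(res.n_troughs)
            durs.append(res.durations_seconds.mean())
        assert counts == sorted(counts, reverse=True)
        assert durs == sorted(durs)

    @pytest.mark.parametrize("mode", ["adjacent-sample", "adjacent-peak"])
    def test_scale_invariance_of_indices(self, rng, mode):
        v = rng.random(200) * 3 + 0.5
        for factor in (0.1, 7.3):
            a = detect_extrema(make_rss(v), TroughCriterion(0.02, mode))
            b = detect_extrema(make_rss(v * factor), TroughCriterion(0.02, mode))
            assert np.array_equal(a.trough_indices, b.trough_indices)
            assert np.array_equal(a.peak_indices, b.peak_indices)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(deadline=None, max_examples=40)
    def test_troughs_and_peaks_alternate(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.random(80) + 0.1
        res = detect_extrema(make_rss(v), TroughCriterion(0.05, "adjacent-peak"))
        assert res.n_peaks == max(0, res.n_troughs - 1)
        if res.n_peaks:
            merged = np.empty(res.n_troughs + res.n_peaks, dtype=int)
            merged[0::2] = res.trough_indices
            merged[1::2] = res.peak_indices
            assert np.all(np.diff(merged) > 0)

    def test_mismatched_series_length(self, rng):
        rss = make_rss(rng.random(50))
        base = detect_base_extrema(rss)
        with pytest.raises(ValueError):
            apply_magnitude_criterion(base, make_rss(rng.random(60)), TroughCriterion(0.01))


class TestDurationsAndHeights:
    def test_duration_arithmetic(self):
        res = detect_base_extrema(make_rss([3, 1, 2, 1, 3], tr=0.72))
        assert trough_durations(res) == pytest.approx([1.44])

    def test_single_trough_empty_durations(self):
        res = detect_base_extrema(make_rss([3, 1, 3]))
        assert len(trough_durations(res)) == 0

    def test_telescoping_sum(self, rng):
        v = rng.random(300)
        res = detect_base_extrema(make_rss(v, tr=0.72))
        if res.n_troughs >= 2:
            total = res.durations_seconds.sum()
            span = (res.trough_indices[-1] - res.trough_indices[0]) * 0.72
            assert total == pytest.approx(span)

    def test_heights_match_interval_max_oracle(self, rng):
        v = rng.random(250) * 6
        res = detect_base_extrema(make_rss(v))
        expected = interval_max_peaks(v, res.trough_indices.tolist())
        assert list(zip(res.peak_indices.tolist(), peak_heights(res).tolist())) == expected

    def test_peak_height_is_absolute_not_relative(self):
        # raising the floor between troughs does not change the peak height
        res = detect_base_extrema(make_rss([5, 1, 4, 1, 5]))
        assert list(peak_heights(res)) == [4]
        res2 = detect_base_extrema(make_rss([5, 3, 4, 3, 5]))
        assert list(peak_heights(res2)) == [4]


class TestSubjectSummary:
    def test_hand_summary(self):
        v = [9, 1, 2, 1, 4, 1, 9]
        s = summarize_subject(make_rss(v, tr=1.0), TroughCriterion(), "s1", "whole-brain")
        assert s.n_troughs == 3
        assert s.mean_trough_duration_seconds == pytest.approx(2.0)
        assert s.mean_peak_height == pytest.approx(3.0)
        assert not s.insufficient_troughs

    def test_mean_duration_telescoping_identity(self, rng):
        v = rng.random(400) + 0.2
        rss = make_rss(v, tr=0.72)
        s = summarize_subject(rss, TroughCriterion(0.01, "adjacent-sample"), "s1")
        res = detect_extrema(rss, TroughCriterion(0.01, "adjacent-sample"))
        if s.n_troughs >= 2:
            ident = (res.trough_indices[-1] - res.trough_indices[0]) * 0.72 / (s.n_troughs - 1)
            assert s.mean_trough_duration_seconds == pytest.approx(ident)

    def test_insufficient_troughs_flagged(self):
        s = summarize_subject(make_rss(np.arange(10.0)), TroughCriterion(), "s1")
        assert s.insufficient_troughs
        assert np.isnan(s.mean_trough_duration_seconds)
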