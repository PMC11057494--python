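import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from echolvef.cycles import (
    CycleSet,
    PeakParams,
    baseline_percentile,
    detect_ed_es,
    refine_jeffrey,
    refine_raw,
)
from echolvef.geometry import AreaCurve


def sinusoid(n_cycles=3, period=40, lo=1000.0, hi=2000.0):
    # -cos phase: peaks at half-periods, interior to the sampled range
    t = np.arange(n_cycles * period + period // 2)
    return AreaCurve((hi + lo) / 2 - (hi - lo) / 2 * np.cos(2 * np.pi * t / period))


class TestDetectEdEs:
    def test_sinusoid_pairs_at_analytic_extrema(self):
        period = 40
        curve = sinusoid(3, period)
        pairs = detect_ed_es(curve).pairs
        assert len(pairs) == 3
        for ed, es in pairs:
            # analytic: peaks at (k + 1/2) * period, troughs at k * period
            assert ed % period == period // 2
            assert es % period == 0
            # brute-force local oracle: argmax/argmin of the surrounding period
            w = period // 2
            seg = curve.areas[ed - w : ed + w]
            assert abs((ed - w + int(np.argmax(seg))) - ed) <= 1
            seg = curve.areas[es - w : es + w]
            assert abs((es - w + int(np.argmin(seg))) - es) <= 1

    def test_constant_curve_yields_no_cycles(self):
        assert len(detect_ed_es(AreaCurve(np.full(100, 7.0)))) == 0

    def test_short_curve_yields_no_cycles(self):
        assert len(detect_ed_es(AreaCurve(np.arange(30.0)))) == 0

    def test_low_prominence_spike_rejected(self):
        curve = sinusoid(3, 40)
        rng_ = curve.areas.max() - curve.areas.min()
        base = len(detect_ed_es(curve))
        spiked = curve.areas.copy()
        spiked[41] += 0.3 * rng_  # spike between two peaks, below half-range prominence
        assert len(detect_ed_es(AreaCurve(np.maximum(spiked, 0)))) == base

    def test_affine_invariance(self):
        curve = sinusoid(4, 45)
        scaled = AreaCurve(3.7 * curve.areas + 1234.5)
        assert detect_ed_es(curve).pairs == detect_ed_es(scaled).pairs

    @pytest.mark.parametrize("n_cycles", [1, 2, 3, 4, 5, 6])
    def test_pair_count_matches_simulated_cycles(self, n_cycles, af_curve_factory):
        _, _, truth = af_curve_factory(seed=n_cycles, n_cycles=n_cycles, period_cv=0.0,
                                       mean_period=48)
        pairs = detect_ed_es(AreaCurve(truth.areas)).pairs
        assert len(pairs) == n_cycles
        for (ed, es), ted, tes in zip(pairs, truth.ed_frames, truth.es_frames):
            assert abs(ed - ted) <= 1 and abs(es - tes) <= 1

    def test_min_distance_prunes_close_peaks(self):
        curve = sinusoid(6, 12)  # period below the default stepsize
        pairs = detect_ed_es(curve, PeakParams(min_distance=20)).pairs
        loose = detect_ed_es(curve, PeakParams(min_distance=5)).pairs
        assert len(pairs) < len(loose)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PeakParams(min_distance=0)
        with pytest.raises(ValueError):
            PeakParams(prominence_fraction=1.0)


def jeffrey_oracle(areas, ed, es, fraction=0.10):
    """Literal four-step transcription, independent of the implementation:
    (1) the ED-frame area; (2) sort all areas descending, take the top 10%;
    (3) sort the ED..ES window descending, take the top 10%; (4) average all
    selected areas.  ES analogue with ascending sorts."""
    areas = list(areas)
    part1 = [areas[ed]]
    part2 = sorted(areas, reverse=True)[: max(1, math.ceil(fraction * len(areas)))]
    window = areas[ed : es + 1]
    part3 = sorted(window, reverse=True)[: max(1, math.ceil(fraction * len(window)))]
    a_ed = sum(part1 + part2 + part3) / len(part1 + part2 + part3)
    p1 = [areas[es]]
    p2 = sorted(areas)[: max(1, math.ceil(fraction * len(areas)))]
    p3 = sorted(window)[: max(1, math.ceil(fraction * len(window)))]
    a_es = sum(p1 + p2 + p3) / len(p1 + p2 + p3)
    return a_ed, a_es


class TestRefineJeffrey:
    def test_matches_literal_step_by_step_oracle(self, af_curve_factory):
        _, _, truth = af_curve_factory(seed=3)
        curve = AreaCurve(truth.areas)
        cycles = detect_ed_es(curve)
        for i, (ed, es) in enumerate(cycles.pairs):
            got = refine_jeffrey(curve, cycles, i)
            assert got == pytest.approx(jeffrey_oracle(curve.areas, ed, es))

    def test_square_wave_pool_is_exact_level(self):
        # two-level wave: every member of the ED pool equals the high level
        areas = np.tile(np.r_[np.full(25, 2000.0), np.full(25, 1000.0)], 3)
        curve = AreaCurve(areas)
        cycles = CycleSet(pairs=((0, 30), (50, 80)), curve_ref=curve)
        a_ed, a_es = refine_jeffrey(curve, cycles, 0)
        assert a_ed == pytest.approx(2000.0)
        assert a_es == pytest.approx(1000.0)

    def test_corrupted_peak_recovered_better_than_raw(self, af_curve_factory):
        from echolvef import corrupt_curve

        _, _, truth = af_curve_factory(seed=11)
        curve = AreaCurve(truth.areas)
        cycles = detect_ed_es(curve)
        ed = cycles.pairs[1][0]
        bad = corrupt_curve(curve, [ed], 0.7)
        a_j, _ = refine_jeffrey(bad, cycles, 1)
        a_r, _ = refine_raw(bad, cycles, 1)
        true_peak = truth.areas[ed]
        assert abs(a_j - true_peak) < abs(a_r - true_peak)

    def test_small_fraction_degenerates_towards_raw(self, af_curve_factory):
        _, _, truth = af_curve_factory(seed=4)
        curve = AreaCurve(truth.areas)
        cycles = detect_ed_es(curve)
        a_raw = refine_raw(curve, cycles, 0)
        # fraction -> 0 keeps single-element top selections: the pool is the
        # ED frame plus the global and window maxima, all near the peak
        a_j = refine_jeffrey(curve, cycles, 0, fraction=1e-9)
        assert a_j[0] == pytest.approx(a_raw[0], rel=1e-9)
        assert a_j[1] == pytest.approx(a_raw[1], rel=0.02)

    def test_three_part_pooling_averages_part_means(self, af_curve_factory):
        _, _, truth = af_curve_factory(seed=5)
        curve = AreaCurve(truth.areas)
        cycles = detect_ed_es(curve)
        ed, es = cycles.pairs[0]
        areas = curve.areas
        n, m = areas.size, es - ed + 1
        top_all = np.sort(areas)[::-1][: math.ceil(0.1 * n)]
        top_win = np.sort(areas[ed : es + 1])[::-1][: math.ceil(0.1 * m)]
        expected = np.mean([areas[ed], top_all.mean(), top_win.mean()])
        got = refine_jeffrey(curve, cycles, 0, pooling="three_part")
        assert got[0] == pytest.approx(expected)

    def test_bad_cycle_index_rejected(self, af_curve_factory):
        _, _, truth = af_curve_factory(seed=6)
        curve = AreaCurve(truth.areas)
        cycles = detect_ed_es(curve)
        with pytest.raises(IndexError):
            refine_jeffrey(curve, cycles, len(cycles))


class TestBaselinePercentile:
    def test_linear_interpolation_convention(self):
        assert baseline_percentile(AreaCurve(np.arange(1.0, 101.0))) == pytest.approx(
            (90.1, 10.9)
        )
        assert baseline_percentile(AreaCurve(np.array([0.0, 100.0]))) == pytest.approx(
            (90.0, 10.0)
        )
        assert baseline_percentile(AreaCurve(np.full(5, 7.0))) == (7.0, 7.0)

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 1000))
    def test_ed_at_least_es(self, seed):
        areas = np.random.default_rng(seed).uniform(0, 100, 50)
        a_ed, a_es = baseline_percentile(AreaCurve(areas))
        assert a_ed >= a_es
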