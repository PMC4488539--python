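"""Dive detection, zero-offset correction and benthic/pelagic classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sealscape import dives
from sealscape.dives import (
    BENTHIC,
    PELAGIC,
    UNCLASSIFIED,
    DepthSeries,
    UnimodalScoresError,
    bottom_proportion,
    classify_dives,
    detect_dives,
    score_nadir,
    zero_offset_correct,
)


def brute_force_dives(times, depths, min_depth=5.0, surface=0.5):
    """Independent exhaustive scan: loop over samples, track submergence runs."""
    out = []
    run = []
    for i in range(len(times)):
        if depths[i] > surface:
            run.append(i)
        else:
            if run and max(depths[j] for j in run) >= min_depth:
                out.append((times[run[0]], times[run[-1]]))
            run = []
    if run and max(depths[j] for j in run) >= min_depth:
        out.append((times[run[0]], times[run[-1]]))
    return [(s, e) for s, e in out if e > s]


def synthetic_trace(rng, n_dives=100, dt=2.0):
    """Random mix of sub- and super-threshold submergences."""
    chunks = [np.zeros(5)]
    for _ in range(n_dives):
        depth = rng.uniform(1, 40)
        dur = rng.integers(4, 40)
        ramp = np.linspace(0, depth, dur // 2)
        chunks.append(np.concatenate([ramp, ramp[::-1]]))
        chunks.append(np.zeros(rng.integers(2, 10)))
    d = np.concatenate(chunks)
    return DepthSeries(times=dt * np.arange(len(d)), depths=d)


class TestZeroOffset:
    def test_constant_surface_offset_removed(self):
        # dive to 20 m between offset surface segments
        d = np.concatenate([np.full(50, 2.0), np.linspace(2, 22, 20),
                            np.full(30, 22.0), np.linspace(22, 2, 20),
                            np.full(50, 2.0)])
        s = DepthSeries(times=np.arange(len(d), dtype=float), depths=d)
        out = zero_offset_correct(s, window=60.0)
        assert np.allclose(out.depths[:40], 0.0, atol=1e-9)
        assert np.allclose(out.depths[-40:], 0.0, atol=1e-9)

    def test_already_zeroed_unchanged(self):
        d = np.concatenate([np.zeros(60), np.linspace(0, 30, 30),
                            np.linspace(30, 0, 30), np.zeros(60)])
        s = DepthSeries(times=np.arange(len(d), dtype=float), depths=d)
        # window longer than any dive so every window sees true surface
        out = zero_offset_correct(s, window=150.0)
        assert np.allclose(out.depths, s.depths, atol=1e-9)

    def test_linear_drift_removed(self, rng):
        # 0 -> 3 m drift over 6 h with regular dives; 1 h correction window
        dt = 5.0
        n = int(6 * 3600 / dt)
        t = dt * np.arange(n)
        depths = np.zeros(n)
        for start in range(0, n - 200, 360):  # a 300 s dive every 30 min
            depths[start + 60 : start + 120] = 25.0
        drifted = depths + 3.0 * t / t[-1]
        out = zero_offset_correct(
            DepthSeries(times=t, depths=drifted), window=3600.0
        )
        surface = depths == 0
        assert out.depths[surface].max() < 0.5

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            DepthSeries(times=np.array([]), depths=np.array([]))


class TestDetectDives:
    def test_simple_dive(self):
        s = DepthSeries(
            times=np.arange(6, dtype=float),
            depths=np.array([0, 0, 6, 10, 6, 0], dtype=float),
        )
        out = detect_dives(s)
        assert len(out) == 1
        assert out[0].max_depth == 10.0
        assert out[0].duration == out[0].end - out[0].start > 0

    def test_below_threshold_no_dives(self):
        d = np.concatenate([np.zeros(5), np.full(10, 4.9), np.zeros(5)])
        s = DepthSeries(times=np.arange(len(d), dtype=float), depths=d)
        assert detect_dives(s) == []

    def test_matches_exhaustive_scan(self, rng):
        s = synthetic_trace(rng)
        got = [(d.start, d.end) for d in detect_dives(s)]
        expected = brute_force_dives(s.times, s.depths)
        assert got == expected

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_tiling_property(self, seed):
        """Detected dives exactly tile the >=-threshold submergence intervals."""
        s = synthetic_trace(np.random.default_rng(seed), n_dives=30)
        got = [(d.start, d.end) for d in detect_dives(s)]
        assert got == brute_force_dives(s.times, s.depths)
        # ordered and non-overlapping
        for (s0, e0), (s1, e1) in zip(got, got[1:]):
            assert e0 < s1


class TestBottomProportion:
    def test_square_wave_is_one(self):
        t = np.arange(10, dtype=float)
        assert bottom_proportion(t, np.full(10, 30.0)) == 1.0

    def test_v_shape_analytic(self):
        # triangle dive: time with depth >= 0.8*max is 0.2 of the duration
        t = np.linspace(0, 100, 2001)
        d = 30 * (1 - np.abs(t - 50) / 50)
        assert bottom_proportion(t, d) == pytest.approx(0.2, abs=0.01)

    def test_matches_independent_timestep_count(self, rng):
        t = np.cumsum(rng.uniform(0.5, 1.5, 300))
        d = np.abs(rng.normal(10, 6, 300)) + 1
        got = bottom_proportion(t, d, 0.8)
        # independent loop: weight each sample by half its adjacent intervals
        thr = 0.8 * d.max()
        num = den = 0.0
        for i in range(len(t)):
            w = 0.0
            if i > 0:
                w += (t[i] - t[i - 1]) / 2
            if i < len(t) - 1:
                w += (t[i + 1] - t[i]) / 2
            den += w
            if d[i] >= thr:
                num += w
        assert got == pytest.approx(num / den, rel=1e-12)

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            bottom_proportion(np.array([1.0]), np.array([10.0]))


class TestClassify:
    def _mixture(self, rng, n=1000):
        lab = rng.uniform(size=n) < 0.5
        scores = np.where(lab, rng.normal(40, 4, n), rng.normal(8, 2, n))
        return np.clip(scores, 0.1, None), lab

    def test_two_gaussian_recovery(self, rng):
        scores, lab = self._mixture(rng)
        nadir = score_nadir(scores)
        assert np.mean((scores >= nadir) != lab) < 0.02

    def test_symmetric_clusters_nadir_at_midpoint(self, rng):
        s = np.concatenate([rng.normal(10, 1, 500), rng.normal(20, 1, 500)])
        nadir = score_nadir(s)
        assert nadir == pytest.approx(15.0, abs=1.5)  # within bandwidth tolerance

    def test_identical_scores_unimodal(self):
        with pytest.raises(UnimodalScoresError):
            score_nadir(np.full(50, 12.0))

    def test_unimodal_leaves_unclassified(self):
        recs = [
            dives.DiveRecord(start=i, end=i + 60, duration=60, max_depth=10,
                             bottom_time_prop=1.0, score=10.0)
            for i in range(20)
        ]
        labelled, nadir = classify_dives(recs)
        assert nadir is None
        assert all(d.dive_class == UNCLASSIFIED for d in labelled)
        labelled, nadir = classify_dives(recs, fallback_threshold=5.0)
        assert nadir == 5.0
        assert all(d.dive_class == BENTHIC for d in labelled)

    def test_order_invariance_and_scale_consistency(self, rng):
        scores, _ = self._mixture(rng, n=400)
        recs = [
            dives.DiveRecord(start=i, end=i + 60, duration=60, max_depth=s,
                             bottom_time_prop=1.0, score=s)
            for i, s in enumerate(scores)
        ]
        lab1, _ = classify_dives(recs)
        shuffled = list(recs)
        np.random.default_rng(1).shuffle(shuffled)
        lab2 = {d.start: d.dive_class for d in classify_dives(shuffled)[0]}
        assert all(d.dive_class == lab2[d.start] for d in lab1)
        # doubling all depths doubles scores, partition labels unchanged
        doubled = [
            dives.DiveRecord(start=d.start, end=d.end, duration=d.duration,
                             max_depth=2 * d.max_depth, bottom_time_prop=1.0,
                             score=2 * d.score)
            for d in recs
        ]
        lab3, nadir3 = classify_dives(doubled)
        _, nadir1 = classify_dives(recs)
        assert nadir3 == pytest.approx(2 * nadir1, rel=0.05)
        assert [d.dive_class for d in lab3] == [d.dive_class for d in lab1]

    def test_mixture_labels_pelagic_below_benthic_above(self, rng):
        scores, lab = self._mixture(rng, n=600)
        recs = [
            dives.DiveRecord(start=i, end=i + 60, duration=60, max_depth=s,
                             bottom_time_prop=1.0, score=s)
            for i, s in enumerate(scores)
        ]
        labelled, nadir = classify_dives(recs)
        for d in labelled:
            assert d.dive_class == (PELAGIC if d.score < nadir else BENTHIC)
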