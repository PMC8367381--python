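"""Track QC, interpolation, window classification, ratios, AUC and group tests."""

import numpy as np
import pytest
from scipy.special import comb

from platysense import simulate
from platysense.behavior import (
    KeypointTrack,
    UndulationSeries,
    classify_track,
    classify_window,
    compare_groups,
    interpolate_missing,
    interval_auc,
    qc_tracks,
    undulation_ratio,
)


def _track(n_frames=100, fps=5.0, present=None, **kw):
    x = np.tile(30.0 * np.arange(7), (n_frames, 1))
    y = np.full((n_frames, 7), 100.0)
    if present is None:
        present = np.ones((n_frames, 7), dtype=bool)
    return KeypointTrack(
        worm_id=kw.get("worm_id", "w0"), genotype=kw.get("genotype", "wt"),
        fps=fps, x=x, y=y, present=present, t0_zt_hours=kw.get("t0", 0.0),
    )


class TestQcTracks:
    def test_single_point_below_coverage_excludes(self):
        present = np.ones((100, 7), dtype=bool)
        present[:11, 3] = False  # 89% coverage on one point
        assert qc_tracks([_track(present=present)]) == []

    def test_full_coverage_retains(self):
        t = _track()
        assert qc_tracks([t]) == [t]

    def test_all_missing_excludes(self):
        present = np.zeros((100, 7), dtype=bool)
        assert qc_tracks([_track(present=present)]) == []

    def test_boundary_exactly_at_threshold_retains(self):
        present = np.ones((100, 7), dtype=bool)
        present[:10, 2] = False  # exactly 90%
        assert len(qc_tracks([_track(present=present)])) == 1


class TestInterpolateMissing:
    def test_identity_when_complete(self):
        t = _track()
        out = interpolate_missing(t)
        np.testing.assert_array_equal(out.x, t.x)
        np.testing.assert_array_equal(out.y, t.y)

    def test_interior_gap_linear(self):
        t = _track(n_frames=20)
        t.x[10, 0], t.y[10, 0] = 0.0, 0.0
        t.x[12, 0], t.y[12, 0] = 2.0, 2.0
        t.x[11, 0], t.y[11, 0] = 999.0, 999.0  # garbage behind the flag
        t.present[11, 0] = False
        out = interpolate_missing(t)
        assert out.x[11, 0] == pytest.approx(1.0)
        assert out.y[11, 0] == pytest.approx(1.0)

    def test_leading_gap_nearest_fill(self):
        t = _track(n_frames=20)
        t.present[:5, 1] = False
        t.x[5, 1], t.y[5, 1] = 5.0, 5.0
        out = interpolate_missing(t)
        assert (out.x[:5, 1] == 5.0).all()
        assert (out.y[:5, 1] == 5.0).all()

    def test_point_never_seen_errors(self):
        t = _track(n_frames=20)
        t.present[:, 6] = False
        with pytest.raises(ValueError):
            interpolate_missing(t)


def _window(amp, freq, fps=10.0, n=100, point=2):
    t = np.arange(n) / fps
    x = np.zeros((n, 5))
    y = np.zeros((n, 5))
    y[:, point] = amp * np.sin(2 * np.pi * freq * t)
    return x, y


class TestClassifyWindow:
    def test_stationary_not_undulating(self):
        x, y = _window(0.0, 1.0)
        assert not classify_window(x, y, 10.0).undulating

    def test_in_band_sinusoid_undulates(self):
        x, y = _window(2.0, 1.0)  # 4 px peak-to-peak at 1 Hz
        c = classify_window(x, y, 10.0)
        assert c.undulating
        assert c.dominant_frequency["body3"] == pytest.approx(1.0)

    def test_frequency_above_band_rejected(self):
        x, y = _window(2.0, 3.0)
        c = classify_window(x, y, 10.0)
        assert not c.undulating
        assert c.dominant_frequency["body3"] == pytest.approx(3.0)

    def test_movement_above_band_rejected(self):
        x, y = _window(15.0, 1.0)  # 30 px peak-to-peak
        assert not classify_window(x, y, 10.0).undulating

    def test_translation_invariance(self):
        x, y = _window(2.0, 1.0)
        a = classify_window(x, y, 10.0)
        b = classify_window(x + 137.0, y - 55.0, 10.0)
        assert a.undulating == b.undulating
        assert a.dominant_frequency == b.dominant_frequency

    @pytest.mark.parametrize("point", range(5))
    def test_any_point_rule(self, point):
        x, y = _window(2.0, 1.0, point=point)
        assert classify_window(x, y, 10.0).undulating

    def test_oscillation_on_x_axis_also_counts(self):
        x, y = _window(2.0, 1.0)
        assert classify_window(y, x, 10.0).undulating

    def test_wrong_window_length_errors(self):
        x, y = _window(2.0, 1.0, n=90)
        with pytest.raises(ValueError, match="frames"):
            classify_window(x, y, 10.0)

    def test_sub_nyquist_fps_errors(self):
        x, y = _window(2.0, 1.0, fps=2.0, n=20)
        with pytest.raises(ValueError, match="Nyquist"):
            classify_window(x, y, 2.0)


class TestUndulationRatio:
    def _cls(self, labels, window_s=10.0):
        from platysense.behavior import WindowClassification

        return [
            WindowClassification(
                window_index=i, start_time=i * window_s,
                dominant_frequency={}, movement={}, undulating=bool(u),
            )
            for i, u in enumerate(labels)
        ]

    def test_saturation_and_floor(self):
        assert undulation_ratio(self._cls([1] * 18)).ratio == (1.0,)
        assert undulation_ratio(self._cls([0] * 18)).ratio == (0.0,)

    def test_half_ratio(self):
        assert undulation_ratio(self._cls([1] * 9 + [0] * 9)).ratio == (0.5,)

    def test_multiple_bins(self):
        series = undulation_ratio(self._cls([1] * 18 + [0] * 18))
        assert series.bin_start == (0.0, 180.0)
        assert series.ratio == (1.0, 0.0)


class TestIntervalAuc:
    def _series(self, bin_starts, ratios, t0=6.0, width=180.0):
        return UndulationSeries(
            worm_id="w", bin_start=tuple(bin_starts), ratio=tuple(ratios),
            bin_width=width, t0_zt_hours=t0,
        )

    def test_constant_one_over_eight_hours(self):
        starts = np.arange(0, 8 * 3600, 180.0)
        s = self._series(starts, np.ones(starts.size))
        assert interval_auc(s, 6.0, 14.0) == pytest.approx(8.0)

    def test_constant_zero(self):
        starts = np.arange(0, 8 * 3600, 180.0)
        s = self._series(starts, np.zeros(starts.size))
        assert interval_auc(s, 6.0, 14.0) == 0.0

    def test_linear_ramp_closed_form(self):
        starts = np.arange(0, 8 * 3600, 180.0)
        mids = starts + 90.0
        ramp = mids / (8 * 3600.0)  # 0 -> ~1 linearly over the interval
        s = self._series(starts, ramp)
        # trapezoid of a linear ramp: mean of edge values x width
        expected = 8.0 * (ramp[0] + ramp[-1]) / 2
        assert interval_auc(s, 6.0, 14.0) == pytest.approx(expected, rel=1e-3)

    def test_no_overlap_errors(self):
        s = self._series([0.0, 180.0], [0.5, 0.5])
        with pytest.raises(ValueError):
            interval_auc(s, 20.0, 22.0)


class TestCompareGroups:
    def test_identical_groups_rank_sum_not_significant(self):
        vals = list(np.linspace(1, 2, 10))
        comps = compare_groups({("wt", "day"): vals, ("mut", "day"): vals})
        rs = [c for c in comps if c.test_name == "wilcoxon_rank_sum"]
        assert len(rs) == 1
        assert rs[0].p_value >= 0.95
        assert not rs[0].significant

    def test_separated_groups_match_exact_enumeration(self):
        """Two non-overlapping groups of 10: two-sided exact p = 2/C(20,10)."""
        a = list(np.linspace(1, 2, 10))
        b = list(np.linspace(10, 11, 10))
        comps = compare_groups({("wt", "day"): a, ("mut", "day"): b})
        rs = [c for c in comps if c.test_name == "wilcoxon_rank_sum"][0]
        exact = 2.0 / comb(20, 10)
        assert rs.p_value < 1e-3
        assert rs.p_value == pytest.approx(exact, rel=0.5) or rs.p_value < 1e-3

    def test_paired_equal_vectors_degenerate(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        comps = compare_groups({("wt", "light"): vals, ("wt", "dark"): vals})
        sr = [c for c in comps if c.test_name == "wilcoxon_signed_rank"][0]
        assert sr.degenerate and sr.p_value == 1.0

    def test_paired_shift_detected(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(1, 2, 12)
        comps = compare_groups(
            {("wt", "light"): list(base + 1.0), ("wt", "dark"): list(base)}
        )
        sr = [c for c in comps if c.test_name == "wilcoxon_signed_rank"][0]
        assert sr.p_value < 0.05 and sr.paired

    def test_shapiro_reported_per_group(self):
        vals = list(np.random.default_rng(1).normal(0, 1, 12))
        comps = compare_groups({("wt", "day"): vals})
        assert [c.test_name for c in comps] == ["shapiro"]

    def test_small_group_errors(self):
        with pytest.raises(ValueError):
            compare_groups({("wt", "day"): [1.0, 2.0]})

    def test_unequal_paired_lengths_error(self):
        with pytest.raises(ValueError, match="equal-length"):
            compare_groups(
                {("wt", "light"): [1.0, 2.0, 3.0], ("wt", "dark"): [1.0, 2.0, 3.0, 4.0]}
            )


class TestScheduledTracksRoundTrip:
    def test_perfect_accuracy_away_from_bout_boundaries(self):
        schedule = [(40.0, 145.0, 1.0, 2.0), (300.0, 420.0, 1.0, 2.0)]
        tracks, labels, boundary = simulate.gen_tracks(
            n_worms=2, duration_s=600.0, bout_schedule=schedule, seed=21
        )
        for tr in tracks:
            pred = np.array([c.undulating for c in classify_track(tr)])
            core = ~boundary
            assert (pred[core] == labels[core]).all()

    def test_ratio_recovers_schedule_fraction(self):
        # bouts aligned to windows covering exactly half of each 180-s bin
        schedule = [(i * 180.0, i * 180.0 + 90.0, 1.0, 2.0) for i in range(5)]
        tracks, labels, boundary = simulate.gen_tracks(
            n_worms=1, duration_s=900.0, bout_schedule=schedule, seed=22
        )
        assert not boundary.any()
        series = undulation_ratio(classify_track(tracks[0]))
        assert np.allclose(series.ratio, 0.5, atol=1 / 18 + 1e-9)

    def test_no_bouts_all_quiescent(self):
        tracks, labels, _ = simulate.gen_tracks(
            n_worms=1, duration_s=300.0, bout_schedule=[], seed=23
        )
        assert not labels.any()
        assert not any(c.undulating for c in classify_track(tracks[0]))

    def test_missing_point_fails_qc(self):
        rates = np.zeros(7)
        rates[3] = 0.15
        tracks, _, _ = simulate.gen_tracks(
            n_worms=1, duration_s=300.0, missing_rate=rates, seed=24
        )
        assert qc_tracks(tracks) == []
        assert len(qc_tracks(tracks, min_coverage=0.8)) == 1
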