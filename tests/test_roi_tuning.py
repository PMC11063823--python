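"""Per-ROI tuning math, classification criteria, and the block-shuffle
permutation test (examples, calibration, and null uniformity)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from dscircuit import imaging, roi_tuning as rt, synthetic as syn
from dscircuit.imaging import ROI


def tuning_oracle(mean_peaks, directions):
    """Independent trigonometric evaluation of the vector-sum formulas."""
    rx = sum(p * math.cos(math.radians(d))
             for p, d in zip(mean_peaks, directions))
    ry = sum(p * math.sin(math.radians(d))
             for p, d in zip(mean_peaks, directions))
    rt_ = sum(mean_peaks)
    mag = math.hypot(rx, ry) / rt_ if rt_ > 0 else 0.0
    ang = math.degrees(math.atan2(ry, rx)) % 360 if rt_ > 0 else float("nan")
    return mag, ang


class TestRoiTrialPeaks:
    def test_windowed_maxima_by_hand(self):
        sched = syn.generate_stimulus_schedule(2, 1, 1.0, 2, 2,
                                               order="sequential")
        T = sched.n_frames_min + 2
        movie = np.full((T, 2, 2), 100.0)
        s0, s180 = sched.sweeps_for(0.0)[0], sched.sweeps_for(180.0)[0]
        movie[s0.onset_frame, 0, 0] = 180.0
        movie[s180.onset_frame, 0, 0] = 140.0
        dff = imaging.compute_dff(movie, sched)
        roi = ROI("r", np.array([[True, False], [False, False]]))
        table = rt.roi_trial_peaks(dff, roi)
        assert table.peaks[0, 0] == pytest.approx(0.8)
        assert table.peaks[1, 0] == pytest.approx(0.4)

    def test_untuned_cell_yields_equal_entries(self, schedule8x3):
        cells = [syn.CellSpec((16, 16), 3, 1.0, 0.0, 0.0, "ON")]
        movie, _ = syn.generate_calcium_movie(schedule8x3, (32, 32), cells,
                                              noise_sd=0.0, seed=0)
        dff = imaging.compute_dff(movie, schedule8x3,
                                  baseline_guard_frames=6)
        mask = np.zeros((32, 32), dtype=bool)
        mask[15:18, 15:18] = True
        table = rt.roi_trial_peaks(dff, ROI("r", mask))
        assert np.allclose(table.peaks, table.peaks[0, 0], atol=1e-9)

    def test_tuned_cell_argmax_matches_manifest(self, schedule8x3):
        cells = [syn.CellSpec((16, 16), 3, 1.0, 4.0, 135.0, "ON")]
        movie, man = syn.generate_calcium_movie(schedule8x3, (32, 32),
                                                cells, noise_sd=0.0, seed=0)
        dff = imaging.compute_dff(movie, schedule8x3)
        mask = np.zeros((32, 32), dtype=bool)
        mask[16, 16] = True
        table = rt.roi_trial_peaks(dff, ROI("r", mask))
        best = table.directions_deg[np.argmax(table.trial_mean)]
        assert best == man.cell_records[0].preferred_direction_deg

    def test_fully_invalid_roi_rejected(self, schedule8x3):
        movie = np.full((schedule8x3.n_frames_min + 2, 4, 4), 100.0)
        movie[:, 0, 0] = 0.0
        dff = imaging.compute_dff(movie, schedule8x3)
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = True
        with pytest.raises(ValueError):
            rt.roi_trial_peaks(dff, ROI("r", mask))


class TestRoiTuning:
    def test_single_direction_responder(self, directions8):
        table = rt.TrialPeakTable(
            np.array([[1.0]] * 1 + [[0.0]] * 7), directions8)
        tuning = rt.roi_tuning(table)
        assert tuning.vector_sum_magnitude == pytest.approx(1.0)
        assert tuning.preferred_angle_deg == pytest.approx(0.0)
        assert tuning.dsi == pytest.approx(1.0)

    def test_flat_table_has_zero_magnitude_and_dsi(self, directions8):
        table = rt.TrialPeakTable(np.ones((8, 3)), directions8)
        tuning = rt.roi_tuning(table)
        assert tuning.vector_sum_magnitude == pytest.approx(0.0, abs=1e-12)
        assert tuning.dsi == pytest.approx(0.0, abs=1e-12)

    def test_matches_trigonometric_oracle(self, directions8):
        mean_peaks = [3, 2, 1, 0, 0, 0, 1, 2]
        table = rt.TrialPeakTable(np.array(mean_peaks, float)[:, None],
                                  directions8)
        tuning = rt.roi_tuning(table)
        mag, ang = tuning_oracle(mean_peaks, directions8)
        assert tuning.dsi == pytest.approx(1.0)     # (3-0)/(3+0)
        assert tuning.vector_sum_magnitude == pytest.approx(mag)
        assert tuning.preferred_angle_deg == pytest.approx(ang)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.01, 100.0), min_size=8, max_size=8),
           st.floats(0.1, 50.0))
    def test_dsi_and_magnitude_scale_invariant(self, peaks, scale):
        directions = 45.0 * np.arange(8)
        a = rt.roi_tuning(rt.TrialPeakTable(
            np.array(peaks)[:, None], directions))
        b = rt.roi_tuning(rt.TrialPeakTable(
            scale * np.array(peaks)[:, None], directions))
        assert a.dsi == pytest.approx(b.dsi, rel=1e-9)
        assert a.vector_sum_magnitude == pytest.approx(
            b.vector_sum_magnitude, rel=1e-9)

    def test_degenerate_all_zero_table(self, directions8):
        tuning = rt.roi_tuning(rt.TrialPeakTable(np.zeros((8, 2)),
                                                 directions8))
        assert tuning.dsi == 0.0
        assert tuning.degenerate


class TestConsistency:
    def test_all_zero_fails(self, directions8):
        table = rt.TrialPeakTable(np.zeros((8, 3)), directions8)
        assert not rt.consistency_check(table, min_peak=0.1)

    def test_robust_pref_bin_passes(self, directions8):
        peaks = np.zeros((8, 3))
        peaks[2] = [0.5, 0.6, 0.55]
        table = rt.TrialPeakTable(peaks, directions8)
        assert rt.consistency_check(table, min_peak=0.2, min_trials=3)

    def test_pass_fraction_monotone_in_threshold(self, directions8):
        rng = np.random.default_rng(8)
        tables = [rt.TrialPeakTable(
            np.abs(rng.normal(0.5, 0.3, (8, 3))), directions8, f"r{i}")
            for i in range(60)]
        fractions = []
        for thr in (0.1, 0.3, 0.5, 0.8):
            fractions.append(np.mean([
                rt.consistency_check(t, min_peak=thr) for t in tables]))
        assert all(a >= b for a, b in zip(fractions, fractions[1:]))


class TestClassifyOnOff:
    @pytest.mark.parametrize("cls,expected", [
        ("ON", "ON"), ("ON-OFF", "ON-OFF")])
    def test_noiseless_classes_by_construction(self, schedule8x3, cls,
                                               expected):
        cells = [syn.CellSpec((16, 16), 3, 1.0, 0.0, 0.0, cls)]
        movie, _ = syn.generate_calcium_movie(schedule8x3, (32, 32), cells,
                                              noise_sd=0.01, seed=1)
        dff = imaging.compute_dff(movie, schedule8x3,
                                  baseline_guard_frames=4)
        mask = np.zeros((32, 32), dtype=bool)
        mask[14:19, 14:19] = True
        assert rt.classify_on_off(dff, ROI("r", mask)) == expected

    def test_silent_roi_is_nonresponsive(self, schedule8x3):
        cells = [syn.CellSpec((16, 16), 3, 0.0, 0.0, 0.0, "none")]
        movie, _ = syn.generate_calcium_movie(schedule8x3, (32, 32), cells,
                                              noise_sd=0.01, seed=1)
        dff = imaging.compute_dff(movie, schedule8x3)
        mask = np.zeros((32, 32), dtype=bool)
        mask[14:19, 14:19] = True
        assert rt.classify_on_off(dff, ROI("r", mask)) == "nonresponsive"

    def test_overlapping_windows_rejected(self, schedule8x3):
        movie = np.full((schedule8x3.n_frames_min + 2, 8, 8), 100.0)
        dff = imaging.compute_dff(movie, schedule8x3)
        mask = np.ones((8, 8), dtype=bool)
        with pytest.raises(ValueError):
            rt.classify_on_off(dff, ROI("r", mask), onset_window_s=3.0,
                               offset_window_s=3.0)

    def test_mixed_population_class_accuracy(self, schedule8x3):
        rng = np.random.default_rng(10)
        classes = ["ON", "ON-OFF"] * 20
        cells, centers = [], []
        for i, cls in enumerate(classes):
            x = 10 + (i % 7) * 15 + rng.uniform(-1, 1)
            y = 10 + (i // 7) * 16 + rng.uniform(-1, 1)
            centers.append((x, y))
            cells.append(syn.CellSpec((x, y), 3.5, 1.0, 2.0,
                                      float(45 * (i % 8)), cls))
        movie, man = syn.generate_calcium_movie(
            schedule8x3, (112, 112), cells, noise_sd=0.05, seed=11)
        dff = imaging.compute_dff(movie, schedule8x3,
                                  baseline_guard_frames=4)
        yy, xx = np.mgrid[0:112, 0:112]
        correct = 0
        for (x, y), rec in zip(centers, man.cell_records):
            mask = (xx - x) ** 2 + (yy - y) ** 2 <= 3.5 ** 2
            got = rt.classify_on_off(dff, ROI(rec.cell_id, mask))
            correct += got == rec.response_class
        assert correct / len(cells) >= 0.95


class TestPermutationTest:
    def test_perfectly_tuned_table_dominates_permutations(self,
                                                          directions8):
        table = rt.TrialPeakTable(
            np.array([[1.0, 1, 1]] + [[0.0, 0, 0]] * 7), directions8, "p")
        actual = rt.roi_tuning(table).dsi
        perm = rt._permuted_dsi(table.peaks, directions8, 1000,
                                np.random.default_rng(0))
        assert actual >= perm.max()    # maximum statistic
        res = rt.permutation_test(table, 1000, seed=0)
        frac_below = np.mean(perm < actual)
        # percentile consistent with the mid-rank formula
        assert res.perm_rank_percentile >= 100 * frac_below - 5

    def test_fully_tied_table_is_50th_percentile(self, directions8):
        table = rt.TrialPeakTable(np.ones((8, 3)), directions8, "t")
        res = rt.permutation_test(table, 500, seed=0)
        assert res.perm_rank_percentile == 50.0
        assert res.degenerate and not res.is_significant_ds

    def test_seeded_reproducibility(self, directions8):
        rng = np.random.default_rng(0)
        table = rt.TrialPeakTable(1 + rng.normal(0, 0.3, (8, 3)),
                                  directions8, "x")
        a = rt.permutation_test(table, 500, seed=3)
        b = rt.permutation_test(table, 500, seed=3)
        assert a.perm_rank_percentile == b.perm_rank_percentile

    def test_type_i_error_near_nominal(self, directions8):
        # 500 untuned ROIs, 1,000 permutations: ~5% declared significant
        rng = np.random.default_rng(123)
        peaks = 1.0 + rng.normal(0, 0.3, size=(500, 8, 3))
        res = rt.permutation_test_batch(peaks, directions8, 1000, seed=123)
        frac_sig = np.mean([r.is_significant_ds for r in res])
        # binomial 99% CI around 0.05 with n=500 is ±0.026
        assert abs(frac_sig - 0.05) <= 0.026

    def test_null_percentiles_uniform(self, directions8):
        rng = np.random.default_rng(7)
        peaks = 1.0 + rng.normal(0, 0.3, size=(500, 8, 3))
        res = rt.permutation_test_batch(peaks, directions8, 1000, seed=7)
        pct = np.array([r.perm_rank_percentile for r in res]) / 100.0
        assert stats.kstest(pct, "uniform").pvalue > 0.01

    def test_power_monotone_in_kappa(self, directions8):
        fractions = []
        for kappa in (0.0, 1.0, 2.0, 4.0):
            rng = np.random.default_rng(99)
            w = syn.von_mises_weight(directions8, 90.0, kappa)
            # peaks are windowed maxima: noise enters through the max
            # over in-window frames, giving a positive noise floor
            floor = rng.normal(0, 0.1, (100, 8, 3, 9)).max(axis=-1)
            peaks = w[:, None] + floor
            res = rt.permutation_test_batch(peaks, directions8, 300,
                                            seed=99)
            fractions.append(np.mean([r.is_significant_ds for r in res]))
        # non-decreasing within Monte-Carlo error at n=100 per rung
        assert all(b >= a - 0.05 for a, b in zip(fractions, fractions[1:]))
        assert fractions[-1] > fractions[0] + 0.5
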