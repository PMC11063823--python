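"""Generator correctness: schedules, movies, sweep circuits, tables,
skeletons, and manifest bookkeeping."""

import numpy as np
import pytest

from dscircuit import synthetic as syn
from dscircuit.conductance import (AccessEstimate, average_and_baseline,
                                   compensate_series_resistance,
                                   extract_conductance)
from dscircuit.morphology import summary_metrics


class TestStimulusSchedule:
    def test_standard_eight_direction_three_trial_run(self):
        sched = syn.generate_stimulus_schedule(8, 3, 2.96, seed=0)
        assert len(sched.sweeps) == 24
        assert sched.directions_deg == [0, 45, 90, 135, 180, 225, 270, 315]
        # every direction exactly once per trial block
        for trial in range(3):
            block = [s.direction_deg for s in sched.sweeps
                     if s.trial_index == trial]
            assert sorted(block) == sched.directions_deg

    def test_sequential_two_direction_schedule(self):
        sched = syn.generate_stimulus_schedule(2, 1, 10.0, 3, 2,
                                               order="sequential")
        assert [s.direction_deg for s in sched.sweeps] == [0.0, 180.0]

    def test_windows_disjoint_and_gap_separated(self):
        sched = syn.generate_stimulus_schedule(8, 3, 2.96, 9, 6, seed=1)
        windows = sorted((s.onset_frame, s.offset_frame)
                         for s in sched.sweeps)
        for (a0, a1), (b0, b1) in zip(windows, windows[1:]):
            assert b0 - a1 == 6

    def test_seeded_determinism(self):
        a = syn.generate_stimulus_schedule(8, 3, 2.96, seed=5)
        b = syn.generate_stimulus_schedule(8, 3, 2.96, seed=5)
        assert [s.direction_deg for s in a.sweeps] == \
            [s.direction_deg for s in b.sweeps]

    @pytest.mark.parametrize("kwargs", [
        {"n_directions": 1}, {"n_trials": 0}, {"stim_frames": 0},
        {"order": "bogus"},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            syn.generate_stimulus_schedule(**{"n_directions": 8,
                                              "n_trials": 3, **kwargs})


class TestCalciumMovie:
    def test_flat_cell_responds_equally_in_all_directions(self, schedule8x3):
        cells = [syn.CellSpec((16, 16), 3, 1.0, 0.0, 0.0, "ON")]
        movie, _ = syn.generate_calcium_movie(schedule8x3, (32, 32), cells,
                                              noise_sd=0.0, seed=0)
        onsets = [movie[s.onset_frame, 16, 16] for s in schedule8x3.sweeps]
        assert np.allclose(onsets, onsets[0])

    def test_tuned_cell_peaks_at_preferred_direction(self, schedule8x3):
        kappa, pref = 4.0, 90.0
        cells = [syn.CellSpec((16, 16), 3, 1.0, kappa, pref, "ON")]
        movie, _ = syn.generate_calcium_movie(schedule8x3, (32, 32), cells,
                                              noise_sd=0.0, seed=0)
        # oracle: closed-form von Mises ratio across the 8 angles
        means = {}
        for s in schedule8x3.sweeps:
            resp = movie[s.onset_frame:s.offset_frame, 16, 16].max()
            means.setdefault(s.direction_deg, []).append(resp)
        baseline = 100.0
        for d, vals in means.items():
            expected = baseline * (1 + np.exp(kappa * (
                np.cos(np.deg2rad(d - pref)) - 1)))
            assert np.allclose(vals, expected, rtol=1e-12)

    def test_zero_signal_movie_is_constant_baseline(self, schedule8x3):
        cells = [syn.CellSpec((16, 16), 3, 0.0, 2.0, 0.0, "ON")]
        movie, _ = syn.generate_calcium_movie(schedule8x3, (32, 32), cells,
                                              noise_sd=0.0, seed=0)
        assert np.allclose(movie, 100.0)

    def test_indicator_kernel_matches_direct_convolution(self, schedule8x3):
        # oracle: independent convolution of the known kernel
        tau, fs = 0.6, schedule8x3.frame_rate_hz
        cells = [syn.CellSpec((16, 16), 2, 0.8, 0.0, 0.0, "ON")]
        movie, _ = syn.generate_calcium_movie(
            schedule8x3, (32, 32), cells, noise_sd=0.0,
            indicator_decay_s=tau, seed=0)
        trace = movie[:, 16, 16] / 100.0 - 1.0
        T = movie.shape[0]
        drive = np.zeros(T)
        for s in schedule8x3.sweeps:
            drive[s.onset_frame] += 0.8
        kern = np.exp(-np.arange(int(np.ceil(5 * tau * fs))) / (tau * fs))
        expected = np.convolve(drive, kern)[:T]
        assert np.allclose(trace, expected, atol=1e-12)

    def test_overlapping_cells_flagged(self, schedule8x3):
        cells = [syn.CellSpec((16, 16), 4, 1, 0, 0, "ON"),
                 syn.CellSpec((20, 16), 4, 1, 0, 0, "ON"),
                 syn.CellSpec((28, 28), 2, 1, 0, 0, "ON")]
        _, man = syn.generate_calcium_movie(schedule8x3, (32, 32), cells,
                                            seed=0)
        assert [r.overlapping for r in man.cell_records] == \
            [True, True, False]

    def test_seeded_determinism(self, schedule8x3):
        cells = [syn.CellSpec((16, 16), 3, 1.0, 2.0, 45.0, "ON-OFF")]
        a, _ = syn.generate_calcium_movie(schedule8x3, (32, 32), cells,
                                          noise_sd=0.1, seed=9)
        b, _ = syn.generate_calcium_movie(schedule8x3, (32, 32), cells,
                                          noise_sd=0.1, seed=9)
        assert np.array_equal(a, b)

    def test_cell_outside_field_rejected(self, schedule8x3):
        with pytest.raises(ValueError):
            syn.generate_calcium_movie(
                schedule8x3, (32, 32),
                [syn.CellSpec((40, 16), 3, 1, 0, 0, "ON")])


class TestVClampSweeps:
    def test_rs_zero_current_is_exactly_ohmic(self):
        ss, _ = syn.generate_vclamp_sweeps(
            g_peak_nS=1.0, e_rev_mV=-60.0, holding_potentials_mV=(-100, 20),
            rs_MOhm=0.0, rin_MOhm=500.0, leak_rev_mV=-60.0, noise_sd_pA=0.0,
            seed=0)
        averaged = average_and_baseline(ss)
        fs = ss.sampling_rate_hz
        t = ss.time_s
        s = t - ss.stim_onset_s
        g_nS = np.where(s > 0, 1.0 * (s / 0.01) * np.exp(1 - s / 0.01), 0.0)
        sl = slice(0, int(0.4 * fs))   # before the test pulse
        for vh in (-100.0, 20.0):
            expected = g_nS[sl] * (vh - (-60.0))
            assert np.allclose(averaged.sweeps[vh][0][sl], expected,
                               atol=1e-9)

    def test_series_resistance_attenuates_per_divider(self):
        # oracle: algebraic two-resistor divider solution
        kw = dict(g_peak_nS=2.0, e_rev_mV=-60.0, leak_rev_mV=-70.0,
                  holding_potentials_mV=(-100.0,), noise_sd_pA=0.0, seed=0)
        with pytest.raises(ValueError):
            # single holding potential is not a usable sweep set
            syn.generate_vclamp_sweeps(rs_MOhm=0.0, rin_MOhm=500.0, **kw)
        kw["holding_potentials_mV"] = (-100.0, 20.0)
        ss0, _ = syn.generate_vclamp_sweeps(rs_MOhm=0.0, rin_MOhm=500.0,
                                            **kw)
        ss10, _ = syn.generate_vclamp_sweeps(rs_MOhm=10.0, rin_MOhm=500.0,
                                             **kw)
        fs = ss0.sampling_rate_hz
        i_peak = int((ss0.stim_onset_s + 0.01) * fs)   # alpha peak sample
        vh = -100.0
        tr0 = average_and_baseline(ss0).sweeps[vh][0]
        tr10 = average_and_baseline(ss10).sweeps[vh][0]
        g_uS = 2.0e-3
        num0 = (vh + 70.0) / 500.0 + g_uS * (vh + 60.0)
        den10 = 1.0 + 10.0 * (1.0 / 500.0 + g_uS)
        base0 = (vh + 70.0) / 500.0
        base10 = base0 / (1.0 + 10.0 / 500.0)
        expected0 = 1e3 * (num0 - base0)
        expected10 = 1e3 * (num0 / den10 - base10)
        assert tr0[i_peak] == pytest.approx(expected0, rel=1e-9)
        assert tr10[i_peak] == pytest.approx(expected10, rel=1e-9)
        assert abs(tr10[i_peak]) < abs(tr0[i_peak])

    def test_no_synapse_gives_flat_baseline_subtracted_iv(self):
        ss, _ = syn.generate_vclamp_sweeps(g_peak_nS=0.0, noise_sd_pA=0.0,
                                           seed=0)
        averaged = average_and_baseline(ss)
        for vh in averaged.holding_potentials:
            pre_pulse = averaged.sweeps[vh][0][:int(
                0.4 * ss.sampling_rate_hz)]
            assert np.allclose(pre_pulse, 0.0, atol=1e-9)

    def test_divergent_divider_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_vclamp_sweeps(g_peak_nS=2000.0, rs_MOhm=10.0,
                                       rin_MOhm=1.0)

    def test_round_trip_recovers_truth_within_one_percent(self):
        ss, man = syn.generate_vclamp_sweeps(noise_sd_pA=0.0, seed=2)
        rec = man.ephys_records[0]
        trace = extract_conductance(
            ss, access=AccessEstimate(rec.rs_MOhm, rec.rin_MOhm))
        assert trace.peak_gT_nS == pytest.approx(rec.peak_conductance_nS,
                                                 rel=0.01)
        assert trace.vrev_at_peak_mV == pytest.approx(rec.reversal_mV,
                                                      abs=0.6)


class TestTuningTable:
    def test_cs_index_truth_forced_by_construction(self):
        from dscircuit.ephys import compute_tuning_indices

        for s in (0.0, 0.4, 1.0):
            responses, man = syn.generate_tuning_table(
                surround_suppression=s, noise_sd_pA=0.0, seed=0)
            idx = compute_tuning_indices(responses)
            assert idx.cs_index_on == pytest.approx(s, abs=1e-12)
            assert man.cell_records[0].true_cs_index == s

    def test_flat_tuning_gives_zero_dsi(self):
        from dscircuit.ephys import compute_tuning_indices

        responses, _ = syn.generate_tuning_table(kappa=0.0, noise_sd_pA=0.0,
                                                 seed=0)
        assert compute_tuning_indices(responses).dsi == pytest.approx(0.0,
                                                                      abs=1e-9)

    def test_preferred_direction_recovered_within_one_bin(self):
        from dscircuit.ephys import compute_tuning_indices

        responses, _ = syn.generate_tuning_table(pref_deg=225.0, kappa=3.0,
                                                 noise_sd_pA=0.0, seed=0)
        idx = compute_tuning_indices(responses)
        assert abs((idx.preferred_deg - 225.0 + 180) % 360 - 180) <= 22.5

    def test_empty_condition_lists_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_tuning_table(spot_diameters_um=(440.0,))


class TestSkeletonGenerator:
    def test_centered_arbor_has_near_zero_asymmetry(self):
        _, man = syn.generate_skeleton(soma_offset_um=0.0, seed=3)
        assert man.morph_records[0].true_ai < 0.1

    def test_seeded_determinism(self):
        a, _ = syn.generate_skeleton(seed=4)
        b, _ = syn.generate_skeleton(seed=4)
        assert np.array_equal(a.xyz, b.xyz)
        assert np.array_equal(a.parent, b.parent)

    def test_manifest_counts_match_measured_morphometry(self):
        skel, man = syn.generate_skeleton(n_branches=5, soma_offset_um=20,
                                          seed=5)
        rec = man.morph_records[0]
        metrics = summary_metrics(skel)
        assert metrics.n_tips == rec.n_tips
        assert metrics.n_branch_points == rec.n_branch_points
        assert metrics.total_length_um == pytest.approx(rec.total_length_um)

    def test_monostratified_profiles_set_depth(self):
        on, _ = syn.generate_skeleton(depth_profile="monostratified_on",
                                      seed=6)
        off, _ = syn.generate_skeleton(depth_profile="monostratified_off",
                                       seed=6)
        assert np.all(on.depth_norm[1:] > 0.5)
        assert np.all(off.depth_norm[1:] < 0.5)

    def test_offset_bounds_enforced(self):
        with pytest.raises(ValueError):
            syn.generate_skeleton(soma_offset_um=100.0,
                                  field_radius_um=100.0)


class TestManifest:
    def test_duplicate_ids_rejected(self):
        rec = syn.CellRecord("a", (0, 0), True, 0.0, 1.0, "ON")
        with pytest.raises(ValueError):
            syn.GroundTruthManifest(seed=0, cell_records=[rec, rec])

    def test_json_round_trip(self, tmp_path):
        _, man = syn.generate_skeleton(seed=1)
        _, man2 = syn.generate_tuning_table(seed=2)
        man.cell_records = man2.cell_records
        path = tmp_path / "manifest.json"
        man.to_json(path)
        back = syn.GroundTruthManifest.from_json(path)
        assert back.morph_records == man.morph_records

    def test_every_movie_cell_has_exactly_one_record(self, schedule8x3):
        cells = [syn.CellSpec((8 + 4 * i, 16), 1.5, 1, 0, 0, "ON")
                 for i in range(5)]
        _, man = syn.generate_calcium_movie(schedule8x3, (32, 32), cells,
                                            seed=0)
        assert len(man.cell_records) == 5
        assert len({r.cell_id for r in man.cell_records}) == 5
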