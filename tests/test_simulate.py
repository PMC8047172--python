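"""Synthetic flight generator: trajectories, schedules, chirps, rendering."""

import numpy as np
import pandas as pd
import pytest
from scipy.signal import correlate, hilbert

from batgaze.beam import BeamModel
from batgaze.geometry import Condition, Trajectory, default_room, distance_to_turn
from batgaze.propagation import Environment
from batgaze.simulate import (ChirpParams, GazeModel, SpeedProfile, TimingModel,
                              default_speed_profile, generate_trajectory,
                              render_mics, schedule_calls, simulate_flight,
                              synthesize_chirp)
from batgaze.timing import classify_ssgs, compute_ipis


def fd_speeds(traj):
    """Independent finite-difference speed oracle on the output positions."""
    d = np.hypot(*np.diff(traj.xy_m, axis=0).T)
    return d / np.diff(traj.t_s)


class TestTrajectory:
    def test_constant_speed_straight(self, room_straight):
        traj = generate_trajectory(room_straight, SpeedProfile(2.5, 2.5, 0.0), seed=0)
        assert traj.path_length_m() / traj.duration_s == pytest.approx(2.5, abs=1e-6)

    def test_near_segment_median_speed(self, room_right):
        traj = generate_trajectory(room_right, SpeedProfile(2.3, 1.9, 0.05), seed=3)
        d = np.array([distance_to_turn(p, room_right).distance_to_turn_cm
                      for p in traj.xy_m[:-1]])
        v = fd_speeds(traj)
        near = v[(d >= 0) & (d < 100)]
        assert np.median(near) == pytest.approx(1.9, rel=0.05)

    def test_default_turn_profile_targets_study_far_speeds(self, room_right):
        profile = default_speed_profile(Condition.RIGHT_TURN)
        assert 2.2 <= profile.far_speed_mps <= 2.4
        traj = generate_trajectory(room_right, profile, seed=5)
        d = np.array([distance_to_turn(p, room_right).distance_to_turn_cm
                      for p in traj.xy_m[:-1]])
        far = fd_speeds(traj)[(d >= 100) & (d < 250)]
        assert 2.1 <= np.median(far) <= 2.5

    def test_lateral_jitter_bounded(self, room_right):
        traj = generate_trajectory(room_right, SpeedProfile(2.3, 1.9, 0.05), seed=9)
        lat = [distance_to_turn(p, room_right).lateral_offset_cm
               for p in traj.xy_m]
        assert np.max(np.abs(lat)) < 20.0     # inside the corridor half-width

    def test_bad_inputs(self, room_right):
        with pytest.raises(ValueError):
            SpeedProfile(-1.0, 2.0)
        with pytest.raises(ValueError):
            generate_trajectory(room_right, SpeedProfile(2, 2, 0), dt_s=0.01)


class TestSchedule:
    def _traj(self, duration=3.0):
        return Trajectory(t_s=np.array([0.0, duration]),
                          xy_m=np.array([[1.0, 2.4], [4.0, 2.4]]))

    def test_all_singles_classified_as_singletons(self):
        tm = TimingModel(single_fraction=1.0, doublet_fraction=0.0,
                         triplet_fraction=0.0, noise_sd_ms=0.0)
        calls = schedule_calls(self._traj(), tm, seed=0)
        labels = classify_ssgs(compute_ipis(calls["emission_time_s"].to_numpy()))
        assert all(l.group_size == 1 for l in labels)

    def test_constant_ipi_call_count(self):
        tm = TimingModel(single_fraction=1.0, doublet_fraction=0.0,
                         triplet_fraction=0.0, base_ipi_ms=30.0, noise_sd_ms=0.0)
        calls = schedule_calls(self._traj(3.0), tm, seed=0)
        assert len(calls) in (100, 101)

    def test_pure_doublets_roundtrip_classifier(self):
        tm = TimingModel(single_fraction=0.0, doublet_fraction=1.0,
                         triplet_fraction=0.0, within_group_ipi_ms=25.0,
                         between_group_ipi_ms=70.0, noise_sd_ms=0.0)
        calls = schedule_calls(self._traj(600.0), tm, seed=7)
        assert len(calls) > 10_000
        labels = classify_ssgs(compute_ipis(calls["emission_time_s"].to_numpy()))
        sizes = np.array([l.group_size for l in labels])
        # every call classified into a doublet (edges may truncate one group)
        frac = sum(s for s in sizes if s == 2) / sizes.sum()
        assert frac == pytest.approx(1.0, abs=1e-3)

    def test_times_strictly_increasing_and_truth_consistent(self, room_right):
        tm = TimingModel()
        traj = generate_trajectory(room_right, SpeedProfile(2.3, 1.9, 0.05), seed=1)
        calls = schedule_calls(traj, tm, seed=1, room=room_right, gaze=GazeModel())
        t = calls["emission_time_s"].to_numpy()
        assert np.all(np.diff(t) > 0)
        assert np.all(np.isfinite(calls["beam_aim_deg"]))
        # group sizes partition the sequence
        assert calls.groupby("ssg_group_id")["ssg_size"].first().sum() == len(calls)

    def test_group_size_frequencies_converge(self):
        tm = TimingModel(noise_sd_ms=0.0)
        calls = schedule_calls(self._traj(400.0), tm, seed=11)
        realized = calls.drop_duplicates("ssg_group_id")["ssg_size"].value_counts(normalize=True)
        expected = tm.group_size_probs()
        n_groups = calls["ssg_group_id"].nunique()
        for size in (1, 2, 3):
            p = expected[size - 1]
            se = np.sqrt(p * (1 - p) / n_groups)
            assert abs(realized.get(size, 0.0) - p) < 3 * se + 1e-9

    def test_invalid_timing_rejected(self):
        with pytest.raises(ValueError):
            TimingModel(within_group_ipi_ms=60.0, between_group_ipi_ms=45.0)
        empty = Trajectory(t_s=np.array([]), xy_m=np.zeros((0, 2)))
        with pytest.raises(ValueError):
            schedule_calls(empty, TimingModel())


class TestChirp:
    def test_length(self):
        y = synthesize_chirp(ChirpParams(duration_ms=3.0), fs_hz=250_000)
        assert len(y) == 750

    @pytest.mark.parametrize("sweep", ["linear_frequency", "linear_period"])
    def test_start_frequency_by_phase_oracle(self, sweep):
        fs = 250_000
        p = ChirpParams(sweep=sweep, taper=0.1)
        y = synthesize_chirp(p, fs)
        phase = np.unwrap(np.angle(hilbert(y)))
        inst = np.gradient(phase) * fs / (2 * np.pi)
        # extrapolate back to t = 0 on the scale where the sweep is linear
        # (frequency for linear-frequency, period for linear-period)
        k = np.arange(40, 140)
        if sweep == "linear_frequency":
            icpt = np.polyfit(k, inst[k], 1)[1]
        else:
            icpt = 1.0 / np.polyfit(k, 1.0 / inst[k], 1)[1]
        assert icpt == pytest.approx(p.f_start_hz, rel=0.02)

    def test_energy_scales_with_source_level(self):
        a = synthesize_chirp(ChirpParams(source_level_db=0.0), 250_000)
        b = synthesize_chirp(ChirpParams(source_level_db=6.0206), 250_000)
        ratio = 10 * np.log10(np.sum(b ** 2) / np.sum(a ** 2))
        assert ratio == pytest.approx(6.0206, abs=1e-6)

    def test_nyquist_guard(self):
        with pytest.raises(ValueError):
            synthesize_chirp(ChirpParams(f_start_hz=55_000), fs_hz=100_000)


class TestRender:
    def _one_call(self, x=2.0, y=2.4, aim=0.0):
        return pd.DataFrame({"call_index": [0], "emission_time_s": [0.01],
                             "x_m": [x], "y_m": [y], "beam_aim_deg": [aim]})

    def test_inverse_square_level_difference(self, room_straight):
        """Two on-axis mics at 1 m and 2 m, absorption off: 6.02 dB apart."""
        from batgaze.geometry import MicArray

        mics = MicArray(np.array([[3.0, 2.4, 1.2], [4.0, 2.4, 1.2],
                                  [2.0, 1.0, 1.2], [2.0, 3.8, 1.2]]),
                        np.arange(1, 5), 250_000.0)
        env = Environment(noise_db=-150.0, absorption_scale=0.0)
        wave = render_mics(self._one_call(), ChirpParams(), BeamModel.calibrated(),
                           mics, env, room_straight, seed=0)
        lvl = 10 * np.log10(np.sum(wave ** 2, axis=1))
        assert lvl[0] - lvl[1] == pytest.approx(6.0206, abs=0.05)

    def test_first_arrival_delay(self, room_straight, mics):
        env = Environment(noise_db=-150.0)
        chirp = ChirpParams()
        wave = render_mics(self._one_call(), chirp, BeamModel.calibrated(),
                           mics, env, room_straight, seed=0)
        proto = synthesize_chirp(chirp, mics.sample_rate_hz)
        src = np.array([2.0, 2.4, 1.2])
        for i in (0, 5, 10):
            r = np.linalg.norm(mics.mic_positions[i] - src)
            cc = correlate(wave[i], proto, mode="valid")
            onset = np.argmax(np.abs(cc)) / mics.sample_rate_hz
            expect = 0.01 + r / env.c_mps
            assert onset == pytest.approx(expect, abs=1.0 / mics.sample_rate_hz)

    def test_call_on_microphone_rejected(self, room_straight, mics):
        call = self._one_call(*mics.mic_positions[0][:2])
        with pytest.raises(ValueError, match="microphone"):
            render_mics(call, ChirpParams(), BeamModel.calibrated(), mics,
                        Environment(), room_straight, seed=0,
                        flight_height_m=float(mics.mic_positions[0][2]))

    def test_seeded_determinism(self, room_right, mics):
        w1, t1 = simulate_flight(room_right, mics, seed=99)
        w2, t2 = simulate_flight(room_right, mics, seed=99)
        np.testing.assert_array_equal(w1, w2)
        pd.testing.assert_frame_equal(t1.calls, t2.calls)

    def test_clutter_adds_energy(self, mics):
        room = default_room(Condition.RIGHT_TURN, with_chains=True)
        env = Environment(noise_db=-150.0)
        call = self._one_call()
        base = render_mics(call, ChirpParams(), BeamModel.calibrated(), mics,
                           env, room, seed=0)
        ech = render_mics(call, ChirpParams(), BeamModel.calibrated(), mics,
                          env, room, seed=0, clutter_reflection_db=15.0)
        assert np.sum(ech ** 2) > np.sum(base ** 2)


def test_ground_truth_log_roundtrip(tmp_path, rt_flight):
    _, truth = rt_flight
    truth.save(tmp_path / "truth.csv")
    back = pd.read_csv(tmp_path / "truth.csv")
    assert len(back) == truth.n_calls
    import json

    sidecar = json.loads((tmp_path / "truth.json").read_text())
    assert sidecar["trial"]["condition"] == "RIGHT_TURN"
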