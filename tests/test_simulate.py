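import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hallgait.config import max_beat_range, range_bin_spacing
from hallgait.simulate import (BeamPattern, HallwayClutter, WalkScenario,
                               beam_gain, ghost_scatterers, limb_scatterers,
                               simulate_walk, synthesize_cube,
                               torso_scatterer, torso_trajectory)

from conftest import make_static_scatterer


class TestScenario:
    def test_step_count_truth_default(self):
        truth = torso_trajectory(WalkScenario()).truth
        assert truth.true_step_count == 36
        assert len(truth.true_step_times) == 36

    def test_step_count_one_round_trip(self):
        truth = torso_trajectory(WalkScenario(n_round_trips=1)).truth
        assert truth.true_step_count == 12

    def test_pass_duration(self):
        scn = WalkScenario(avg_speed=0.87)
        a, b = torso_trajectory(scn).truth.pass_intervals[0]
        assert b - a == pytest.approx(4.2 / 0.87, rel=1e-9)
        assert b - a == pytest.approx(4.83, abs=0.01)

    @pytest.mark.parametrize("kwargs", [
        {"path_length": 4.0},            # not a multiple of 0.7
        {"avg_speed": 0.0},
        {"speed_modulation_depth": 1.0},
        {"start_range": -0.5},
        {"walk_azimuth": 120.0},
    ])
    def test_invalid_scenarios(self, kwargs):
        with pytest.raises(ValueError):
            WalkScenario(**kwargs)


class TestTrajectory:
    def test_truth_step_points_spacing(self):
        truth = torso_trajectory(WalkScenario()).truth
        for pid in range(6):
            pts = truth.true_step_points[truth.true_pass_ids == pid]
            np.testing.assert_allclose(np.abs(np.diff(pts)), 0.7, rtol=1e-9)

    def test_range_is_integral_of_velocity(self):
        traj = torso_trajectory(WalkScenario())
        dt = np.diff(traj.times)
        rebuilt = traj.range_m[0] + np.concatenate(
            [[0.0], np.cumsum(0.5 * (traj.velocity[1:] + traj.velocity[:-1])
                              * dt)])
        np.testing.assert_allclose(rebuilt, traj.range_m, atol=1e-9)

    def test_one_velocity_peak_per_step(self):
        import scipy.signal
        traj = torso_trajectory(WalkScenario())
        a, b = traj.truth.pass_intervals[0]
        sel = (traj.times >= a) & (traj.times < b)
        peaks, _ = scipy.signal.find_peaks(np.abs(traj.velocity[sel]))
        assert len(peaks) == 6

    def test_zero_modulation_is_constant_speed(self):
        traj = torso_trajectory(WalkScenario(speed_modulation_depth=0.0))
        a, b = traj.truth.pass_intervals[0]
        sel = (traj.times >= a) & (traj.times < b)
        assert np.ptp(np.abs(traj.velocity[sel])) < 1e-9

    def test_truth_avg_speed_formula(self):
        scn = WalkScenario()
        traj = torso_trajectory(scn)
        d_ramp = scn.avg_speed * (1 - scn.speed_modulation_depth) \
            * scn.turn_ramp_time / 2
        n_p = scn.n_passes
        dist = n_p * scn.path_length + (2 * (n_p - 1) + 1) * d_ramp
        walk_end = (n_p * scn.pass_duration
                    + (n_p - 1) * (2 * scn.turn_ramp_time + scn.turn_duration)
                    + scn.turn_ramp_time)
        assert traj.truth.true_avg_speed == pytest.approx(dist / walk_end)

    def test_turns_separate_passes(self):
        truth = torso_trajectory(WalkScenario()).truth
        assert len(truth.turn_intervals) == 5
        for (a0, b0), (a1, _) in zip(truth.pass_intervals,
                                     truth.pass_intervals[1:]):
            assert b0 < a1

    def test_range_positive_everywhere(self):
        traj = torso_trajectory(WalkScenario())
        assert np.all(traj.range_m > 0)


class TestGhosts:
    def test_mirror_image_oracle(self):
        # explicit image-point construction for a static torso
        torso = make_static_scatterer(3.0, 0.0, label="torso")
        clutter = HallwayClutter(wall_offsets=(1.0,), wall_sides=(1,),
                                 wall_reflection_loss_db=6.0)
        ghost = ghost_scatterers(torso, clutter)[0]
        # subject at (3, 0); wall y=+1; image at (3, 2)
        image_dist = math.hypot(3.0, 2.0)
        expected_range = 0.5 * (3.0 + image_dist)
        expected_az = math.degrees(math.atan2(2.0, 3.0))
        assert float(ghost.range_trajectory(0.0)) == pytest.approx(
            expected_range)
        assert float(ghost.azimuth_trajectory(0.0)) == pytest.approx(
            expected_az)
        assert ghost.amplitude == pytest.approx(10 ** (-6.0 / 20))
        assert ghost.label == "ghost"

    def test_ghost_range_never_below_direct(self):
        traj = torso_trajectory(WalkScenario())
        torso = torso_scatterer(traj)
        clutter = HallwayClutter(wall_offsets=(0.8, 1.5),
                                 wall_sides=(1, -1))
        t = np.linspace(0, traj.duration, 500)
        direct = torso.range_trajectory(t)
        for ghost in ghost_scatterers(torso, clutter)[:2]:
            assert np.all(ghost.range_trajectory(t) >= direct - 1e-12)

    def test_no_walls_no_ghosts(self):
        torso = make_static_scatterer(3.0, label="torso")
        clutter = HallwayClutter(wall_offsets=(), wall_sides=())
        assert ghost_scatterers(torso, clutter) == []

    def test_static_reflectors_passed_through(self):
        torso = make_static_scatterer(3.0, label="torso")
        clutter = HallwayClutter(wall_offsets=(), wall_sides=(),
                                 static_reflectors=[(2.5, 15.0, 0.4)])
        out = ghost_scatterers(torso, clutter)
        assert len(out) == 1
        assert out[0].label == "static"
        assert float(out[0].range_trajectory(1.0)) == 2.5
        assert out[0].amplitude == 0.4


class TestBeam:
    def test_boresight_maximal(self):
        beam = BeamPattern.lens()
        assert beam_gain(beam, 0.0) >= beam_gain(beam, 5.0)

    def test_half_power_at_hpbw(self):
        beam = BeamPattern.no_lens()
        ratio = beam_gain(beam, beam.half_power_beamwidth / 2) \
            / beam_gain(beam, 0.0)
        assert ratio == pytest.approx(0.5, rel=1e-9)

    def test_lens_gain_improvement(self):
        g_lens = beam_gain(BeamPattern.lens(), 0.0)
        g_bare = beam_gain(BeamPattern.no_lens(), 0.0)
        assert 10 * math.log10(g_lens / g_bare) >= 14.0

    def test_azimuth_limit(self):
        with pytest.raises(ValueError):
            beam_gain(BeamPattern.lens(), 91.0)

    @settings(max_examples=25, deadline=None)
    @given(a=st.floats(min_value=0.0, max_value=89.0),
           delta=st.floats(min_value=0.0, max_value=1.0))
    def test_monotone_nonincreasing(self, a, delta):
        beam = BeamPattern.no_lens()
        assert beam_gain(beam, a + delta) <= beam_gain(beam, a) + 1e-15


class TestSynthesis:
    def test_bin_centre_static_scatterer(self, cfg):
        # target placed exactly on bin 30 of the 64-point grid
        r = 30 * range_bin_spacing(cfg, 64)
        sc = make_static_scatterer(r, label="torso")
        cube = synthesize_cube([sc], cfg, BeamPattern.lens(), None,
                               duration=cfg.frame_period, rng_seed=0)
        spectrum = np.abs(np.fft.fft(cube.data[0, 0]))
        assert int(np.argmax(spectrum)) == 30

    def test_matches_brute_force_dft(self, small_cfg):
        sc = make_static_scatterer(2.0, label="torso")
        cube = synthesize_cube([sc], small_cfg, BeamPattern.lens(), None,
                               duration=small_cfg.frame_period, rng_seed=0)
        x = cube.data[0, 0].astype(np.complex128)
        n = len(x)
        k = np.arange(n)
        dft = np.array([np.sum(x * np.exp(-2j * np.pi * kk * k / n))
                        for kk in range(n)])
        np.testing.assert_allclose(np.fft.fft(x), dft, rtol=1e-6, atol=1e-8)

    def test_beat_frequency_below_nyquist(self, cfg):
        # 4.2 m -> 1.68 MHz < 2.2 MHz complex sampling
        f_beat = 2 * cfg.slope * 4.2 / 299792458.0
        assert f_beat == pytest.approx(1.681e6, rel=1e-3)
        assert f_beat < cfg.adc_sample_rate
        assert 4.2 < max_beat_range(cfg)

    def test_deterministic_given_seed(self, cfg):
        sc = make_static_scatterer(2.0, label="torso")
        mk = lambda seed: synthesize_cube(
            [sc], cfg, BeamPattern.lens(), 20.0,
            duration=2 * cfg.frame_period, rng_seed=seed)
        assert np.array_equal(mk(5).data, mk(5).data)
        assert not np.array_equal(mk(5).data, mk(6).data)

    def test_out_of_range_scatterer_named(self, cfg):
        sc = make_static_scatterer(6.0, label="far_wall")
        with pytest.raises(ValueError, match="far_wall"):
            synthesize_cube([sc], cfg, BeamPattern.lens(), None,
                            duration=cfg.frame_period, rng_seed=0)

    def test_empty_scatterers_rejected(self, cfg):
        with pytest.raises(ValueError):
            synthesize_cube([], cfg, BeamPattern.lens(), None,
                            duration=cfg.frame_period, rng_seed=0)

    def test_sub_frame_duration_rejected(self, cfg):
        sc = make_static_scatterer(2.0)
        with pytest.raises(ValueError):
            synthesize_cube([sc], cfg, BeamPattern.lens(), None,
                            duration=0.01, rng_seed=0)

    def test_power_scales_with_gain_squared_over_r4(self, small_cfg):
        # radar-equation proportionality: power ~ beam_gain^2 * R^-4
        beam = BeamPattern.no_lens()

        def power(r, az):
            sc = make_static_scatterer(r, az, label="torso")
            cube = synthesize_cube([sc], small_cfg, beam, None,
                                   duration=small_cfg.frame_period,
                                   rng_seed=0)
            return float(np.mean(np.abs(cube.data) ** 2))

        assert power(1.0, 0.0) / power(2.0, 0.0) == pytest.approx(
            16.0, rel=1e-6)
        hp = beam.half_power_beamwidth / 2
        assert power(1.0, 0.0) / power(1.0, hp) == pytest.approx(
            4.0, rel=1e-6)


class TestLimbs:
    def test_limb_amplitude_below_torso(self):
        traj = torso_trajectory(WalkScenario())
        torso = torso_scatterer(traj)
        for limb in limb_scatterers(traj):
            assert limb.amplitude < torso.amplitude

    def test_limb_peak_speed_exceeds_torso(self):
        traj = torso_trajectory(WalkScenario())
        limb = limb_scatterers(traj)[0]
        t = np.linspace(0.5, traj.duration - 0.5, 4000)
        dt = t[1] - t[0]
        v_limb = np.abs(np.diff(limb.range_trajectory(t))) / dt
        assert v_limb.max() > np.abs(traj.velocity).max() * 1.2

    def test_disabled_by_default(self):
        scn = WalkScenario(n_round_trips=1, rng_seed=3)
        with_limbs = simulate_walk(scn, include_limbs=True)
        without = simulate_walk(scn, include_limbs=False)
        labels = [s.label for s in with_limbs.scatterers]
        assert "limb" in labels
        assert "limb" not in [s.label for s in without.scatterers]
        assert not np.array_equal(with_limbs.cube.data, without.cube.data)
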