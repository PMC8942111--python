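"""Synthetic lung-sound generator: envelope truth, channel model, bookkeeping."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import breathsnr as bs
from breathsnr.errors import InvalidConfigurationError
from breathsnr.spectral import bandpass
from breathsnr.synth import ChannelModel, _banded_power


def _interval_power(x, intervals):
    mask = np.zeros(x.size, bool)
    for s, e in intervals:
        mask[s:e] = True
    return float(np.mean(x[mask] ** 2)), mask


class TestBreathSource:
    def test_breath_count_matches_program(self, tiny_program, rate):
        # 10 s at 15 breaths/min = 2.5 breaths -> 2 or 3 active windows
        _, active, _ = bs.simulate_breath_source(tiny_program, rate=rate, seed=3)
        assert 2 <= len(active) <= 3

    def test_active_power_exceeds_quiet_by_10db(self, tiny_program, rate):
        x, active, _ = bs.simulate_breath_source(tiny_program, rate=rate, seed=3)
        p_active, mask = _interval_power(x, active)
        p_quiet = float(np.mean(x[~mask] ** 2))
        assert 10 * np.log10(p_active / max(p_quiet, 1e-300)) >= 10.0

    def test_zero_depth_gain_makes_depths_indistinguishable(self, rate):
        prog = bs.BreathProgram(depth_sequence=(("normal", 12.0), ("deep", 12.0)),
                                depth_gain_db=0.0)
        x, active, depths = bs.simulate_breath_source(prog, rate=rate, seed=5)
        p = {d: _interval_power(x, [iv])[0]
             for iv, d in zip(active, depths)}
        by_depth = {d: np.mean([_interval_power(x, [iv])[0]
                                for iv, dd in zip(active, depths) if dd == d])
                    for d in ("normal", "deep")}
        ratio_db = 10 * np.log10(by_depth["deep"] / by_depth["normal"])
        assert abs(ratio_db) < 1.0

    def test_deep_blocks_boosted_by_depth_gain(self, short_program, rate):
        x, active, depths = bs.simulate_breath_source(short_program, rate=rate,
                                                      seed=5)
        p_norm = np.mean([_interval_power(x, [iv])[0]
                          for iv, d in zip(active, depths) if d == "normal"])
        p_deep = np.mean([_interval_power(x, [iv])[0]
                          for iv, d in zip(active, depths) if d == "deep"])
        # 6 dB amplitude gain -> factor 10**(6/20) -> 6 dB power ratio
        assert 10 * np.log10(p_deep / p_norm) == pytest.approx(6.0, abs=2.0)

    def test_band_outside_nyquist_rejected(self, tiny_program):
        with pytest.raises(InvalidConfigurationError):
            bs.simulate_breath_source(tiny_program, band=(100, 2500), rate=4000)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(InvalidConfigurationError):
            bs.BreathProgram(depth_sequence=(("normal", 0.0),))

    def test_inspiration_fraction_bounds(self):
        with pytest.raises(InvalidConfigurationError):
            bs.BreathProgram(inspiration_fraction=1.0)


class TestApplyChannel:
    def test_identity_channel(self, tiny_program, rate):
        x, active, _ = bs.simulate_breath_source(tiny_program, rate=rate, seed=1)
        model = ChannelModel(taps_left=((1.0, 0.0),), fabric_attenuation_db=0.0,
                             ambient_noise_power=0.0, turbulence_noise_power=0.0)
        y = bs.apply_channel(x, model, "left", active, rate=rate, seed=0)
        np.testing.assert_allclose(y, x)

    def test_pure_scaling(self, tiny_program, rate):
        x, active, _ = bs.simulate_breath_source(tiny_program, rate=rate, seed=1)
        model = ChannelModel(taps_left=((0.5, 0.0),), ambient_noise_power=0.0)
        y = bs.apply_channel(x, model, "left", active, rate=rate, seed=0)
        np.testing.assert_allclose(y, 0.5 * x)

    def test_impulse_through_two_taps(self):
        # brute-force discrete convolution oracle: taps (1, 0 s), (0.5, 10 ms)
        # at 1000 Hz put mass exactly at indices 0 and 10
        imp = np.zeros(100)
        imp[0] = 1.0
        model = ChannelModel(taps_left=((1.0, 0.0), (0.5, 0.010)),
                             ambient_noise_power=0.0)
        y = bs.apply_channel(imp, model, "left", np.empty((0, 2)), rate=1000.0)
        expected = np.zeros(100)
        expected[0], expected[10] = 1.0, 0.5
        np.testing.assert_allclose(y, expected)

    def test_delay_beyond_signal_rejected(self):
        model = ChannelModel(taps_left=((1.0, 3.0),), ambient_noise_power=0.0)
        with pytest.raises(InvalidConfigurationError):
            bs.apply_channel(np.zeros(100), model, "left", np.empty((0, 2)),
                             rate=50.0)

    def test_turbulence_confined_to_active_windows(self, tiny_program, rate):
        x, active, _ = bs.simulate_breath_source(tiny_program, rate=rate,
                                                 seed=1, amplitude=0.0)
        model = ChannelModel(taps_left=((1.0, 0.0),), ambient_noise_power=0.0,
                             turbulence_noise_power=0.1)
        y = bs.apply_channel(x, model, "left", active, rate=rate, seed=2)
        p_act, mask = _interval_power(y, active)
        assert p_act == pytest.approx(0.1, rel=0.1)
        assert np.all(y[~mask] == 0.0)


class TestHeartSounds:
    def test_zero_amplitude_is_identity(self, rate):
        x = np.random.default_rng(0).standard_normal(4000)
        y = bs.add_heart_sounds(x, rate, amplitude=0.0)
        np.testing.assert_array_equal(x, y)

    def test_low_band_power_increases(self, rate):
        x = 0.01 * np.random.default_rng(0).standard_normal(40000)
        y = bs.add_heart_sounds(x, rate, amplitude=0.5, seed=1)
        lo = (20.0, 150.0)
        p_before = np.mean(bandpass(x, rate, lo) ** 2)
        p_after = np.mean(bandpass(y, rate, lo) ** 2)
        assert p_after > p_before

    def test_s1_burst_count(self, rate):
        # 60 beats/min over 10 s -> 10 S1 onsets in the clean train
        train = bs.heart_sound_train(int(10 * rate), rate, heart_rate=60.0,
                                     amplitude=1.0, seed=None)
        from scipy.signal import find_peaks

        env = np.abs(train)
        # S1 peaks reach ~amplitude; S2 peaks are 0.6x -> threshold between
        peaks, _ = find_peaks(env, height=0.75, distance=int(0.5 * rate))
        assert len(peaks) == 10


class TestSimulateSubject:
    def test_duration_matches_program(self, short_program, rate):
        sim = bs.simulate_subject(bs.SimSubject("a", 9, seed=1),
                                  program=short_program, rate=rate)
        assert abs(sim.recording.n_samples
                   - round(short_program.total_duration * rate)) <= 1

    def test_truth_segments_tile_recording(self, short_program):
        sim = bs.simulate_subject(bs.SimSubject("a", 9, seed=1),
                                  program=short_program)
        segs = sim.truth_segments
        assert segs.starts[0] == 0
        assert segs.ends[-1] == sim.recording.n_samples
        assert np.all(segs.starts[1:] == segs.ends[:-1])

    def test_noise_free_snr_is_capped(self, tiny_program):
        subj = bs.SimSubject("a", 10, turbulence_noise_power=0.0, seed=1)
        models = ChannelModel(ambient_noise_power=0.0, turbulence_noise_power=0.0)
        sim = bs.simulate_subject(subj, program=tiny_program, left_model=models,
                                  right_model=models, motion_burst_count=0)
        assert sim.truth_snr_db["left"] == 60.0
        assert sim.truth_snr_db["right"] == 60.0

    def test_tenfold_turbulence_costs_10db(self, short_program):
        # when turbulence dominates ambient, x10 power -> -10 dB truth SNR
        kw = dict(program=short_program, motion_burst_count=0)
        sims = []
        for p_t in (0.01, 0.1):
            subj = bs.SimSubject("a", 5, turbulence_noise_power=p_t,
                                 breath_gain_db=0.0, seed=9)
            m = ChannelModel(ambient_noise_power=1e-8,
                             turbulence_noise_power=p_t)
            sims.append(bs.simulate_subject(subj, left_model=m, right_model=m,
                                            **kw))
        diff = sims[0].truth_snr_db["left"] - sims[1].truth_snr_db["left"]
        assert diff == pytest.approx(10.0, abs=1.0)

    def test_heart_sounds_raise_left_truth_snr(self, short_program):
        m = ChannelModel()           # identical taps both sides
        sim = bs.simulate_subject(
            bs.SimSubject("a", 9, seed=4), program=short_program,
            left_model=m, right_model=m, motion_burst_count=0,
            heart_counts_as_signal=True)
        assert sim.truth_snr_db["left"] >= sim.truth_snr_db["right"]

    def test_determinism(self, short_program):
        subj = bs.SimSubject("a", 7, seed=123)
        a = bs.simulate_subject(subj, program=short_program)
        b = bs.simulate_subject(subj, program=short_program)
        np.testing.assert_array_equal(a.recording.data, b.recording.data)
        np.testing.assert_array_equal(a.recording.motion, b.recording.motion)

    def test_power_bookkeeping_matches_components(self, short_program, rate):
        # reported truth powers == banded variance of the stored components
        sim = bs.simulate_subject(bs.SimSubject("a", 8, seed=2),
                                  program=short_program, motion_burst_count=0,
                                  keep_components=True)
        mask = sim.truth_segments.sample_mask("active")
        for side in ("left", "right"):
            p_s = np.mean(bandpass(sim.components[side]["clean"], rate,
                                   (100.0, 1000.0))[mask] ** 2)
            assert p_s == pytest.approx(sim.truth_powers[side][0], rel=0.01)

    def test_truth_snr_decreasing_in_turbulence(self, short_program):
        snrs = []
        for p_t in (1e-4, 1e-3, 1e-2, 1e-1):
            subj = bs.SimSubject("a", 5, turbulence_noise_power=p_t,
                                 breath_gain_db=0.0, seed=11)
            m = ChannelModel(turbulence_noise_power=p_t)
            sim = bs.simulate_subject(subj, program=short_program,
                                      left_model=m, right_model=m,
                                      motion_burst_count=0)
            snrs.append(sim.truth_snr_db["left"])
        assert all(a > b for a, b in zip(snrs, snrs[1:]))

    def test_truth_snr_nonincreasing_in_fabric(self, short_program):
        snrs = []
        for fab in (0.0, 6.0, 12.0):
            m = ChannelModel(fabric_attenuation_db=fab)
            sim = bs.simulate_subject(bs.SimSubject("a", 9, seed=6),
                                      program=short_program, left_model=m,
                                      right_model=m, motion_burst_count=0)
            snrs.append(sim.truth_snr_db["left"])
        assert all(a >= b for a, b in zip(snrs, snrs[1:]))


class TestSimulateCohort:
    def test_metadata_has_unique_rows(self, tmp_path):
        prog = bs.BreathProgram(depth_sequence=(("normal", 6.0),))
        _, meta = bs.simulate_cohort(n_healthy=5, n_copd=2, seed=0,
                                     program=prog, out_dir=tmp_path,
                                     motion_burst_count=0)
        assert len(meta) == 7
        assert meta["subject_id"].is_unique
        assert set(meta.columns) >= {"subject_id", "age", "gender", "group",
                                     "health_scale", "seed"}
        assert (tmp_path / "sub000.wav").exists()
        assert (tmp_path / "metadata.csv").exists()
        assert (tmp_path / "truth_labels.csv").exists()

    def test_constant_scale_map_decorrelates_truth(self, short_program):
        outs, meta = bs.simulate_cohort(
            n_healthy=16, n_copd=2, seed=1, program=short_program,
            scale_map=lambda h: 1e-3, breath_gain_map=lambda h: 0.0,
            motion_burst_count=0)
        truth = [o.truth_snr_db["left"] for o in outs]
        rho = spearmanr(meta["health_scale"], truth).statistic
        assert abs(rho) < 0.5

    def test_default_maps_give_positive_truth_correlation(self, short_program):
        outs, meta = bs.simulate_cohort(n_healthy=16, n_copd=2, seed=1,
                                        program=short_program,
                                        motion_burst_count=0)
        truth = [o.truth_snr_db["left"] for o in outs]
        rho = spearmanr(meta["health_scale"], truth).statistic
        assert rho > 0.8

    def test_turbulence_map_strictly_decreasing_in_health(self):
        powers = [bs.default_turbulence_power(h) for h in range(1, 11)]
        assert all(a > b for a, b in zip(powers, powers[1:]))
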