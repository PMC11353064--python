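"""Stimulus synthesis: grids, spectra, envelopes, onset geometry, WAV I/O."""

import math

import numpy as np
import pytest

from echofit.stimulus import (
    StimulusSpec,
    assemble_trial_audio,
    am_envelope,
    make_f0_grid,
    phase_to_onset_delay,
    read_wav,
    synth_am_noise,
    synth_multitone,
    write_wav,
)

PHASES = (0.0, 0.5 * math.pi, math.pi, 1.5 * math.pi, 2.0 * math.pi)


class TestF0Grid:
    def test_design_grid_endpoints_and_size(self):
        grid = make_f0_grid(270, 715, 211)
        assert grid.size == 211
        assert grid[0] == pytest.approx(270)
        assert grid[-1] == pytest.approx(715)

    def test_log_spacing_constant_ratio(self):
        grid = make_f0_grid(270, 715, 211)
        ratios = grid[1:] / grid[:-1]
        assert np.allclose(ratios, ratios[0])

    @pytest.mark.parametrize("n, expected", [
        (2, [270.0, 715.0]),
        (3, [270.0, math.sqrt(270 * 715), 715.0]),
    ])
    def test_small_grids(self, n, expected):
        assert make_f0_grid(270, 715, n) == pytest.approx(expected)

    @pytest.mark.parametrize("args", [(0, 715, 5), (715, 270, 5), (270, 715, 1)])
    def test_invalid_arguments(self, args):
        with pytest.raises(ValueError):
            make_f0_grid(*args)


class TestMultitone:
    def test_sample_count(self):
        wave = synth_multitone(270.0, StimulusSpec())
        assert wave.size == 2205  # 50 ms at 44.1 kHz

    def test_component_frequencies_and_3db_steps(self):
        # long variant, Hann-windowed analysis so ramp skirts don't leak
        spec = StimulusSpec(target_dur=1.0)
        f0 = 441.0
        wave = synth_multitone(f0, spec) * np.hanning(44100)
        mag = np.abs(np.fft.rfft(wave))
        freqs = np.fft.rfftfreq(wave.size, 1.0 / spec.sample_rate)
        peak_db = []
        for mult in spec.harmonic_multipliers:
            k = int(np.argmin(np.abs(freqs - f0 * mult)))
            sl = slice(max(k - 3, 0), k + 4)
            peak_db.append(20 * np.log10(mag[sl].max()))
        steps = -np.diff(peak_db) * np.diff(spec.harmonic_multipliers) ** 0
        # successive components 3 +/- 0.5 dB apart
        assert np.all(np.abs(np.array(steps) - 3.0) < 0.5)
        # nothing above the -60 dB floor away from the components
        floor_mask = np.ones_like(mag, bool)
        for mult in spec.harmonic_multipliers:
            k = int(np.argmin(np.abs(freqs - f0 * mult)))
            floor_mask[max(k - 30, 0):k + 31] = False
        top = 20 * np.log10(mag[~floor_mask].max())
        assert 20 * np.log10(mag[floor_mask].max() + 1e-300) < top - 60

    def test_peak_normalized(self):
        wave = synth_multitone(440.0, StimulusSpec())
        assert np.max(np.abs(wave)) == pytest.approx(0.9)

    def test_aliasing_rejected(self):
        with pytest.raises(ValueError, match="alias"):
            synth_multitone(3000.0, StimulusSpec())


class TestEnvelope:
    def test_cosine_envelope_landmarks(self):
        spec = StimulusSpec()
        assert am_envelope(0.0, spec) == pytest.approx(0.0)       # starts at min
        assert am_envelope(0.0625, spec) == pytest.approx(1.0)    # mid-cycle peak
        assert am_envelope(0.125, spec) == pytest.approx(0.0)     # full cycle

    def test_full_depth_reaches_zero(self):
        spec = StimulusSpec()
        t = np.linspace(0, spec.am_period, 1000)
        assert am_envelope(t, spec).min() == pytest.approx(0.0, abs=1e-4)

    def test_inverse_sawtooth_edges(self):
        spec = StimulusSpec(am_waveform="inverse_sawtooth")
        assert am_envelope(0.0, spec) == pytest.approx(1.0)
        assert am_envelope(0.125 - 1e-9, spec) == pytest.approx(0.0, abs=1e-6)
        assert am_envelope(0.125, spec) == pytest.approx(1.0)

    def test_autocorrelation_period_125ms(self):
        spec = StimulusSpec()
        n = round(spec.noise_dur * spec.sample_rate)
        t = np.arange(n) / spec.sample_rate
        env = np.asarray(am_envelope(t, spec)) - 0.5
        # envelope holds 16 whole cycles in 2 s: circular autocorrelation
        # is exact and peaks at the true (non-integer) 5512.5-sample period
        ac = np.fft.irfft(np.abs(np.fft.rfft(env)) ** 2, n=n)
        period = spec.sample_rate / spec.am_rate  # 125 ms
        lo, hi = int(0.6 * period), int(1.4 * period)
        lag = lo + int(np.argmax(ac[lo:hi]))
        assert abs(lag - period) <= 1

    def test_noise_is_seeded_and_bounded(self):
        spec = StimulusSpec()
        a = synth_am_noise(spec, seed=5)
        b = synth_am_noise(spec, seed=5)
        c = synth_am_noise(spec, seed=6)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)
        assert np.max(np.abs(a)) <= 1.0


class TestOnsetGeometry:
    def test_cosine_mode_delays(self):
        spec = StimulusSpec()
        assert phase_to_onset_delay(0.0, spec) == pytest.approx(0.0625)
        assert phase_to_onset_delay(2 * math.pi, spec) == pytest.approx(0.1875)
        assert (phase_to_onset_delay(math.pi, spec)
                - phase_to_onset_delay(0.0, spec)) == pytest.approx(0.0625)

    def test_five_conditions_quarter_period_spacing(self):
        spec = StimulusSpec()
        delays = np.array([phase_to_onset_delay(p, spec) for p in PHASES])
        assert np.all(np.diff(delays) > 0)
        assert np.diff(delays) == pytest.approx(np.full(4, 0.03125))
        assert delays[-1] - delays[0] == pytest.approx(1.0 / spec.am_rate)

    def test_inverse_sawtooth_next_peak_full_period(self):
        spec = StimulusSpec(am_waveform="inverse_sawtooth")
        assert phase_to_onset_delay(0.0, spec) == pytest.approx(0.125)
        assert phase_to_onset_delay(2 * math.pi, spec) == pytest.approx(0.250)

    def test_phase_out_of_range(self):
        with pytest.raises(ValueError):
            phase_to_onset_delay(-0.1, StimulusSpec())
        with pytest.raises(ValueError):
            phase_to_onset_delay(7.0, StimulusSpec())


class TestTrialAssembly:
    def test_target_noise_peak_ratio_8db(self):
        spec = StimulusSpec()
        audio = assemble_trial_audio(440.0, 0.0, spec, seed=1)
        sr = spec.sample_rate
        noise_part = audio.samples[: round(spec.noise_dur * sr)]
        onset = round(audio.target_onset_time * sr)
        target_part = audio.samples[onset: onset + round(spec.target_dur * sr)]
        ratio = np.max(np.abs(target_part)) / np.max(np.abs(noise_part))
        assert ratio == pytest.approx(10 ** (8 / 20), rel=1e-6)

    def test_same_seed_same_noise_different_placement(self):
        spec = StimulusSpec()
        a = assemble_trial_audio(440.0, 0.0, spec, seed=3)
        b = assemble_trial_audio(440.0, 2 * math.pi, spec, seed=3)
        n = round(spec.noise_dur * spec.sample_rate)
        assert np.array_equal(a.samples[:n], b.samples[:n])
        assert b.target_onset_time > a.target_onset_time

    def test_event_times_and_duration_bound(self):
        spec = StimulusSpec()
        audio = assemble_trial_audio(300.0, math.pi, spec, seed=0)
        assert audio.am_offset_time == pytest.approx(spec.noise_dur)
        assert audio.target_onset_time == pytest.approx(
            spec.noise_dur + phase_to_onset_delay(math.pi, spec))
        min_dur = spec.noise_dur + phase_to_onset_delay(math.pi, spec) + spec.target_dur
        assert audio.samples.size / spec.sample_rate >= min_dur
        assert np.max(np.abs(audio.samples)) <= 1.0


class TestWavIO:
    def test_round_trip_within_quantization(self, tmp_path):
        spec = StimulusSpec()
        audio = assemble_trial_audio(440.0, 0.0, spec, seed=2)
        path = write_wav(audio, tmp_path / "trial.wav")
        samples, rate = read_wav(path)
        assert rate == spec.sample_rate
        assert np.max(np.abs(samples - audio.samples)) <= 2 ** -15
        assert (tmp_path / "trial.json").exists()

    def test_frame_count(self, tmp_path):
        from echofit.stimulus import TrialAudio
        sr = 44100
        n = round(2.25 * sr)
        audio = TrialAudio(samples=np.zeros(n), sample_rate=sr,
                           am_offset_time=1.0, target_onset_time=2.0,
                           phase_condition=0.0, f0=440.0)
        path = write_wav(audio, tmp_path / "z.wav", sidecar=False)
        samples, _ = read_wav(path)
        assert samples.size == 99225


class TestSpecValidation:
    @pytest.mark.parametrize("kwargs", [
        {"am_rate": 0.0},
        {"am_depth": 1.5},
        {"noise_dur": 2.01},                       # non-integer cycle count
        {"target_dur": 0.006, "ramp_dur": 0.005},  # ramps longer than body
        {"harmonic_multipliers": (2, 4, 6)},       # missing fundamental
        {"am_waveform": "square"},
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            StimulusSpec(**kwargs)

    def test_experiment_presets(self):
        e1 = StimulusSpec.for_experiment(1)
        e2 = StimulusSpec.for_experiment(2)
        assert e1.target_dur == 0.050 and e1.am_waveform == "cosine"
        assert e2.target_dur == 0.025 and e2.am_waveform == "inverse_sawtooth"
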