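"""Stimulus generators: construction properties and ground-truth bookkeeping."""

import numpy as np
import pytest
from scipy.fft import rfft, rfftfreq

import tcstream as tc
from tcstream.stimuli import RAMP_DUR


def spectral_peak_freqs(w: tc.Waveform, n_peaks: int, min_rel: float = 0.1):
    spec = np.abs(rfft(w.samples))
    freqs = rfftfreq(w.samples.size, 1 / w.sample_rate)
    order = np.argsort(spec)[::-1]
    peaks = []
    for i in order:
        if spec[i] < min_rel * spec[order[0]]:
            break
        if all(abs(freqs[i] - p) > 20 for p in peaks):
            peaks.append(freqs[i])
        if len(peaks) == n_peaks:
            break
    return sorted(peaks)


class TestAlternatingTones:
    def test_duration_and_spectral_content(self):
        mix, _ = tc.gen_alternating_tones(400, 1000, tone_dur=0.1, ioi=0.15,
                                          reps=10)
        assert mix.samples.size == int(20 * 0.15 * mix.sample_rate)
        peaks = spectral_peak_freqs(mix, 2)
        assert np.allclose(peaks, [400, 1000], atol=5)

    def test_equal_frequencies_collapse_to_one_stream(self):
        _, truth = tc.gen_alternating_tones(500, 500, reps=3)
        assert truth.labels == [1, 1]

    def test_per_tone_rms_equal_across_streams(self):
        _, truth = tc.gen_alternating_tones(400, 1000, tone_dur=0.1,
                                            ioi=0.15, reps=5)
        rms = []
        for comp, onsets in zip(truth.components, truth.onsets):
            sr = comp.sample_rate
            for t0, t1 in onsets:
                seg = comp.samples[int(t0 * sr): int(t1 * sr)]
                rms.append(np.sqrt(np.mean(seg ** 2)))
        assert np.ptp(rms) / np.mean(rms) < 0.01

    def test_aliasing_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            tc.gen_alternating_tones(400, 9000, sr=16000)

    def test_tone_longer_than_ioi_rejected(self):
        with pytest.raises(ValueError):
            tc.gen_alternating_tones(400, 1000, tone_dur=0.2, ioi=0.15)


class TestCrossingTones:
    def test_tracks_symmetric_about_midpoint(self):
        _, truth = tc.gen_crossing_tones(400, 1600, step=1.6, reps=16)
        low, high = truth.component_freqs
        assert low[0] == 400 and high[0] == 1600
        # symmetric pair around the crossing: low[7] == high[8], etc.
        assert np.isclose(low[7], high[8], rtol=1e-9)
        assert np.isclose(low[8], high[7], rtol=1e-9)

    def test_register_labeling_splits_at_crossover(self):
        _, truth = tc.gen_crossing_tones(400, 1600, step=1.6, reps=16)
        cross = truth.extras["crossover_hz"]
        assert np.isclose(cross, np.sqrt(400 * 1600))
        for freqs, regs in zip(truth.component_freqs,
                               truth.extras["register_labels"]):
            for f, r in zip(freqs, regs):
                assert r == (2 if f >= cross else 1)

    def test_zero_step_single_rep_reduces_to_alternating(self):
        mix, truth = tc.gen_crossing_tones(400, 1000, step=0.0, reps=1,
                                           tone_dur=0.1, ioi=0.15)
        alt, _ = tc.gen_alternating_tones(400, 1000, tone_dur=0.1, ioi=0.15,
                                          reps=1)
        assert np.allclose(mix.samples, alt.samples)

    def test_track_exiting_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            tc.gen_crossing_tones(400, 1600, step=40.0, reps=16)


class TestToneComplexes:
    def test_zero_asynchrony_onsets_coincide(self):
        _, truth = tc.gen_tone_complexes((400, 800), (600, 1200), 0.0, reps=3)
        for (a0, _), (b0, _) in zip(*truth.onsets):
            assert a0 == b0

    def test_asynchrony_shifts_second_complex(self):
        _, truth = tc.gen_tone_complexes((400, 800), (600, 1200), 0.04, reps=3)
        for (a0, _), (b0, _) in zip(*truth.onsets):
            assert np.isclose(b0 - a0, 0.04)

    def test_energy_additivity_for_disjoint_frequencies(self):
        mix, truth = tc.gen_tone_complexes((400, 800), (566, 1131), 0.02,
                                           reps=4)
        e_mix = np.sum(mix.samples ** 2)
        e_parts = sum(np.sum(c.samples ** 2) for c in truth.components)
        assert abs(e_mix - e_parts) / e_parts < 1e-2

    def test_asynchrony_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tc.gen_tone_complexes((400,), (600,), 0.3, period=0.24)


class TestHarmonicComplex:
    def test_partial_frequencies(self):
        w, truth = tc.gen_harmonic_complex(500, 4, dur=0.5)
        assert truth.component_freqs[0] == [500, 1000, 1500, 2000]
        peaks = spectral_peak_freqs(w, 4)
        assert np.allclose(peaks, [500, 1000, 1500, 2000], atol=5)

    def test_fig3_top_partials_are_closely_spaced(self):
        _, t500 = tc.gen_harmonic_complex(500, 4)
        _, t630 = tc.gen_harmonic_complex(630, 3)
        assert t500.component_freqs[0][-1] == 2000
        assert t630.component_freqs[0][-1] == 1890

    def test_single_harmonic_is_pure_tone(self):
        w, _ = tc.gen_harmonic_complex(440, 1, dur=0.3)
        peaks = spectral_peak_freqs(w, 1)
        assert np.allclose(peaks, [440], atol=5)

    def test_peak_at_zero_phase_alignment(self):
        amp = 0.2
        w, _ = tc.gen_harmonic_complex(500, 4, dur=0.3, amps=[amp] * 4,
                                       ramp=0.0)
        assert np.isclose(w.samples[0], 4 * amp)

    def test_aliasing_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            tc.gen_harmonic_complex(500, 20)


class TestMixture:
    def test_zero_db_equal_rms(self):
        w1, _ = tc.gen_harmonic_complex(300, 3, dur=0.5)
        w2, _ = tc.gen_harmonic_complex(1200, 2, dur=0.5)
        _, truth = tc.gen_mixture(w1, w2, 0.0)
        r1, r2 = (np.sqrt(np.mean(c.samples ** 2)) for c in truth.components)
        assert np.isclose(r1, r2, rtol=1e-9)

    @pytest.mark.parametrize("snr_db", [-10.0, 0.0, 12.5])
    def test_stated_snr_is_realized(self, snr_db):
        w1, _ = tc.gen_harmonic_complex(300, 3, dur=0.5)
        w2, _ = tc.gen_harmonic_complex(1200, 2, dur=0.5)
        _, truth = tc.gen_mixture(w1, w2, snr_db)
        p1, p2 = (np.mean(c.samples ** 2) for c in truth.components)
        assert np.isclose(10 * np.log10(p1 / p2), snr_db, atol=1e-9)

    def test_silent_input_rejected(self):
        w1, _ = tc.gen_harmonic_complex(300, 3, dur=0.5)
        silent = tc.Waveform(np.zeros(1000))
        with pytest.raises(ValueError, match="silent"):
            tc.gen_mixture(w1, silent, 0.0)

    def test_infinite_snr_returns_first_source(self):
        w1, _ = tc.gen_harmonic_complex(300, 3, dur=0.5)
        w2, _ = tc.gen_harmonic_complex(1200, 2, dur=0.5)
        mix, truth = tc.gen_mixture(w1, w2, np.inf)
        assert np.array_equal(mix.samples, w1.samples)
        assert len(truth.components) == 1


class TestAuxEnvelope:
    def test_am_tone_envelope_tracks_modulator(self):
        w, _ = tc.gen_am_tone(1000, 4.0, dur=2.0)
        env = tc.gen_aux_envelope(w, cutoff=8.0)
        t = (np.arange(env.size) + 1) / 125.0
        modulator = 1.0 - 0.5 * (1 + np.cos(2 * np.pi * 4.0 * t))
        n = env.size
        c = np.corrcoef(env[10 : n - 10], modulator[10 : n - 10])[0, 1]
        assert c > 0.9

    def test_constant_tone_envelope_flat(self):
        w, _ = tc.gen_harmonic_complex(800, 1, dur=1.0)
        env = tc.gen_aux_envelope(w, cutoff=8.0)
        mid = env[30:-10]
        assert np.ptp(mid) / np.mean(mid) < 0.15

    def test_silence_gives_zero_envelope(self):
        env = tc.gen_aux_envelope(tc.Waveform(np.zeros(16000)), cutoff=8.0)
        assert np.all(env == 0)

    def test_cutoff_above_cortical_range_rejected(self):
        w, _ = tc.gen_harmonic_complex(800, 1, dur=0.5)
        with pytest.raises(ValueError):
            tc.gen_aux_envelope(w, cutoff=50.0)


class TestInvariants:
    @pytest.mark.parametrize("make", [
        lambda: tc.gen_alternating_tones(400, 1000, reps=4),
        lambda: tc.gen_crossing_tones(400, 1600, step=1.6, reps=8),
        lambda: tc.gen_tone_complexes((400, 800, 1600), (566, 1131, 2263),
                                      0.04, reps=3),
        lambda: tc.gen_alternating_complexes(500, 630, reps=2),
    ])
    def test_components_sum_to_mixture(self, make):
        mix, truth = make()
        assert truth.mixture_residual(mix) < 1e-9

    def test_generators_deterministic(self):
        a, _ = tc.gen_alternating_tones(400, 1000, reps=3)
        b, _ = tc.gen_alternating_tones(400, 1000, reps=3)
        assert np.array_equal(a.samples, b.samples)
        pa = tc.gen_benchmark_pairs(4, dur=0.5, seed=7)
        pb = tc.gen_benchmark_pairs(4, dur=0.5, seed=7)
        for (x, y, _), (u, v, _) in zip(pa, pb):
            assert np.array_equal(x.samples, u.samples)
            assert np.array_equal(y.samples, v.samples)

    def test_wav_round_trip(self, tmp_path):
        from tcstream import io

        mix, _ = tc.gen_alternating_tones(400, 1000, reps=3)
        path = tmp_path / "stim.wav"
        io.write_wav(path, mix.samples, mix.sample_rate)
        back, sr = io.read_wav(path)
        assert sr == mix.sample_rate
        assert np.max(np.abs(back - mix.samples)) < 1e-4

    def test_ramps_bound_peak(self):
        w, _ = tc.gen_harmonic_complex(500, 8, dur=0.3)
        assert np.max(np.abs(w.samples)) <= 1.0
        n_ramp = int(RAMP_DUR * w.sample_rate)
        assert abs(w.samples[0]) < 1e-12  # ramp starts at zero
        assert np.max(np.abs(w.samples[:n_ramp // 2])) < np.max(np.abs(w.samples))
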