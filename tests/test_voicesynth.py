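"""Synthetic voices: harmonic structure, jitter, whispering, word codes."""

import numpy as np
import pytest
from scipy.signal import butter, freqz, tf2zpk, zpk2tf

from cuedgain.cochlea import AudioClip
from cuedgain.voicesynth import (MODULATION_BANDS, JitterPattern,
                                 band_envelopes, identify_word, make_voice,
                                 make_word, sample_jitter, synth_utterance,
                                 whisper_filter)


def spectral_peaks(clip, n_peaks=12, fmax=4000.0, window_s=0.25):
    """FFT peak-picking oracle on a short window (slow f0 contour ~frozen)."""
    n = int(window_s * clip.sample_rate)
    x = clip.samples[0][:n] * np.hanning(n)
    spec = np.abs(np.fft.rfft(x, 8 * n))
    freqs = np.fft.rfftfreq(8 * n, 1 / clip.sample_rate)
    sel = freqs < fmax
    spec, freqs = spec[sel], freqs[sel]
    peaks = []
    s = spec.copy()
    df = freqs[1] - freqs[0]
    for _ in range(n_peaks):
        i = np.argmax(s)
        peaks.append(freqs[i])
        lo = max(0, i - int(30 / df))
        s[lo: i + int(30 / df)] = 0
    return np.sort(peaks)


class TestSynthUtterance:
    def test_duration_and_determinism(self, catalog):
        words = [catalog.words[i] for i in (0, 1, 2)]
        a, tra = synth_utterance(catalog.voices[0], words,
                                 rng=np.random.default_rng(5))
        b, trb = synth_utterance(catalog.voices[0], words,
                                 rng=np.random.default_rng(5))
        assert a.duration == pytest.approx(2.5)
        assert np.array_equal(a.samples, b.samples)
        assert tra == trb

    def test_transcript_covers_midpoint(self, catalog):
        words = [catalog.words[i] for i in (3, 4, 5)]
        _, tr = synth_utterance(catalog.voices[1], words,
                                rng=np.random.default_rng(0))
        assert any(w["onset"] <= 1.25 < w["offset"] for w in tr)

    def test_unjittered_peaks_lie_on_f0_multiples(self):
        # contour disabled so spectral lines are sharp
        rng = np.random.default_rng(0)
        v = make_voice(0, "low", rng)
        v.contour_depth = 0.0
        words = [make_word(i) for i in (0, 0, 0)]
        clip, _ = synth_utterance(v, words, rng=np.random.default_rng(1))
        peaks = spectral_peaks(clip, n_peaks=6)
        mult = peaks / v.f0
        assert np.all(np.abs(mult - np.round(mult)) < 0.03)

    def test_overflowing_words_rejected(self, catalog):
        with pytest.raises(ValueError):
            synth_utterance(catalog.voices[0], [catalog.words[0]] * 5,
                            clip_len=2.5, rng=np.random.default_rng(0))


class TestJitter:
    def test_bounds_and_spacing_many_draws(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            f0 = float(rng.uniform(80, 280))
            pat = sample_jitter(60, f0, rng)
            assert np.all(np.abs(pat.shifts) <= 0.3)
            assert pat.shifts[0] == 0.0
            assert np.all(np.diff(pat.component_freqs(f0)) >= 30.0)

    def test_zero_jitter_equals_harmonic_synthesis(self):
        rng = np.random.default_rng(0)
        v = make_voice(0, "high", rng)
        words = [make_word(i) for i in (1, 2, 3)]
        zero = JitterPattern(np.zeros(200))
        h, _ = synth_utterance(v, words, rng=np.random.default_rng(1))
        iz, _ = synth_utterance(v, words, rng=np.random.default_rng(1),
                                mode="inharmonic", jitter=zero)
        np.testing.assert_allclose(h.samples, iz.samples, atol=1e-12)

    def test_infeasible_f0_rejected(self):
        with pytest.raises(ValueError):
            sample_jitter(10, 20.0, np.random.default_rng(0))

    def test_inharmonic_component_at_shifted_frequency(self):
        rng = np.random.default_rng(0)
        v = make_voice(0, "low", rng)
        v.contour_depth = 0.0
        pat = sample_jitter(80, v.f0, np.random.default_rng(2))
        words = [make_word(0)] * 3
        clip, _ = synth_utterance(v, words, rng=np.random.default_rng(1),
                                  mode="inharmonic", jitter=pat)
        expected = pat.component_freqs(v.f0)[2]     # component 3
        peaks = spectral_peaks(clip, n_peaks=10)
        assert np.min(np.abs(peaks - expected)) < 8.0

    def test_missing_jitter_rejected(self, catalog):
        with pytest.raises(ValueError):
            synth_utterance(catalog.voices[0], [catalog.words[0]] * 3,
                            rng=np.random.default_rng(0), mode="inharmonic")


class TestWhisper:
    def test_highpass_ordering(self):
        rng = np.random.default_rng(0)
        noise = AudioClip(rng.standard_normal(44100))
        out = whisper_filter(noise)
        spec = np.abs(np.fft.rfft(out.samples[0])) ** 2
        freqs = np.fft.rfftfreq(out.n_samples, 1 / 44100)

        def band_power(lo, hi):
            return spec[(freqs > lo) & (freqs < hi)].mean()

        assert band_power(3500, 4500) > 10 * band_power(300, 500)

    def test_dc_attenuated_but_nonzero(self):
        # zeros moved off z = 1, so DC leaks through strongly attenuated
        out = whisper_filter(AudioClip(np.ones(4410)))
        tail = out.samples[0][2000:]
        assert 0 < np.abs(tail).max() < 0.2

    def test_magnitude_matches_pole_zero_oracle(self):
        # independent |H(e^{jw})| evaluation of the constructed filter
        b, a = butter(2, 1200.0, btype="highpass", fs=44100)
        z, p, k = tf2zpk(b, a)
        bz, az = zpk2tf(z * 0.95, p, k)
        w = np.linspace(0.001, np.pi * 0.9, 64)
        zinv = np.exp(-1j * w)
        num = k * (1 - (z[0] * 0.95) * zinv) * (1 - (z[1] * 0.95) * zinv)
        den = (1 - p[0] * zinv) * (1 - p[1] * zinv)
        oracle = np.abs(num / den)
        _, h = freqz(bz, az, worN=w)
        np.testing.assert_allclose(np.abs(h), oracle, rtol=1e-8)

    def test_whispered_output_has_no_discrete_lines(self, catalog):
        v = catalog.voices[0]
        words = [catalog.words[i] for i in (0, 1, 2)]
        wcl, _ = synth_utterance(v, words, rng=np.random.default_rng(3),
                                 mode="whispered")
        hcl, _ = synth_utterance(v, words, rng=np.random.default_rng(3))

        def flatness(clip, lo=1700, hi=2800, window_s=0.25):
            # strictly inside one modulation band so band-edge steps do
            # not count; short window so the f0 contour is ~frozen
            n = int(window_s * clip.sample_rate)
            x = clip.samples[0][:n] * np.hanning(n)
            spec = np.abs(np.fft.rfft(x, 4 * n)) ** 2
            freqs = np.fft.rfftfreq(4 * n, 1 / clip.sample_rate)
            s = spec[(freqs > lo) & (freqs < hi)]
            return np.exp(np.mean(np.log(s + 1e-30))) / s.mean()

        assert flatness(wcl) > 0.3
        assert flatness(wcl) > 3 * flatness(hcl)


class TestSeparability:
    def test_word_matched_filter_identification(self, catalog):
        rng = np.random.default_rng(11)
        ok = n = 0
        for vi in range(len(catalog.voices)):
            for wi in range(catalog.vocab):
                seq = [catalog.words[(wi + 1) % 8], catalog.words[wi],
                       catalog.words[(wi + 3) % 8]]
                clip, tr = synth_utterance(catalog.voices[vi], seq, rng=rng)
                mid = tr[1]
                got = identify_word(clip, catalog.words,
                                    (mid["onset"], mid["offset"]))
                ok += int(got == wi)
                n += 1
        assert ok / n >= 0.99

    def test_f0_recovery_within_5_percent(self, catalog):
        for v in catalog.voices:
            words = [catalog.words[i] for i in (0, 2, 4)]
            clip, _ = synth_utterance(v, words, rng=np.random.default_rng(1))
            x = clip.samples[0][:44100]
            ac = np.correlate(x, x, "full")[len(x) - 1:]
            lo, hi = int(44100 / 300), int(44100 / 70)
            lag = np.argmax(ac[lo:hi]) + lo
            assert abs(44100 / lag - v.f0) / v.f0 < 0.05

    def test_envelope_invariant_to_jitter(self, catalog):
        # jitter changes fine structure, not content: the dominant-energy
        # band's amplitude envelope must survive.  (Weak bands bordering a
        # formant are excluded: jittered partials crossing an analysis-band
        # edge genuinely change those envelopes.)
        for v in catalog.voices:
            words = [catalog.words[i] for i in (1, 5, 6)]
            pat = sample_jitter(200, v.f0, np.random.default_rng(4))
            h, _ = synth_utterance(v, words, rng=np.random.default_rng(2))
            ih, _ = synth_utterance(v, words, rng=np.random.default_rng(2),
                                    mode="inharmonic", jitter=pat)
            eh, ei = band_envelopes(h), band_envelopes(ih)
            dom = int(np.argmax(eh.mean(axis=1)))
            assert np.corrcoef(eh[dom], ei[dom])[0, 1] > 0.9


def test_sex_groups_have_disjoint_f0_ranges():
    rng = np.random.default_rng(0)
    lows = [make_voice(i, "low", rng).f0 for i in range(20)]
    highs = [make_voice(i, "high", rng).f0 for i in range(20)]
    assert max(lows) < min(highs)
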