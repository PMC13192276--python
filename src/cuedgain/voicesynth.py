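"""Synthetic-talker "speech": harmonic complexes with talker-specific
source and filter parameters, carrying word identity in deterministic
spectrotemporal amplitude patterns.

These voices stand in for recorded speech corpora so the attentional
mechanism can be exercised at desk scale.  Word identity is carried by
per-band temporal envelopes (not phonetics); voice identity by the
fundamental (with a slow contour) and a formant-like spectral
envelope.  Two disjoint f0 ranges play the role of talker sex.  The
module also implements the source manipulations used to probe
harmonicity: bounded random jitter of harmonic frequencies
(inharmonic) and high-pass-filtered noise excitation (whispered).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, lfilter, sosfiltfilt, tf2zpk, zpk2tf

from .cochlea import AudioClip

__all__ = [
    "VoiceSpec", "WordSpec", "JitterPattern", "Catalog",
    "make_voice", "make_word", "sample_jitter", "synth_utterance",
    "apply_excitation", "whisper_filter", "noise_texture",
    "band_envelopes", "identify_word",
]

SAMPLE_RATE = 44100
LOW_F0_RANGE = (80.0, 140.0)     # "male-like" group
HIGH_F0_RANGE = (160.0, 280.0)   # "female-like" group
MAX_COMPONENT_HZ = 8000.0        # highest synthesized partial
MODULATION_BANDS = np.array([100.0, 300.0, 700.0, 1500.0, 3000.0, 8000.0])


@dataclass
class VoiceSpec:
    voice_id: int
    f0: float
    sex_tag: str                      # "low" or "high" f0 group
    contour_depth: float = 0.03       # fractional f0 excursion
    contour_rate: float = 0.6         # Hz
    contour_phase: float = 0.0
    formants: np.ndarray = field(default=None)      # (n, 2): centre, bandwidth
    tilt_db_per_oct: float = -4.0

    def envelope(self, f: np.ndarray) -> np.ndarray:
        """Formant-like spectral envelope evaluated at frequencies f (Hz)."""
        f = np.asarray(f, dtype=float)
        e = np.zeros_like(f)
        for fc, bw in self.formants:
            e += np.exp(-0.5 * ((f - fc) / bw) ** 2)
        e += 0.05
        tilt = 2.0 ** (np.log2(np.maximum(f, 50.0) / 500.0)
                       * self.tilt_db_per_oct / 6.0)
        return e * tilt


@dataclass
class WordSpec:
    word_id: int
    duration: float = 2.5 / 3
    # per-band envelope over the word interval, drawn deterministically
    # from the word id; shape (n_bands, n_knots)
    knots: np.ndarray = field(default=None)

    def band_envelope(self, band: int, t: np.ndarray) -> np.ndarray:
        """Amplitude trajectory of `band` over word-relative time t in [0,1]."""
        k = self.knots[band]
        return np.interp(t, np.linspace(0, 1, len(k)), k)


@dataclass
class JitterPattern:
    """Per-harmonic fractional shifts in [-0.3, 0.3]; component k >= 2 moves
    to k f0 (1 + shift_k), the fundamental is unshifted."""

    shifts: np.ndarray

    def component_freqs(self, f0: float) -> np.ndarray:
        k = np.arange(1, len(self.shifts) + 1, dtype=float)
        f = k * f0
        f[1:] *= 1.0 + self.shifts[1:]
        return f


def make_voice(voice_id: int, sex_tag: str,
               rng: np.random.Generator) -> VoiceSpec:
    lo, hi = LOW_F0_RANGE if sex_tag == "low" else HIGH_F0_RANGE
    f0 = float(rng.uniform(lo, hi))
    # formants interleave across voices on a log-frequency comb: each voice
    # emphasises its own set of spectral regions, giving talkers distinct
    # excitation patterns (the timbre cue attentional selection relies on)
    offset = 0.25 * (voice_id % 4)
    centers = 320.0 * 2.0 ** (np.arange(3) * 1.25 + offset
                              + rng.uniform(-0.06, 0.06, 3))
    bws = centers * rng.uniform(0.10, 0.16, 3)
    formants = np.stack([centers, bws], axis=1)
    return VoiceSpec(voice_id=voice_id, f0=f0, sex_tag=sex_tag,
                     contour_depth=float(rng.uniform(0.01, 0.05)),
                     contour_rate=float(rng.uniform(0.3, 1.0)),
                     contour_phase=float(rng.uniform(0, 2 * np.pi)),
                     formants=formants,
                     tilt_db_per_oct=float(rng.uniform(-6.0, -2.0)))


def make_word(word_id: int, duration: float = 2.5 / 3,
              n_knots: int = 6) -> WordSpec:
    """Deterministic per-band envelope signature for a word id.

    Each band's trajectory is a piecewise-linear pattern drawn from a
    word-id-seeded generator, with at least one strongly on and one
    strongly off band so words are separable by envelope matched filters.
    """
    rng = np.random.default_rng(977 + word_id)
    n_bands = len(MODULATION_BANDS) - 1
    knots = rng.uniform(0.05, 1.0, size=(n_bands, n_knots))
    on = rng.permutation(n_bands)
    knots[on[0]] = rng.uniform(0.8, 1.0, n_knots)
    knots[on[1]] = rng.uniform(0.0, 0.1, n_knots)
    return WordSpec(word_id=word_id, duration=duration, knots=knots)


def sample_jitter(n_harmonics: int, f0: float, rng: np.random.Generator,
                  max_tries: int = 10000) -> JitterPattern:
    """Uniform [-0.3, 0.3] shifts, rejection-sampled until all adjacent
    shifted components are at least 30 Hz apart (fundamental unshifted)."""
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    if 1.3 * f0 < 30.0:
        # even a maximally up-shifted next component cannot clear 30 Hz
        raise ValueError(f"f0 = {f0} Hz cannot satisfy 30-Hz spacing "
                         "under +/-30% jitter")
    shifts = np.zeros(n_harmonics)
    prev_f = f0
    for k in range(1, n_harmonics):
        nominal = (k + 1) * f0
        for tries in range(max_tries):
            j = rng.uniform(-0.3, 0.3)
            if nominal * (1.0 + j) - prev_f >= 30.0:
                shifts[k] = j
                prev_f = nominal * (1.0 + j)
                break
        else:
            raise RuntimeError("jitter constraint not satisfiable "
                               "within retry budget")
    return JitterPattern(shifts)


def whisper_filter(noise: AudioClip) -> AudioClip:
    """Breath-noise shaping: order-2 high-pass Butterworth at 1,200 Hz whose
    zeros are moved 5% toward the z-plane origin, applied once, causal."""
    b, a = butter(2, 1200.0, btype="highpass", fs=noise.sample_rate)
    z, p, k = tf2zpk(b, a)
    b, a = zpk2tf(z * 0.95, p, k)
    return AudioClip(lfilter(b, a, noise.samples, axis=-1), noise.sample_rate)


def _word_track(words: list, clip_len: float, t: np.ndarray) -> np.ndarray:
    """(n_bands, len(t)) amplitude modulation from the word sequence."""
    n_bands = len(MODULATION_BANDS) - 1
    M = np.zeros((n_bands, len(t)))
    onset = 0.0
    for w in words:
        sel = (t >= onset) & (t < onset + w.duration)
        rel = (t[sel] - onset) / w.duration
        for b in range(n_bands):
            M[b, sel] = w.band_envelope(b, rel)
        onset += w.duration
    return M


def _transcript(words: list) -> list:
    out, onset = [], 0.0
    for w in words:
        out.append({"word_id": int(w.word_id), "onset": onset,
                    "offset": onset + w.duration})
        onset += w.duration
    return out


def synth_utterance(voice: VoiceSpec, words: list, clip_len: float = 2.5,
                    rng: np.random.Generator | None = None,
                    mode: str = "harmonic",
                    jitter: JitterPattern | None = None,
                    sample_rate: int = SAMPLE_RATE):
    """Synthesize an utterance; returns (AudioClip, transcript).

    transcript is a list of {word_id, onset, offset}.  One word must
    overlap the clip's temporal midpoint (the labelled word).
    """
    total = sum(w.duration for w in words)
    if total > clip_len + 1e-9:
        raise ValueError("words overflow the clip")
    mid = clip_len / 2.0
    tr = _transcript(words)
    if not any(w["onset"] <= mid < w["offset"] for w in tr):
        raise ValueError("no word overlaps the clip midpoint")
    clip = apply_excitation(voice, words, mode=mode, jitter=jitter,
                            rng=rng, clip_len=clip_len, sample_rate=sample_rate)
    return clip, tr


def apply_excitation(voice: VoiceSpec, words: list, mode: str = "harmonic",
                     jitter: JitterPattern | None = None,
                     rng: np.random.Generator | None = None,
                     clip_len: float = 2.5,
                     sample_rate: int = SAMPLE_RATE) -> AudioClip:
    """Generate the waveform for a word sequence under a source mode.

    harmonic: partials at k f0 (with the voice's slow f0 contour);
    inharmonic: partial k >= 2 at k f0 (1 + jitter_k); whispered: noise
    excitation through the whisper filter.  All modes share the same
    spectrotemporal envelope (voice envelope x word modulation).
    """
    if mode == "inharmonic" and jitter is None:
        raise ValueError("inharmonic mode requires a jitter pattern")
    if mode != "inharmonic" and jitter is not None:
        raise ValueError("jitter is only meaningful in inharmonic mode")
    n = int(round(clip_len * sample_rate))
    t = np.arange(n) / sample_rate
    M = _word_track(words, clip_len, t)     # (n_bands, n)
    band_edges = MODULATION_BANDS

    if mode == "whispered":
        rng = rng or np.random.default_rng()
        noise = AudioClip(rng.standard_normal(n), sample_rate)
        src = whisper_filter(noise).samples[0]
        out = np.zeros(n)
        ny = sample_rate / 2
        for b in range(len(band_edges) - 1):
            lo, hi = band_edges[b] / ny, min(band_edges[b + 1] / ny, 0.99)
            sos = butter(4, [lo, hi], btype="bandpass", output="sos")
            band = sosfiltfilt(sos, src)
            fc = np.sqrt(band_edges[b] * band_edges[b + 1])
            out += band * M[b] * voice.envelope(np.array([fc]))[0]
        return AudioClip(_soft_normalize(out), sample_rate)

    n_harm = int(MAX_COMPONENT_HZ // voice.f0)
    if mode == "inharmonic" and len(jitter.shifts) < n_harm:
        raise ValueError("jitter pattern has fewer components than needed")
    contour = 1.0 + voice.contour_depth * np.sin(
        2 * np.pi * voice.contour_rate * t + voice.contour_phase)
    if mode == "inharmonic":
        base = jitter.component_freqs(voice.f0)[:n_harm]
    else:
        base = np.arange(1, n_harm + 1) * voice.f0
    # instantaneous phase per component: 2 pi f_k int contour dt
    phase_unit = np.cumsum(contour) / sample_rate * 2 * np.pi
    out = np.zeros(n)
    band_idx = np.clip(np.searchsorted(band_edges, base) - 1, 0,
                       len(band_edges) - 2)
    amps = voice.envelope(base)
    for k in range(n_harm):
        env_t = M[band_idx[k]]
        out += amps[k] * env_t * np.cos(base[k] * phase_unit)
    return AudioClip(_soft_normalize(out), sample_rate)


def _soft_normalize(x: np.ndarray, peak: float = 0.5) -> np.ndarray:
    m = np.abs(x).max()
    return x if m == 0 else x * (peak / m)


def noise_texture(texture_id: int, duration: float = 2.5,
                  rng: np.random.Generator | None = None,
                  sample_rate: int = SAMPLE_RATE) -> AudioClip:
    """Synthesized non-speech distractor: filtered noise with a
    texture-specific spectral envelope and slow amplitude modulation."""
    prng = np.random.default_rng(40577 + texture_id)   # texture identity
    rng = rng or np.random.default_rng()               # exemplar variability
    n = int(round(duration * sample_rate))
    x = rng.standard_normal(n)
    ny = sample_rate / 2
    lo = prng.uniform(60, 800)
    hi = prng.uniform(max(2 * lo, 1200), 12000)
    sos = butter(2, [lo / ny, hi / ny], btype="bandpass", output="sos")
    x = sosfiltfilt(sos, x)
    mod_rate = prng.uniform(1.0, 8.0)
    depth = prng.uniform(0.2, 0.9)
    t = np.arange(n) / sample_rate
    x *= 1.0 - depth * 0.5 * (1 + np.sin(2 * np.pi * mod_rate * t
                                         + rng.uniform(0, 2 * np.pi)))
    return AudioClip(_soft_normalize(x), sample_rate)


@dataclass
class Catalog:
    """Pool of synthetic voices, words and noise textures for scene
    sampling and experiment grids."""

    voices: list
    words: list
    textures: list                      # texture ids

    @classmethod
    def build(cls, n_voices: int = 4, n_words: int = 8, n_textures: int = 3,
              seed: int = 0, word_duration: float = 2.5 / 3) -> "Catalog":
        rng = np.random.default_rng(seed)
        voices = [make_voice(i, "low" if i % 2 == 0 else "high", rng)
                  for i in range(n_voices)]
        words = [make_word(i, duration=word_duration) for i in range(n_words)]
        return cls(voices=voices, words=words, textures=list(range(n_textures)))

    @property
    def vocab(self) -> int:
        return len(self.words)


def band_envelopes(clip: AudioClip, env_rate: float = 100.0) -> np.ndarray:
    """Smoothed modulation-band amplitude envelopes, (n_bands, T).

    Bandpass at the word-code band edges, rectify, low-pass well below
    the beating rate of adjacent harmonics, then decimate to env_rate.
    """
    ny = clip.sample_rate / 2
    step = int(round(clip.sample_rate / env_rate))
    sos_lp = butter(4, 30.0 / ny, btype="lowpass", output="sos")
    envs = []
    for b in range(len(MODULATION_BANDS) - 1):
        lo = MODULATION_BANDS[b] / ny
        hi = min(MODULATION_BANDS[b + 1] / ny, 0.99)
        sos = butter(4, [lo, hi], btype="bandpass", output="sos")
        e = sosfiltfilt(sos_lp, np.abs(sosfiltfilt(sos, clip.samples[0])))
        envs.append(e[::step])
    return np.array(envs)


def identify_word(clip: AudioClip, words: list, window: tuple,
                  env_rate: float = 100.0) -> int:
    """Matched-filter word identification from band envelopes.

    `window` is the (onset, offset) of the word interval in seconds.
    Returns the word_id in `words` whose per-band envelope pattern best
    correlates with the clip's envelopes over the window.
    """
    env = band_envelopes(clip, env_rate)
    i0, i1 = (int(round(w * env_rate)) for w in window)
    seg = env[:, i0:i1]
    t_rel = np.linspace(0, 1, seg.shape[1])
    best, best_score = None, -np.inf
    for w in words:
        tpl = np.array([w.band_envelope(b, t_rel) for b in range(len(seg))])
        score = 0.0
        for b in range(len(seg)):
            if seg[b].std() > 0 and tpl[b].std() > 0:
                score += np.corrcoef(seg[b], tpl[b])[0, 1]
        if score > best_score:
            best, best_score = w.word_id, score
    return best


def write_transcript(path, transcript: list) -> None:
    with open(path, "w") as fh:
        json.dump(transcript, fh, indent=1)
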