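"""Fixed simulation of the auditory periphery.

Maps a (stereo) waveform to a per-ear cochleagram: gammatone filterbank
spaced on the ERB-number scale, half-wave rectification, power-law
compression (exponent 0.3, emulating outer-hair-cell compression),
Kaiser-windowed-sinc low-pass + polyphase downsampling, and a centre
crop that discards onset/offset context.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile
from functools import lru_cache

from scipy.fft import irfft, next_fast_len, rfft
from scipy.signal import upfirdn

__all__ = [
    "AudioClip", "CochleaConfig", "FeatureMap",
    "erb_number", "erb_number_inverse", "erb_bandwidth",
    "erb_center_frequencies", "gammatone_fir", "cochleagram",
]

# Glasberg-Moore ERB-number scale constants
ERB_A = 21.4
ERB_B = 0.00437


def erb_number(f_hz):
    """Frequency (Hz) -> ERB number (Cams)."""
    return ERB_A * np.log10(ERB_B * np.asarray(f_hz, dtype=float) + 1.0)


def erb_number_inverse(n_erb):
    """ERB number (Cams) -> frequency (Hz)."""
    return (10.0 ** (np.asarray(n_erb, dtype=float) / ERB_A) - 1.0) / ERB_B


def erb_bandwidth(f_hz):
    """Equivalent rectangular bandwidth (Hz) at centre frequency f_hz."""
    return 24.7 * (1.0 + 4.37 * np.asarray(f_hz, dtype=float) / 1000.0)


@dataclass
class AudioClip:
    """A sampled waveform: ``samples`` is (n_channels, n_samples)."""

    samples: np.ndarray
    sample_rate: int = 44100

    def __post_init__(self):
        s = np.asarray(self.samples, dtype=np.float64)
        if s.ndim == 1:
            s = s[None, :]
        if s.ndim != 2:
            raise ValueError("samples must be 1-D or (n_channels, n_samples)")
        if not np.all(np.isfinite(s)):
            raise ValueError("non-finite sample values")
        self.samples = s

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def rms(self) -> float:
        """Single scalar RMS across all channels jointly."""
        return float(np.sqrt(np.mean(self.samples**2)))

    def normalized(self, target_rms: float = 0.02) -> "AudioClip":
        r = self.rms()
        if r == 0.0:
            return AudioClip(self.samples.copy(), self.sample_rate)
        return AudioClip(self.samples * (target_rms / r), self.sample_rate)

    def to_mono(self) -> "AudioClip":
        return AudioClip(self.samples.mean(axis=0), self.sample_rate)

    def diotic(self) -> "AudioClip":
        """Duplicate a mono clip to both ears (explicit caller decision)."""
        if self.n_channels != 1:
            raise ValueError("diotic presentation requires a mono clip")
        return AudioClip(np.repeat(self.samples, 2, axis=0), self.sample_rate)

    @classmethod
    def silence(cls, duration: float, sample_rate: int = 44100,
                n_channels: int = 1) -> "AudioClip":
        n = int(round(duration * sample_rate))
        return cls(np.zeros((n_channels, n)), sample_rate)

    @classmethod
    def from_wav(cls, path) -> "AudioClip":
        rate, data = wavfile.read(path)
        data = np.asarray(data)
        if data.dtype == np.int16:
            data = data / 32768.0
        elif data.dtype == np.int32:
            data = data / 2147483648.0
        else:
            data = data.astype(np.float64)
        if data.ndim == 2:           # wavfile stores (n_samples, n_channels)
            data = data.T
        return cls(data, int(rate))

    def to_wav(self, path, dtype: str = "float32") -> None:
        data = self.samples.T
        if dtype == "int16":
            data = np.clip(data, -1.0, 1.0)
            data = (data * 32767).astype(np.int16)
        else:
            data = data.astype(np.float32)
        wavfile.write(path, self.sample_rate, np.squeeze(data))


@dataclass
class CochleaConfig:
    n_filters: int = 40
    cf_lo: float = 40.0
    cf_hi: float = 20000.0
    fir_taps: int = 1102          # ~25 ms at 44.1 kHz
    compression_exponent: float = 0.3
    lp_cutoff: float = 4000.0     # nominal band edge of the output envelope
    out_rate: int = 10000
    kaiser_width: int = 64        # half-width of the sinc, in zero crossings
    kaiser_rolloff: float = 0.94759
    kaiser_beta: float = 14.76965
    crop_seconds: float = 2.0
    dtype: str = "float32"        # "float64" for strict numerical checks

    def __post_init__(self):
        if not (0 < self.cf_lo < self.cf_hi):
            raise ValueError("require 0 < cf_lo < cf_hi")
        if self.out_rate < 2 * self.effective_cutoff():
            raise ValueError("out_rate must be at least twice the low-pass cutoff")

    def effective_cutoff(self) -> float:
        """Anti-alias cutoff actually used by the resampler: the roll-off
        fraction of the output Nyquist (the nominal lp_cutoff is descriptive)."""
        return self.kaiser_rolloff * self.out_rate / 2.0


@dataclass
class FeatureMap:
    """3-D activation array (channels x frequency x time) between stages."""

    values: np.ndarray
    stage_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 3:
            raise ValueError("FeatureMap values must be (C, F, T)")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite activation values")
        self.values = v

    @property
    def shape(self):
        return self.values.shape

    def save(self, path) -> None:
        np.savez(path, values=self.values, stage_id=self.stage_id)

    @classmethod
    def load(cls, path) -> "FeatureMap":
        with np.load(path, allow_pickle=False) as z:
            return cls(values=z["values"], stage_id=str(z["stage_id"]))


def erb_center_frequencies(n: int, lo: float, hi: float) -> np.ndarray:
    """`n` centre frequencies uniform on the ERB-number scale on [lo, hi]."""
    if n < 2:
        raise ValueError("need at least 2 filters")
    if not (0 < lo < hi):
        raise ValueError("require 0 < lo < hi")
    cfs = erb_number_inverse(np.linspace(erb_number(lo), erb_number(hi), n))
    cfs[0], cfs[-1] = lo, hi  # pin endpoints against round-off
    return cfs


def gammatone_fir(cf: float, sample_rate: float, taps: int) -> np.ndarray:
    """FIR approximation of a 4th-order gammatone filter at centre `cf`.

    Cosine carrier with zero starting phase; the envelope is t^3 e^{-2 pi b t}
    with b = 1.019 ERB(cf).  Peak magnitude response normalized to unity.
    """
    if cf >= sample_rate / 2:
        raise ValueError("centre frequency at or above Nyquist")
    t = np.arange(taps) / sample_rate
    b = 1.019 * erb_bandwidth(cf)
    h = t**3 * np.exp(-2.0 * math.pi * b * t) * np.cos(2.0 * math.pi * cf * t)
    # unit peak gain at cf
    w = np.exp(-2j * math.pi * cf * np.arange(taps) / sample_rate)
    h /= np.abs(np.dot(h, w))
    return h


def _resample_kernel(up: int, down: int, width: int, rolloff: float,
                     beta: float) -> np.ndarray:
    """Kaiser-windowed sinc for polyphase resampling at ratio up/down.

    Operates at the virtual rate fs*up; cutoff is `rolloff` times the
    output Nyquist. Unit DC gain after the `up` scaling applied by upfirdn.
    """
    m = max(up, down)
    half = width * m
    n = np.arange(-half, half + 1)
    fc = rolloff / (2.0 * m)       # cycles per virtual sample
    h = 2.0 * fc * np.sinc(2.0 * fc * n)
    h *= np.kaiser(2 * half + 1, beta)
    # unit passband gain: normalize DC to 1, then scale by `up` because only
    # every up-th virtual input sample is non-zero in the polyphase scheme
    return h * (up / h.sum())


_kernel_cache = lru_cache(maxsize=8)(_resample_kernel)


@lru_cache(maxsize=8)
def _bank_fft(n_filters: int, cf_lo: float, cf_hi: float, taps: int,
              fs: int, nfft: int, dtype: str):
    cfs = erb_center_frequencies(n_filters, cf_lo, cf_hi)
    bank = np.stack([gammatone_fir(cf, fs, taps) for cf in cfs])
    return cfs, rfft(bank.astype(dtype), nfft, axis=-1)


def _lowpass_resample(x: np.ndarray, fs: int, cfg: CochleaConfig) -> np.ndarray:
    """Low-pass + downsample the last axis from fs to cfg.out_rate."""
    g = math.gcd(int(fs), int(cfg.out_rate))
    up, down = cfg.out_rate // g, int(fs) // g
    h = _kernel_cache(up, down, cfg.kaiser_width, cfg.kaiser_rolloff,
                      cfg.kaiser_beta)
    y = upfirdn(h.astype(x.dtype), x, up=up, down=down, axis=-1)
    # trim the filter's group delay so output index m maps to t = m/out_rate
    delay = (len(h) - 1) // 2
    start = delay // down
    n_out = int(x.shape[-1] * up / down)
    return y[..., start:start + n_out]


def cochleagram(clip: AudioClip, cfg: CochleaConfig | None = None) -> FeatureMap:
    """Full peripheral pipeline: filterbank -> half-wave rectify -> power
    compression -> low-pass/downsample -> centre crop.

    Output shape (n_ears, n_filters, crop_seconds*out_rate); defaults give
    (2, 40, 20000) for a 2.5-s stereo clip.
    """
    cfg = cfg or CochleaConfig()
    if clip.duration + 1e-9 < cfg.crop_seconds:
        raise ValueError(
            f"input ({clip.duration:.3f}s) shorter than crop window "
            f"({cfg.crop_seconds}s)")
    fs = clip.sample_rate
    n = clip.n_samples
    nfft = next_fast_len(n + cfg.fir_taps - 1)
    cfs, bank_f = _bank_fft(cfg.n_filters, cfg.cf_lo, cfg.cf_hi,
                            cfg.fir_taps, fs, nfft, cfg.dtype)
    lead = (cfg.fir_taps - 1) // 2  # 'same' alignment
    ears = []
    for ch in range(clip.n_channels):
        xf = rfft(clip.samples[ch].astype(cfg.dtype), nfft)
        sub = irfft(xf[None, :] * bank_f, nfft, axis=-1)[:, lead:lead + n]
        sub = np.maximum(sub, 0.0) ** cfg.compression_exponent
        env = _lowpass_resample(sub, fs, cfg)
        ears.append(env)
    out = np.stack(ears)                      # (C, F, T_full)
    out = np.maximum(out, 0.0)                # resampler ripple can dip below 0
    t_keep = int(round(cfg.crop_seconds * cfg.out_rate))
    lead = (out.shape[-1] - t_keep) // 2
    out = out[..., lead:lead + t_keep]
    return FeatureMap(out.astype(cfg.dtype), stage_id="cochleagram",
                      meta={"center_frequencies": cfs, "out_rate": cfg.out_rate})
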