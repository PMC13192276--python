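"""Spatial rendering and spatial-stimulus construction.

The binaural renderer is parametric and anechoic: an interaural time
difference from a spherical-head (Woodworth) delay model, an
energy-preserving frequency-dependent interaural level difference, an
elevation-dependent monaural spectral notch and 1/distance level
scaling.  It deliberately preserves the cue structure the spatial
experiments rest on (interaural cues for azimuth, monaural spectral
cues for elevation) without simulating reflections; externally
measured binaural impulse responses can be convolved instead via
`render_with_brir`.

Room/location-grid sampling reproduces the training-distribution
geometry exactly: shoebox rooms with log-uniform dimensions and
1,584-point source grids (72 azimuths x 11 elevations x 2 distances).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve, firwin2

from .cochlea import AudioClip

__all__ = [
    "SourcePosition", "RoomSpec", "RendererConfig", "location_grid",
    "sample_room", "render_binaural", "precedence_pair", "woodworth_itd",
    "render_with_brir", "grid_to_csv",
]

SPEED_OF_SOUND = 343.0   # m/s

AZIMUTHS = np.arange(-175.0, 185.0, 5.0)       # 72 values in (-180, 180]
ELEVATIONS = np.linspace(-40.0, 60.0, 11)      # 11 values (simulator guess)
FIXED_DISTANCE = 1.4                           # m


@dataclass(frozen=True)
class SourcePosition:
    azimuth: float           # degrees, 0 = front, positive right
    elevation: float = 0.0   # degrees
    distance: float = FIXED_DISTANCE

    def __post_init__(self):
        if not (-180.0 < self.azimuth <= 180.0 + 1e-9):
            raise ValueError("azimuth must lie in (-180, 180]")
        if self.distance <= 0:
            raise ValueError("distance must be positive")


@dataclass
class RoomSpec:
    length: float
    width: float
    height: float
    listener: tuple          # (x, y, z) metres

    MIN_WALL = 1.45
    MAX_HEAD_HEIGHT = 2.0

    def __post_init__(self):
        x, y, z = self.listener
        if min(x, self.length - x, y, self.width - y) < self.MIN_WALL - 1e-9:
            raise ValueError("listener closer than 1.45 m to a wall")
        if z > self.MAX_HEAD_HEIGHT + 1e-9:
            raise ValueError("listener head above 2 m")

    def min_wall_distance(self) -> float:
        x, y, _ = self.listener
        return min(x, self.length - x, y, self.width - y)


@dataclass
class RendererConfig:
    head_radius: float = 0.0875          # m (Woodworth model)
    ild_max_db: float = 20.0             # broadband ILD at 90 deg, high freq
    ild_freq_exponent: float = 0.8       # ILD growth with frequency
    notch_depth_db: float = 12.0
    notch_base_hz: float = 6000.0        # notch centre at 0 deg elevation
    notch_hz_per_deg: float = 60.0
    fir_taps: int = 257
    ref_distance: float = FIXED_DISTANCE


def sample_room(rng: np.random.Generator) -> RoomSpec:
    """Shoebox room: length/width log-uniform on [3, 30] m, height on
    [2.2, 10] m; listener uniform, >= 1.45 m from every wall, head <= 2 m."""
    def logu(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    length, width = logu(3, 30), logu(3, 30)
    height = logu(2.2, 10)
    m = RoomSpec.MIN_WALL
    x = rng.uniform(m, length - m)
    y = rng.uniform(m, width - m)
    z = rng.uniform(0.0, min(RoomSpec.MAX_HEAD_HEIGHT, height))
    return RoomSpec(length, width, height, (float(x), float(y), float(z)))


def location_grid(room: RoomSpec, rng: np.random.Generator) -> list:
    """1,584 source positions: 72 azimuths x 11 elevations x 2 distances.

    One distance is always 1.4 m; the other is sampled per
    azimuth-elevation pair, uniform on (1 m, wall distance - 0.1 m).
    """
    wall = room.min_wall_distance()
    hi = wall - 0.1
    if hi <= 1.0:
        raise ValueError("room too small for the sampled-distance bound")
    grid = []
    for az in AZIMUTHS:
        for el in ELEVATIONS:
            d2 = float(rng.uniform(1.0, hi))
            grid.append(SourcePosition(float(az), float(el), FIXED_DISTANCE))
            grid.append(SourcePosition(float(az), float(el), d2))
    return grid


def grid_to_csv(grid: list, path) -> None:
    import pandas as pd
    pd.DataFrame([{"azimuth": p.azimuth, "elevation": p.elevation,
                   "distance": p.distance} for p in grid]).to_csv(
        path, index=False)


def woodworth_itd(azimuth_deg: float, head_radius: float = 0.0875) -> float:
    """Spherical-head ITD in seconds (positive = right ear leads)."""
    az = np.deg2rad(azimuth_deg)
    # fold rear hemifield onto the front (cone of confusion)
    inc = np.arcsin(np.sin(az))
    return float(head_radius / SPEED_OF_SOUND * (inc + np.sin(inc)))


def _ear_filters(pos: SourcePosition, cfg: RendererConfig, fs: int):
    """Linear-phase FIR magnitude shaping per ear.

    ILD is energy-preserving per frequency: near-ear gain sqrt(1+s),
    far-ear sqrt(1-s) with s = sin|azimuth| * w(f), so that for
    symmetrically placed sources the per-ear energy sum is independent
    of the offset.  Elevation adds an identical spectral notch to both
    ears whose centre frequency moves with elevation.
    """
    ny = fs / 2
    f = np.linspace(0.0, ny, 128)
    w = np.clip((f / 8000.0) ** cfg.ild_freq_exponent, 0.0, 1.0)
    s_max = 1.0 - 10 ** (-cfg.ild_max_db / 10.0)   # caps ILD at ild_max_db
    s = np.sin(np.abs(np.deg2rad(pos.azimuth))) * w * s_max
    near = np.sqrt(1.0 + s)
    far = np.sqrt(1.0 - s)
    notch_fc = cfg.notch_base_hz + cfg.notch_hz_per_deg * pos.elevation
    notch = 1.0 - (1.0 - 10 ** (-cfg.notch_depth_db / 20.0)) * np.exp(
        -0.5 * ((f - notch_fc) / (0.15 * notch_fc)) ** 2)
    near *= notch
    far *= notch
    fn = f / ny
    h_near = firwin2(cfg.fir_taps, fn, near)
    h_far = firwin2(cfg.fir_taps, fn, far)
    if pos.azimuth >= 0:     # source on the right: right ear is near
        return h_far, h_near
    return h_near, h_far


def render_binaural(clip: AudioClip, pos: SourcePosition,
                    cfg: RendererConfig | None = None) -> AudioClip:
    """Render a mono clip to stereo at a source position.

    Deterministic and linear; a front-centre source at 0 deg elevation
    yields identical left/right channels.
    """
    cfg = cfg or RendererConfig()
    if clip.n_channels != 1:
        raise ValueError("render_binaural expects a mono clip")
    fs = clip.sample_rate
    x = clip.samples[0]
    hl, hr = _ear_filters(pos, cfg, fs)
    left = fftconvolve(x, hl, mode="full")[: len(x) + (cfg.fir_taps - 1) // 2]
    right = fftconvolve(x, hr, mode="full")[: len(x) + (cfg.fir_taps - 1) // 2]
    gd = (cfg.fir_taps - 1) // 2
    left, right = left[gd:], right[gd:]
    itd = woodworth_itd(pos.azimuth, cfg.head_radius)
    lag = int(round(abs(itd) * fs))
    if lag > 0:
        if itd > 0:      # right leads; delay left
            left = np.concatenate([np.zeros(lag), left[:-lag] if lag else left])
        else:
            right = np.concatenate([np.zeros(lag), right[:-lag]])
    gain = cfg.ref_distance / pos.distance
    return AudioClip(np.stack([left, right]) * gain, fs)


def render_with_brir(clip: AudioClip, brir: np.ndarray,
                     sample_rate: int | None = None) -> AudioClip:
    """Convolve a mono clip with an externally supplied (2, n) binaural
    impulse response (pluggable alternative to the parametric renderer)."""
    if clip.n_channels != 1:
        raise ValueError("expects a mono clip")
    brir = np.atleast_2d(brir)
    out = np.stack([fftconvolve(clip.samples[0], h)[: clip.n_samples]
                    for h in brir])
    return AudioClip(out, sample_rate or clip.sample_rate)


def precedence_pair(distractor: AudioClip, lead_pos: SourcePosition,
                    lag_pos: SourcePosition, delay_s: float = 0.004,
                    cfg: RendererConfig | None = None) -> AudioClip:
    """Lead-lag pair for illusory spatial separation.

    The distractor is rendered at the lead position; a copy zero-padded
    by round(delay_s * fs) samples is rendered at the lag position; the
    two binaural signals are summed per channel.
    """
    if delay_s < 0:
        raise ValueError("delay must be non-negative")
    fs = distractor.sample_rate
    pad = int(round(delay_s * fs))
    lead = render_binaural(distractor, lead_pos, cfg)
    delayed = AudioClip(
        np.concatenate([np.zeros((1, pad)), distractor.samples], axis=1)[:, :distractor.n_samples],
        fs)
    lag = render_binaural(delayed, lag_pos, cfg)
    return AudioClip(lead.samples + lag.samples, fs)
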