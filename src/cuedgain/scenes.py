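"""Scene sampling, augmentation, mixing and dataset assembly.

Replicates the statistical structure of the training distribution:
1-6 distractors per scene with a uniform speech/non-speech split,
distractor levels spanning a 20-dB range, SNR uniform on [-10, 10] dB,
50% of scenes with distractors colocated with the target, and 10%
single-talker examples with a silent cue.  Cue and mixture are
RMS-normalized to 0.02; clips are generated at 2.5 s (the cochlear
stage later crops the middle 2 s).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfilt

from .cochlea import AudioClip
from .spatial import RendererConfig, SourcePosition, render_binaural
from .voicesynth import Catalog, noise_texture, synth_utterance

__all__ = [
    "SceneConfig", "TrainingExample", "sample_scene_config", "augment",
    "mix", "realize_scene", "build_dataset", "DistractorSpec",
]

CLIP_SECONDS = 2.5
TARGET_RMS = 0.02
SNR_RANGE = (-10.0, 10.0)
LEVEL_OFFSET_RANGE = (-10.0, 10.0)    # 20-dB distractor level range
SILENT_CUE_PROB = 0.1
COLOCATED_PROB = 0.5
BANDPASS_PROB = 0.5


@dataclass
class DistractorSpec:
    kind: str                      # "voice" or "texture"
    source_id: int                 # voice_id or texture_id
    word_ids: tuple = ()           # for voice distractors
    level_offset_db: float = 0.0
    position: SourcePosition = None


@dataclass
class SceneConfig:
    """Full recipe for one training/evaluation example."""

    target_voice: int
    target_words: tuple            # word ids; middle one is the label
    cue_words: tuple               # same voice, different middle word
    position: SourcePosition
    distractors: list              # list[DistractorSpec]
    snr_db: float
    silent_cue: bool = False
    colocated: bool = False
    bandpass_branch: str = "none"  # "cue" | "target" | "none"
    bandpass_params: tuple = ()
    time_shift_s: float = 0.0
    seed: int = 0
    diotic: bool = False

    @property
    def label(self) -> int:
        return self.target_words[len(self.target_words) // 2]


@dataclass
class TrainingExample:
    cue: AudioClip
    mixture: AudioClip
    label: int
    config: SceneConfig = None


def _word_sequence(catalog: Catalog, rng: np.random.Generator,
                   exclude_middle: int | None = None) -> tuple:
    n_words = int(CLIP_SECONDS // catalog.words[0].duration)
    ids = rng.integers(0, catalog.vocab, size=n_words)
    if exclude_middle is not None:
        while ids[n_words // 2] == exclude_middle:
            ids[n_words // 2] = rng.integers(0, catalog.vocab)
    return tuple(int(i) for i in ids)


def sample_scene_config(catalog: Catalog, rng: np.random.Generator,
                        grid: list | None = None,
                        diotic: bool = False) -> SceneConfig:
    """Seven-step scene sampling procedure over a synthetic catalog."""
    if len(catalog.voices) < 2 or len(catalog.textures) < 1:
        raise ValueError("catalog needs >= 2 voices and >= 1 noise texture")
    tv = int(rng.integers(0, len(catalog.voices)))
    t_words = _word_sequence(catalog, rng)
    c_words = _word_sequence(catalog, rng, exclude_middle=t_words[len(t_words) // 2])

    def sample_pos():
        if grid:
            return grid[int(rng.integers(0, len(grid)))]
        return SourcePosition(float(rng.uniform(-175, 180)),
                              float(rng.choice(np.linspace(-40, 60, 11))))

    pos = sample_pos()
    if rng.random() < SILENT_CUE_PROB:
        return SceneConfig(target_voice=tv, target_words=t_words,
                           cue_words=c_words, position=pos, distractors=[],
                           snr_db=np.inf, silent_cue=True, colocated=True,
                           seed=int(rng.integers(2**31)), diotic=diotic)
    n_d = int(rng.integers(1, 7))
    n_speech = int(rng.integers(0, n_d + 1))
    colocated = bool(rng.random() < COLOCATED_PROB)
    others = [v.voice_id for v in catalog.voices if v.voice_id != tv]
    distractors = []
    for i in range(n_d):
        d_pos = pos if colocated else sample_pos()
        lvl = float(rng.uniform(*LEVEL_OFFSET_RANGE))
        if i < n_speech:
            dv = int(rng.choice(others))
            d_words = _word_sequence(catalog, rng,
                                     exclude_middle=t_words[len(t_words) // 2])
            distractors.append(DistractorSpec("voice", dv, d_words, lvl, d_pos))
        else:
            tx = int(rng.choice(catalog.textures))
            distractors.append(DistractorSpec("texture", tx, (), lvl, d_pos))
    snr = float(rng.uniform(*SNR_RANGE))
    bp_branch, bp_params, shift = "none", (), 0.0
    if rng.random() < BANDPASS_PROB:
        bp_branch = "cue" if rng.random() < 0.5 else "target"
        bp_params = (float(rng.uniform(40.0, 400.0)),
                     float(rng.uniform(4000.0, 16000.0)),
                     int(rng.integers(1, 5)))
    word_dur = catalog.words[0].duration
    # shift bounded so the labelled word still overlaps the clip midpoint
    shift = float(rng.uniform(0.0, 0.5) * word_dur) * (1 if rng.random() < 0.5 else -1)
    return SceneConfig(target_voice=tv, target_words=t_words,
                       cue_words=c_words, position=pos,
                       distractors=distractors, snr_db=snr,
                       colocated=colocated, bandpass_branch=bp_branch,
                       bandpass_params=bp_params, time_shift_s=shift,
                       seed=int(rng.integers(2**31)), diotic=diotic)


def _bandpass(clip: AudioClip, lo: float, hi: float, order: int) -> AudioClip:
    ny = clip.sample_rate / 2
    sos = butter(order, [lo / ny, min(hi / ny, 0.99)], btype="bandpass",
                 output="sos")
    return AudioClip(sosfilt(sos, clip.samples, axis=-1), clip.sample_rate)


def _time_shift(clip: AudioClip, shift_s: float) -> AudioClip:
    n = clip.n_samples
    k = int(round(shift_s * clip.sample_rate))
    out = np.zeros_like(clip.samples)
    if k >= 0:
        out[:, k:] = clip.samples[:, :n - k] if k else clip.samples
    else:
        out[:, :n + k] = clip.samples[:, -k:]
    return AudioClip(out, clip.sample_rate)


def augment(target: AudioClip, cue: AudioClip, word_window: tuple,
            cfg: SceneConfig) -> tuple:
    """Apply the sampled bandpass (to exactly one of cue/target) and the
    target time shift, re-checking the midpoint-overlap constraint."""
    if cfg.bandpass_branch == "cue":
        cue = _bandpass(cue, *cfg.bandpass_params)
    elif cfg.bandpass_branch == "target":
        target = _bandpass(target, *cfg.bandpass_params)
    shift = cfg.time_shift_s
    onset, offset = word_window
    mid = CLIP_SECONDS / 2.0
    if not (onset + shift <= mid <= offset + shift):
        shift = np.clip(shift, mid - offset, mid - onset)
    if shift != 0.0:
        target = _time_shift(target, shift)
    return target, cue


def mix(target: AudioClip, distractor_sum: AudioClip | None,
        snr_db: float) -> AudioClip:
    """Combine target and summed distractors at the requested SNR (RMS
    over both channels jointly), then RMS-normalize to 0.02."""
    t_rms = target.rms()
    if distractor_sum is None or np.isinf(snr_db):
        return target.normalized(TARGET_RMS)
    if t_rms == 0.0:
        raise ValueError("silent target with finite SNR is undefined")
    if target.samples.shape != distractor_sum.samples.shape:
        raise ValueError("target and distractor shapes differ")
    d_rms = distractor_sum.rms()
    if d_rms == 0.0:
        return target.normalized(TARGET_RMS)
    scale = t_rms / d_rms / (10.0 ** (snr_db / 20.0))
    mixture = AudioClip(target.samples + scale * distractor_sum.samples,
                        target.sample_rate)
    return mixture.normalized(TARGET_RMS)


def _render(clip: AudioClip, pos: SourcePosition, diotic: bool,
            renderer: RendererConfig) -> AudioClip:
    if diotic:
        return clip.diotic()
    return render_binaural(clip, pos, renderer)


def realize_scene(cfg: SceneConfig, catalog: Catalog,
                  renderer: RendererConfig | None = None) -> TrainingExample:
    """Synthesize, spatialize, augment and mix one scene; deterministic
    given cfg.seed."""
    renderer = renderer or RendererConfig()
    rng = np.random.default_rng(cfg.seed)
    voice = catalog.voices[cfg.target_voice]
    words = [catalog.words[i] for i in cfg.target_words]
    target_mono, tr = synth_utterance(voice, words, CLIP_SECONDS, rng)
    mid_word = tr[len(tr) // 2]
    if cfg.silent_cue:
        cue_mono = AudioClip.silence(CLIP_SECONDS,
                                     target_mono.sample_rate)
    else:
        cue_words = [catalog.words[i] for i in cfg.cue_words]
        cue_mono, _ = synth_utterance(voice, cue_words, CLIP_SECONDS, rng)
    target_mono, cue_mono = augment(
        target_mono, cue_mono, (mid_word["onset"], mid_word["offset"]), cfg)
    target = _render(target_mono, cfg.position, cfg.diotic, renderer)
    if cfg.silent_cue:
        cue = AudioClip(np.zeros_like(target.samples), target.sample_rate)
    else:
        cue = _render(cue_mono, cfg.position, cfg.diotic, renderer).normalized(
            TARGET_RMS)
    d_sum = None
    if cfg.distractors:
        acc = np.zeros_like(target.samples)
        for d in cfg.distractors:
            if d.kind == "voice":
                dv = catalog.voices[d.source_id]
                d_words = [catalog.words[i] for i in d.word_ids]
                mono, _ = synth_utterance(dv, d_words, CLIP_SECONDS, rng)
            else:
                mono = noise_texture(d.source_id, CLIP_SECONDS, rng)
            mono = mono.normalized(TARGET_RMS * 10 ** (d.level_offset_db / 20.0))
            acc += _render(mono, d.position, cfg.diotic, renderer).samples
        d_sum = AudioClip(acc, target.sample_rate)
    mixture = mix(target, d_sum, cfg.snr_db)
    return TrainingExample(cue=cue, mixture=mixture, label=cfg.label,
                           config=cfg)


def build_dataset(n_examples: int, catalog: Catalog, seed: int,
                  out_dir: str | None = None,
                  grid: list | None = None, diotic: bool = False,
                  renderer: RendererConfig | None = None):
    """Sample and realize `n_examples` scenes; optionally write WAV pairs
    plus a manifest CSV.  Fully reproducible from (catalog, seed)."""
    rng = np.random.default_rng(seed)
    rows, examples = [], []
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
    for i in range(n_examples):
        cfg = sample_scene_config(catalog, rng, grid=grid, diotic=diotic)
        ex = realize_scene(cfg, catalog, renderer)
        examples.append(ex)
        row = {"id": i, "label": ex.label,
               "n_distractors": len(cfg.distractors),
               "colocated": cfg.colocated, "silent_cue": cfg.silent_cue,
               "snr_db": cfg.snr_db, "seed": cfg.seed}
        if out_dir:
            cue_path = os.path.join(out_dir, f"ex{i:05d}_cue.wav")
            mix_path = os.path.join(out_dir, f"ex{i:05d}_mix.wav")
            ex.cue.to_wav(cue_path)
            ex.mixture.to_wav(mix_path)
            row.update(cue_path=cue_path, mix_path=mix_path)
        rows.append(row)
    manifest = pd.DataFrame(rows)
    if out_dir:
        manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return examples, manifest
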