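"""Desk-scale cocktail-party benchmark.

A small, fully synthetic version of the cued word-recognition task:
8 words, 4 voices (2 per f0 group), two-talker mixtures presented
diotically, with 10% silent-cue single-talker examples.  A 3-block
feature-gain model on a reduced (250-Hz frame rate) cochleagram is
trained from scratch and probed for (a) cued-word accuracy at 0 dB,
(b) the cue-swap selection property and (c) the stage-of-selection
correlation gap against a random-weight control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .attention import AttentionModel, ModelVariant
from .cochlea import AudioClip, CochleaConfig, cochleagram
from .evaluation import stage_selection
from .netblocks import mini_architecture
from .scenes import CLIP_SECONDS, TARGET_RMS, mix
from .spatial import SourcePosition, render_binaural
from .training import TrainConfig, train
from .voicesynth import Catalog, synth_utterance

__all__ = ["MiniBenchConfig", "mini_cochlea_config", "make_mini_dataset",
           "train_mini_model", "eval_cue_swap", "stage_gap",
           "run_mini_benchmark"]


@dataclass
class MiniBenchConfig:
    n_voices: int = 4
    n_words: int = 8
    n_train: int = 320
    n_val: int = 40
    n_eval: int = 96
    n_quads: int = 24
    pool_per_voice: int = 64          # reusable utterances per voice
    silent_cue_prob: float = 0.1
    train_snr_range: tuple = (-10.0, 10.0)
    eval_snr_db: float = 0.0
    seed: int = 0             # evaluation draws: held-out trials, quads,
                              # random-weight control
    protocol_seed: int = 0    # fixed benchmark protocol: materials, model
                              # init, batch order (like a hyperparameter)
    gain_init_theta1: float = 0.5    # initial lower asymptote at calibration
    train: TrainConfig = field(default_factory=lambda: TrainConfig(
        learning_rate=2e-3, batch_size=32, max_epochs=30, patience=8))


def mini_cochlea_config() -> CochleaConfig:
    """Reduced cochleagram: 24 ERB channels, 250-Hz output frame rate,
    shorter Kaiser sinc.

    Envelope information above ~118 Hz is discarded, so voice identity is
    carried by the spectral excitation pattern rather than periodicity.
    """
    return CochleaConfig(n_filters=24, out_rate=250, lp_cutoff=118.0,
                        kaiser_width=8)


class UtterancePool:
    """Reusable synthesized utterances (each clip appears in several
    scenes, mirroring the target-clip reuse of the full-scale training
    recipe), with cached diotic cue cochleagrams."""

    def __init__(self, catalog: Catalog, per_voice: int, coch: CochleaConfig,
                 seed: int):
        from .scenes import _word_sequence
        rng = np.random.default_rng(seed)
        self.coch = coch
        self.entries = []                 # (voice_id, words, mono clip)
        for v in catalog.voices:
            for _ in range(per_voice):
                words = _word_sequence(catalog, rng)
                clip, _ = synth_utterance(
                    v, [catalog.words[i] for i in words], CLIP_SECONDS,
                    np.random.default_rng(rng.integers(2**31)))
                self.entries.append((v.voice_id, words, clip))
        self._cue_cache = {}

    def middle(self, idx: int) -> int:
        words = self.entries[idx][1]
        return words[len(words) // 2]

    def pick(self, rng, voice_id=None, exclude_middle=None,
             not_voice=None) -> int:
        cands = [i for i, (v, w, _) in enumerate(self.entries)
                 if (voice_id is None or v == voice_id)
                 and (not_voice is None or v != not_voice)
                 and (exclude_middle is None
                      or w[len(w) // 2] != exclude_middle)]
        return int(rng.choice(cands))

    def cue_coch(self, idx: int) -> np.ndarray:
        if idx not in self._cue_cache:
            clip = self.entries[idx][2].diotic().normalized(TARGET_RMS)
            self._cue_cache[idx] = cochleagram(clip, self.coch).values
        return self._cue_cache[idx]


def make_mini_dataset(pool: UtterancePool, n: int, rng: np.random.Generator,
                      cfg: MiniBenchConfig) -> list:
    """(cue_cochleagram, mixture_cochleagram, label) triples.

    Two-talker diotic scenes at SNR ~ U(train_snr_range), with
    `silent_cue_prob` single-talker silent-cue examples.
    """
    data = []
    zero_cue = None
    for _ in range(n):
        ti = pool.pick(rng)
        tv, _, t_clip = pool.entries[ti]
        label = pool.middle(ti)
        target = t_clip.diotic()
        if rng.random() < cfg.silent_cue_prob:
            mixture = mix(target, None, np.inf)
            if zero_cue is None:
                zero_cue = np.zeros_like(pool.cue_coch(ti))
            data.append((zero_cue, cochleagram(mixture, pool.coch).values,
                         label))
            continue
        ci = pool.pick(rng, voice_id=tv, exclude_middle=label)
        di = pool.pick(rng, not_voice=tv, exclude_middle=label)
        distr = pool.entries[di][2].diotic()
        snr = float(rng.uniform(*cfg.train_snr_range))
        mixture = mix(target, distr.normalized(TARGET_RMS), snr)
        data.append((pool.cue_coch(ci),
                     cochleagram(mixture, pool.coch).values, label))
    return data


def train_mini_model(cfg: MiniBenchConfig | None = None,
                     variant: ModelVariant = ModelVariant.FEATURE_GAIN,
                     verbose: bool = False):
    """Build catalog + data, train a mini model; returns
    (model, catalog, history, coch_cfg)."""
    cfg = cfg or MiniBenchConfig()
    coch = mini_cochlea_config()
    # the training protocol (materials, model init, batch order) is a
    # fixed instrument, like a published experiment's stimulus lists and
    # its released trained model; cfg.seed varies the held-out evaluation
    catalog = Catalog.build(n_voices=cfg.n_voices, n_words=cfg.n_words,
                            seed=cfg.protocol_seed)
    pool = UtterancePool(catalog, cfg.pool_per_voice, coch,
                         cfg.protocol_seed + 5)
    rng = np.random.default_rng(cfg.protocol_seed + 1)
    train_data = make_mini_dataset(pool, cfg.n_train, rng, cfg)
    val_data = make_mini_dataset(pool, cfg.n_val, rng, cfg)
    in_ch = 4 if ModelVariant(variant) == ModelVariant.BASELINE else 2
    arch = mini_architecture(vocab=cfg.n_words, in_channels=in_ch,
                             in_freq=coch.n_filters,
                             in_time=int(coch.crop_seconds * coch.out_rate))
    model = AttentionModel(arch, variant=variant, cochlea_cfg=coch,
                           seed=cfg.protocol_seed)
    if model.sites:
        # calibrate gain sigmoids to the cue-memory statistics of a few
        # training cues so gating has contrast from the first step
        sample = np.stack([d[0] for d in train_data[:16]
                           if d[0].any()][:8])
        model.calibrate_gains(sample, theta1=cfg.gain_init_theta1)
    tc = cfg.train
    tc.seed = cfg.protocol_seed
    model, history = train(model, train_data, val_data, tc, verbose=verbose)
    return model, catalog, history, coch


def _eval_trial(catalog: Catalog, rng: np.random.Generator, snr_db: float,
                same_sex: bool | None = None):
    """One held-out two-talker trial with both talkers' cues.

    Returns (cue_A, cue_B, mixture, label_A, label_B) where A is the
    target stream and B the distractor stream.  `same_sex` stratifies
    the talker pairing (None = unconstrained).
    """
    from .scenes import _word_sequence
    va = int(rng.integers(0, len(catalog.voices)))
    sex_a = catalog.voices[va].sex_tag
    cands = [v.voice_id for v in catalog.voices if v.voice_id != va
             and (same_sex is None or (v.sex_tag == sex_a) == same_sex)]
    if not cands:
        cands = [v.voice_id for v in catalog.voices if v.voice_id != va]
    vb = int(rng.choice(cands))
    wa = _word_sequence(catalog, rng)
    wb = _word_sequence(catalog, rng, exclude_middle=wa[len(wa) // 2])
    ca = _word_sequence(catalog, rng, exclude_middle=wa[len(wa) // 2])
    cb = _word_sequence(catalog, rng, exclude_middle=wb[len(wb) // 2])
    srng = np.random.default_rng(rng.integers(2**31))
    A, _ = synth_utterance(catalog.voices[va],
                           [catalog.words[i] for i in wa], CLIP_SECONDS, srng)
    B, _ = synth_utterance(catalog.voices[vb],
                           [catalog.words[i] for i in wb], CLIP_SECONDS, srng)
    cueA, _ = synth_utterance(catalog.voices[va],
                              [catalog.words[i] for i in ca], CLIP_SECONDS,
                              srng)
    cueB, _ = synth_utterance(catalog.voices[vb],
                              [catalog.words[i] for i in cb], CLIP_SECONDS,
                              srng)
    mixture = mix(A.diotic(), AudioClip(B.diotic().samples *
                                        (TARGET_RMS / B.diotic().rms())),
                  snr_db)
    return (cueA.diotic().normalized(TARGET_RMS),
            cueB.diotic().normalized(TARGET_RMS),
            mixture, wa[len(wa) // 2], wb[len(wb) // 2])


def eval_cue_swap(model: AttentionModel, catalog: Catalog,
                  cfg: MiniBenchConfig, coch: CochleaConfig) -> dict:
    """Accuracy with the matching cue, and the cue-swap selection test."""
    rng = np.random.default_rng(cfg.seed + 9)
    n_correct, n_swap, n = 0, 0, 0
    for i in range(cfg.n_eval):
        # stratified talker pairing: half same-sex, half different-sex
        cueA, cueB, mixture, la, lb = _eval_trial(catalog, rng,
                                                  cfg.eval_snr_db,
                                                  same_sex=bool(i % 2))
        pa = model.attend_clips(cueA, mixture).argmax()
        pb = model.attend_clips(cueB, mixture).argmax()
        n_correct += int(pa == la)
        n_swap += int(pa == la and pb == lb)
        n += 1
    return {"accuracy": n_correct / n, "swap_fraction": n_swap / n,
            "chance": 1.0 / catalog.vocab, "n_trials": n}


def _stage_quads(catalog: Catalog, cfg: MiniBenchConfig,
                 coch: CochleaConfig, separation_deg: float) -> list:
    """(cue, target, distractor, mixture) cochleagram quads at a given
    azimuthal separation; everything RMS-normalized to 0.02, 0 dB SNR."""
    from .scenes import _word_sequence
    rng = np.random.default_rng(cfg.seed + 17)
    quads = []
    for q in range(cfg.n_quads):
        va = int(rng.integers(0, len(catalog.voices)))
        sex_a = catalog.voices[va].sex_tag
        same = bool(q % 2)      # half same-sex, half different-sex pairs
        cands = [v.voice_id for v in catalog.voices if v.voice_id != va
                 and (v.sex_tag == sex_a) == same]
        if not cands:
            cands = [v.voice_id for v in catalog.voices if v.voice_id != va]
        vb = int(rng.choice(cands))
        wa = _word_sequence(catalog, rng)
        wb = _word_sequence(catalog, rng, exclude_middle=wa[len(wa) // 2])
        ca = _word_sequence(catalog, rng, exclude_middle=wa[len(wa) // 2])
        srng = np.random.default_rng(rng.integers(2**31))
        A, _ = synth_utterance(catalog.voices[va],
                               [catalog.words[i] for i in wa], CLIP_SECONDS,
                               srng)
        B, _ = synth_utterance(catalog.voices[vb],
                               [catalog.words[i] for i in wb], CLIP_SECONDS,
                               srng)
        cue, _ = synth_utterance(catalog.voices[va],
                                 [catalog.words[i] for i in ca], CLIP_SECONDS,
                                 srng)
        half = separation_deg / 2.0
        sign = 1.0 if q % 2 == 0 else -1.0
        pa = SourcePosition(sign * half)
        pb = SourcePosition(-sign * half)
        tgt = render_binaural(A, pa).normalized(TARGET_RMS)
        dis = render_binaural(B, pb).normalized(TARGET_RMS)
        mixture = AudioClip(tgt.samples + dis.samples).normalized(TARGET_RMS)
        cue_r = render_binaural(cue, pa).normalized(TARGET_RMS)
        quads.append(tuple(cochleagram(c, coch).values
                           for c in (cue_r, tgt, dis, mixture)))
    return quads


def stage_gap(model: AttentionModel, catalog: Catalog, cfg: MiniBenchConfig,
              coch: CochleaConfig, separation_deg: float = 90.0) -> dict:
    """Late-stage (final fully connected ReLU) target-vs-distractor
    correlation gap for the given model."""
    quads = _stage_quads(catalog, cfg, coch, separation_deg)
    per_stage = stage_selection(model, quads)
    return {"per_stage": per_stage,
            "late_gap": per_stage["relufc"]["gap"]}


def run_mini_benchmark(cfg: MiniBenchConfig | None = None,
                       verbose: bool = False) -> dict:
    """Full desk-scale benchmark; returns the three headline measures and
    the trained model."""
    cfg = cfg or MiniBenchConfig()
    model, catalog, history, coch = train_mini_model(cfg, verbose=verbose)
    swap = eval_cue_swap(model, catalog, cfg, coch)
    trained_gap = stage_gap(model, catalog, cfg, coch)
    random_model = AttentionModel(model.net.spec,
                                  variant=ModelVariant.FEATURE_GAIN,
                                  cochlea_cfg=coch, seed=cfg.seed + 101)
    random_gap = stage_gap(random_model, catalog, cfg, coch)
    return {
        "accuracy": swap["accuracy"],
        "swap_fraction": swap["swap_fraction"],
        "chance": swap["chance"],
        "late_gap_trained": trained_gap["late_gap"],
        "late_gap_random": random_gap["late_gap"],
        "history": history.to_frame(),
        "model": model,
        "catalog": catalog,
        "cochlea_cfg": coch,
        "stage_profile_trained": trained_gap["per_stage"],
        "stage_profile_random": random_gap["per_stage"],
    }
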