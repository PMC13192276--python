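"""Cue-memory computation, sigmoidal feature gains and the two-pass
forward algorithm, with the architectural variants used for ablation.

The attended forward pass runs the cue through the shared-weight
backbone, time-averages each gated stage's activations into a cue
memory m in R^{C x F}, maps the memory through a per-stage 3-parameter
sigmoid

    g = theta1 + (1 - theta1) / (1 + exp(-theta2 (m - theta3)))

and multiplies every time slice of the mixture's activation at the
same site by the resulting gain field before the next block's
normalization (variants move or restrict the gain sites).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from ._autograd import DTYPE, Tensor, softmax
from .cochlea import AudioClip, CochleaConfig, FeatureMap, cochleagram
from .netblocks import ArchitectureSpec, Network

__all__ = [
    "ModelVariant", "GainParams", "CueMemory", "GainField",
    "AttentionModel", "gain_sites", "gains_from_memory", "apply_gains",
]


class ModelVariant(str, Enum):
    FEATURE_GAIN = "feature_gain"
    BASELINE = "baseline"
    EARLY_ONLY = "early_only"
    LATE_ONLY = "late_only"
    GAIN_AFTER_NORM = "gain_after_norm"


@dataclass
class GainParams:
    """One shared sigmoid triple per gain site: bias (lower asymptote),
    slope and threshold.  theta1 is unconstrained."""

    theta1: Tensor
    theta2: Tensor
    theta3: Tensor

    @classmethod
    def init(cls, theta1: float = 0.5, theta2: float = 1.0,
             theta3: float = 0.0) -> "GainParams":
        return cls(Tensor(theta1, requires_grad=True),
                   Tensor(theta2, requires_grad=True),
                   Tensor(theta3, requires_grad=True))

    def parameters(self):
        return [self.theta1, self.theta2, self.theta3]


@dataclass
class CueMemory:
    """Per-stage time-averaged cue activation, shape (C, F)."""

    m: np.ndarray
    site: int


@dataclass
class GainField:
    """Per-stage multiplicative gains, shape (C, F)."""

    g: np.ndarray
    site: int


def gain_sites(variant: ModelVariant, n_blocks: int) -> list:
    """Ordered gain-site indices (0 = cochleagram, i = output of block i)."""
    variant = ModelVariant(variant)
    if variant in (ModelVariant.FEATURE_GAIN, ModelVariant.GAIN_AFTER_NORM):
        return list(range(n_blocks + 1))
    if variant == ModelVariant.EARLY_ONLY:
        return [0]
    if variant == ModelVariant.LATE_ONLY:
        return [n_blocks]
    if variant == ModelVariant.BASELINE:
        return []
    raise ValueError(f"unknown variant {variant}")


def gains_from_memory(m: Tensor | np.ndarray, p: GainParams) -> Tensor:
    """Elementwise g = t1 + (1 - t1) * sigmoid(t2 (m - t3))."""
    m = m if isinstance(m, Tensor) else Tensor(np.asarray(m, DTYPE))
    s = ((m - p.theta3) * p.theta2).sigmoid()
    return p.theta1 + (Tensor(1.0) - p.theta1) * s


def apply_gains(x: FeatureMap, g: np.ndarray) -> FeatureMap:
    """Multiply every time slice of a (C, F, T) map by a (C, F) gain field."""
    g = np.asarray(g)
    if g.shape != x.values.shape[:2]:
        raise ValueError(f"gain shape {g.shape} does not match feature "
                         f"shape {x.values.shape[:2]}")
    return FeatureMap(x.values * g[:, :, None], stage_id=x.stage_id)


class AttentionModel:
    """A backbone network plus per-site gain parameters under a variant.

    Works on cochleagram arrays; `attend_clips` is the waveform-level
    convenience wrapper.  Cue and mixture passes share the backbone
    weights by construction (same Network object).
    """

    def __init__(self, arch: ArchitectureSpec,
                 variant: ModelVariant = ModelVariant.FEATURE_GAIN,
                 cochlea_cfg: CochleaConfig | None = None, seed: int = 0):
        self.variant = ModelVariant(variant)
        if self.variant == ModelVariant.BASELINE and arch.in_channels != 4:
            raise ValueError("baseline variant needs a 4-input-channel "
                             "architecture (cue + mixture stereo pairs)")
        self.net = Network(arch, seed=seed)
        self.cochlea_cfg = cochlea_cfg or CochleaConfig()
        self.sites = gain_sites(self.variant, len(arch.blocks))
        self.gain_params = {s: GainParams.init() for s in self.sites}

    # -- parameters ----------------------------------------------------
    def parameters(self):
        ps = self.net.parameters()
        for s in self.sites:
            ps += self.gain_params[s].parameters()
        return ps

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- cue processing -------------------------------------------------
    def _site_activations(self, x: Tensor) -> dict:
        """Run a plain (ungated) pass, returning {site: activation Tensor}."""
        record = []
        self.net.forward(x, record=record, training=False)
        names = self.net.stage_names()
        acts = dict(zip(names, (t for _, t in record)))
        out = {}
        for s in self.sites:
            key = "cochleagram" if s == 0 else f"block{s}"
            out[s] = acts[key]
        return out

    def compute_cue_memory(self, cue_coch: Tensor) -> dict:
        """Time-averaged cue activation per gain site: {site: (B, C, F)}.

        A silent cue yields an all-zero cochleagram-stage memory.  Stays in
        the autograd graph so gains receive gradients through the cue pass.
        """
        acts = self._site_activations(cue_coch)
        return {s: a.mean(axis=3) for s, a in acts.items()}

    def compute_gains(self, cue_coch: Tensor) -> dict:
        memories = self.compute_cue_memory(cue_coch)
        gains = {}
        for s, m in memories.items():
            g = gains_from_memory(m, self.gain_params[s])
            gains[s] = g.reshape(*g.shape, 1)   # broadcast over time
        return gains

    def calibrate_gains(self, sample_cues: np.ndarray, slope_sigmas: float = 2.0,
                        theta1: float = 0.5) -> None:
        """Data-dependent gain initialization.

        Sets each site's threshold to the mean cue memory and the slope to
        `slope_sigmas` per memory standard deviation, so the sigmoid has
        real contrast over the activation range from the first gradient
        step (a flat sigmoid makes the cue-free solution a strong local
        optimum at small training scales).
        """
        memories = self.compute_cue_memory(Tensor(sample_cues))
        for s, m in memories.items():
            vals = m.data.ravel()
            sd = float(vals.std())
            p = self.gain_params[s]
            p.theta1.data = np.asarray(theta1, DTYPE)
            p.theta2.data = np.asarray(
                slope_sigmas / max(sd, 1e-6), DTYPE)
            p.theta3.data = np.asarray(float(vals.mean()), DTYPE)

    # -- attended forward pass -------------------------------------------
    def forward_attend(self, cue_coch: Tensor, mix_coch: Tensor,
                       training: bool = False,
                       rng: np.random.Generator | None = None,
                       record: list | None = None) -> Tensor:
        """Two-pass attended forward: returns logits (B, V)."""
        if self.variant == ModelVariant.BASELINE:
            # cue and mixture cochleagrams concatenated on the channel axis
            x = Tensor(np.concatenate([mix_coch.data, cue_coch.data], axis=1))
            return self.net.forward(x, training=training, rng=rng,
                                    record=record)
        gains = self.compute_gains(cue_coch)
        return self.net.forward(
            mix_coch, gains=gains,
            gate_after_norm=(self.variant == ModelVariant.GAIN_AFTER_NORM),
            training=training, rng=rng, record=record)

    # -- waveform-level API ----------------------------------------------
    def _coch(self, clip: AudioClip) -> np.ndarray:
        return cochleagram(clip, self.cochlea_cfg).values

    def attend_clips(self, cue: AudioClip, mixture: AudioClip) -> np.ndarray:
        """Probability distribution over the vocabulary for one trial."""
        cue_c = Tensor(self._coch(cue)[None])
        mix_c = Tensor(self._coch(mixture)[None])
        logits = self.forward_attend(cue_c, mix_c, training=False)
        return softmax(logits.data, axis=1)[0]

    # -- checkpointing -----------------------------------------------------
    def save(self, path) -> None:
        arrays = self.net.state_arrays()
        for s in self.sites:
            p = self.gain_params[s]
            arrays[f"gain{s}.theta"] = np.stack(
                [p.theta1.data, p.theta2.data, p.theta3.data])
        arrays["_meta.variant"] = np.array(self.variant.value)
        arrays["_meta.schema"] = np.array(Network.SCHEMA_VERSION)
        np.savez(path, **arrays)

    def load(self, path) -> None:
        with np.load(path, allow_pickle=False) as z:
            variant = str(z["_meta.variant"])
            if variant != self.variant.value:
                raise ValueError(
                    f"checkpoint was trained as '{variant}', model is "
                    f"'{self.variant.value}' (gains are trained jointly; "
                    "variant cannot be overridden at load time)")
            self.net.load_state_arrays({k: z[k] for k in z.files})
            for s in self.sites:
                t = z[f"gain{s}.theta"]
                p = self.gain_params[s]
                p.theta1.data, p.theta2.data, p.theta3.data = (
                    np.asarray(t[0], DTYPE), np.asarray(t[1], DTYPE),
                    np.asarray(t[2], DTYPE))
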