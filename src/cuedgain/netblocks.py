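"""Constituent neural-network operations and architecture assembly.

Each convolutional block is layer-norm -> conv (valid time / same
frequency, stride 1, no bias) -> ReLU -> Hanning weighted-average
pooling.  The classifier head is flatten -> fully connected -> ReLU ->
dropout (p=0.5, training only) -> fully connected -> softmax over the
word vocabulary.  Layer-norm statistics are computed per example over
all (C, F, T) elements, with full-shape learnable scale/shift, which
ties each architecture to a fixed input duration.

Architectures are data-driven (`ArchitectureSpec`); the module ships a
desk-scale 3-block "mini" spec and a deeper paper-scale template.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autograd import (DTYPE, Tensor, conv2d_valid_same, dropout,
                        hann_pool2d, softmax)

__all__ = [
    "BlockSpec", "HeadSpec", "ArchitectureSpec", "Network",
    "LayerNorm", "ConvBlock", "ClassifierHead",
    "hann_kernel", "pool_kernel_size", "mini_architecture",
    "paper_scale_architecture", "propagate_shapes",
]


def pool_kernel_size(stride: int) -> int:
    """Stride-dependent Hanning kernel size: 1 if s=1, else 4s."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    return 1 if stride == 1 else 4 * stride


def hann_kernel(sf: int, st: int) -> np.ndarray:
    """Separable 2-D Hanning window, unit sum (preserves constants)."""
    def w(h):
        if h == 1:
            return np.ones(1)
        return np.hanning(h + 2)[1:-1]  # strictly positive interior
    k = np.outer(w(pool_kernel_size(sf)), w(pool_kernel_size(st)))
    return (k / k.sum()).astype(DTYPE)


@dataclass
class BlockSpec:
    c_out: int
    n_f: int
    n_t: int
    s_f: int = 1
    s_t: int = 1


@dataclass
class HeadSpec:
    fc_dim: int
    vocab: int
    dropout_p: float = 0.5


@dataclass
class ArchitectureSpec:
    """Shape-level description of a full model."""

    in_channels: int
    in_freq: int
    in_time: int
    blocks: list = field(default_factory=list)   # list[BlockSpec]
    head: HeadSpec = None
    name: str = "custom"

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        blocks = [BlockSpec(**b) for b in d["blocks"]]
        head = HeadSpec(**d["head"])
        return cls(in_channels=d.get("in_channels", 2),
                   in_freq=d.get("in_freq", 40),
                   in_time=d["in_time"], blocks=blocks, head=head,
                   name=d.get("name", "custom"))

    def to_dict(self) -> dict:
        return {
            "name": self.name, "in_channels": self.in_channels,
            "in_freq": self.in_freq, "in_time": self.in_time,
            "blocks": [vars(b) for b in self.blocks],
            "head": vars(self.head),
        }

    @classmethod
    def from_yaml(cls, path) -> "ArchitectureSpec":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        import yaml
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def propagate_shapes(spec: ArchitectureSpec) -> list:
    """Symbolic shape bookkeeping from input through every block.

    Returns the (C, F, T) entering each block plus the final block output.
    """
    shapes = [(spec.in_channels, spec.in_freq, spec.in_time)]
    c, f, t = shapes[0]
    for b in spec.blocks:
        t2 = t - b.n_t + 1
        if t2 < 1:
            raise ValueError(f"time axis exhausted in block with n_t={b.n_t}")
        f2, c = f, b.c_out
        hf, ht = pool_kernel_size(b.s_f), pool_kernel_size(b.s_t)
        if hf > f2 or ht > t2:
            raise ValueError("pooling kernel larger than block output")
        f = (f2 - hf) // b.s_f + 1
        t = (t2 - ht) // b.s_t + 1
        shapes.append((c, f, t))
    return shapes


# ---------------------------------------------------------------------
# parameterized stages
# ---------------------------------------------------------------------

class LayerNorm:
    """Per-example normalization over all (C, F, T) feature dimensions
    with full-shape learnable gamma/beta."""

    def __init__(self, shape, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(shape), requires_grad=True)
        self.beta = Tensor(np.zeros(shape), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[1:] != self.gamma.shape:
            raise ValueError(f"layer-norm shape mismatch: {x.shape[1:]} vs "
                             f"{self.gamma.shape}")
        axes = tuple(range(1, x.ndim))
        mu = x.mean(axis=axes, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=axes, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gamma + self.beta

    def parameters(self):
        return [self.gamma, self.beta]


class ConvBlock:
    """norm -> conv -> ReLU -> Hanning pool.

    `gate_after_norm` supports the gain-after-normalization model variant:
    when a gain field is passed to __call__, it multiplies either the block
    input (before the norm; the default, matching gains-then-normalization)
    or the normalized activations.
    """

    def __init__(self, in_shape, spec: BlockSpec, rng: np.random.Generator):
        c_in, f_in, t_in = in_shape
        self.norm = LayerNorm(in_shape)
        fan_in = c_in * spec.n_f * spec.n_t
        w = rng.standard_normal((spec.c_out, c_in, spec.n_f, spec.n_t))
        self.w = Tensor(w * np.sqrt(2.0 / fan_in), requires_grad=True)
        self.kernel = hann_kernel(spec.s_f, spec.s_t)
        self.spec = spec

    def __call__(self, x: Tensor, gain: Tensor | None = None,
                 gate_after_norm: bool = False) -> Tensor:
        if gain is not None and not gate_after_norm:
            x = x * gain
        x = self.norm(x)
        if gain is not None and gate_after_norm:
            x = x * gain
        x = conv2d_valid_same(x, self.w)
        x = x.relu()
        return hann_pool2d(x, self.kernel, self.spec.s_f, self.spec.s_t)

    def parameters(self):
        return self.norm.parameters() + [self.w]


class ClassifierHead:
    """flatten -> affine -> ReLU -> dropout -> affine (logits)."""

    def __init__(self, in_dim: int, spec: HeadSpec, rng: np.random.Generator):
        self.w1 = Tensor(rng.standard_normal((in_dim, spec.fc_dim)) *
                         np.sqrt(2.0 / in_dim), requires_grad=True)
        self.b1 = Tensor(np.zeros(spec.fc_dim), requires_grad=True)
        self.w2 = Tensor(rng.standard_normal((spec.fc_dim, spec.vocab)) *
                         np.sqrt(1.0 / spec.fc_dim), requires_grad=True)
        self.b2 = Tensor(np.zeros(spec.vocab), requires_grad=True)
        self.p = spec.dropout_p
        self.in_dim = in_dim

    def __call__(self, x: Tensor, training: bool = False,
                 rng: np.random.Generator | None = None,
                 record: list | None = None) -> Tensor:
        B = x.shape[0]
        flat_dim = int(np.prod(x.shape[1:]))
        if flat_dim != self.in_dim:
            raise ValueError(f"head expects {self.in_dim} features, got {flat_dim}")
        h = (x.reshape(B, flat_dim) @ self.w1 + self.b1).relu()
        if record is not None:
            record.append(("relufc", h))
        h = dropout(h, self.p, rng or np.random.default_rng(), training)
        return h @ self.w2 + self.b2

    def parameters(self):
        return [self.w1, self.b1, self.w2, self.b2]


class Network:
    """Assembled backbone: cochleagram input -> conv blocks -> head.

    The forward pass optionally records every stage activation (for the
    stage-of-selection analysis) and accepts per-site gain fields (driven
    by the attention module).
    """

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        self.spec = spec
        self.shapes = propagate_shapes(spec)
        rng = np.random.default_rng(seed)
        self.blocks = [ConvBlock(self.shapes[i], b, rng)
                       for i, b in enumerate(spec.blocks)]
        head_in = int(np.prod(self.shapes[-1]))
        self.head = ClassifierHead(head_in, spec.head, rng)

    # -- parameter plumbing -------------------------------------------
    def parameters(self):
        ps = []
        for b in self.blocks:
            ps += b.parameters()
        ps += self.head.parameters()
        return ps

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def stage_names(self):
        return (["cochleagram"] +
                [f"block{i + 1}" for i in range(len(self.blocks))] +
                ["relufc"])

    # -- forward -------------------------------------------------------
    def forward(self, x: Tensor, gains: dict | None = None,
                gate_after_norm: bool = False, training: bool = False,
                rng: np.random.Generator | None = None,
                record: list | None = None) -> Tensor:
        """x: (B, C, F, T) cochleagram batch; gains maps site index
        (0 = cochleagram output, i = output of block i) to a gain Tensor
        broadcastable as (B, C, F, 1).  Returns logits (B, V)."""
        gains = gains or {}
        n_blocks = len(self.blocks)
        if record is not None:
            record.append(("cochleagram", x))
        for i, block in enumerate(self.blocks):
            # gains attached to site i (the previous stage's output) gate the
            # input of this block: before its norm by default, after it for
            # the gain-after-normalization variant
            x = block(x, gain=gains.get(i), gate_after_norm=gate_after_norm)
            if record is not None:
                record.append((f"block{i + 1}", x))
        if n_blocks in gains:
            # final conv-block output has no subsequent norm; gate directly
            x = x * gains[n_blocks]
        return self.head(x, training=training, rng=rng, record=record)

    def predict_proba(self, x: Tensor, **kw) -> np.ndarray:
        logits = self.forward(x, training=False, **kw)
        return softmax(logits.data, axis=1)

    # -- checkpointing ---------------------------------------------------
    SCHEMA_VERSION = 1

    def state_arrays(self) -> dict:
        out = {}
        for i, b in enumerate(self.blocks):
            out[f"block{i}.gamma"] = b.norm.gamma.data
            out[f"block{i}.beta"] = b.norm.beta.data
            out[f"block{i}.w"] = b.w.data
        for k in ("w1", "b1", "w2", "b2"):
            out[f"head.{k}"] = getattr(self.head, k).data
        return out

    def load_state_arrays(self, arrays: dict) -> None:
        for i, b in enumerate(self.blocks):
            b.norm.gamma.data = np.asarray(arrays[f"block{i}.gamma"], DTYPE)
            b.norm.beta.data = np.asarray(arrays[f"block{i}.beta"], DTYPE)
            b.w.data = np.asarray(arrays[f"block{i}.w"], DTYPE)
        for k in ("w1", "b1", "w2", "b2"):
            getattr(self.head, k).data = np.asarray(arrays[f"head.{k}"], DTYPE)


def mini_architecture(vocab: int = 8, in_channels: int = 2,
                      in_freq: int = 40, in_time: int = 500) -> ArchitectureSpec:
    """Desk-scale 3-block architecture for the reduced (250-Hz) cochleagram."""
    return ArchitectureSpec(
        in_channels=in_channels, in_freq=in_freq, in_time=in_time,
        blocks=[
            BlockSpec(c_out=8, n_f=5, n_t=9, s_f=2, s_t=4),
            BlockSpec(c_out=16, n_f=5, n_t=9, s_f=1, s_t=2),
            BlockSpec(c_out=32, n_f=3, n_t=7, s_f=1, s_t=2),
        ],
        head=HeadSpec(fc_dim=128, vocab=vocab), name="mini")


def paper_scale_architecture(vocab: int = 800,
                             in_channels: int = 2) -> ArchitectureSpec:
    """Plausible paper-scale template for the (2, 40, 20000) cochleagram.

    Documentation/configuration template only: training it is cluster work.
    """
    return ArchitectureSpec(
        in_channels=in_channels, in_freq=40, in_time=20000,
        blocks=[
            BlockSpec(c_out=32, n_f=5, n_t=32, s_f=1, s_t=4),
            BlockSpec(c_out=64, n_f=5, n_t=16, s_f=2, s_t=4),
            BlockSpec(c_out=128, n_f=5, n_t=16, s_f=1, s_t=4),
            BlockSpec(c_out=256, n_f=3, n_t=8, s_f=2, s_t=2),
            BlockSpec(c_out=512, n_f=3, n_t=8, s_f=1, s_t=2),
            BlockSpec(c_out=512, n_f=3, n_t=4, s_f=1, s_t=2),
        ],
        head=HeadSpec(fc_dim=1024, vocab=vocab), name="paper-scale")
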