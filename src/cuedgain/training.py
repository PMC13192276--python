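"""Optimization loop for the attention-model variants, desk-scaled.

Cross-entropy on the softmax word output; cue memories are recomputed
inside each forward pass so the gain parameters and backbone features
are jointly optimized.  AdamW with decoupled weight decay; gain
parameters and normalization shifts are excluded from decay.
"""

from __future__ import annotations

import gc
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._autograd import Tensor, cross_entropy, softmax
from .attention import AttentionModel

__all__ = ["TrainConfig", "AdamW", "train", "evaluate", "TrainHistory"]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3       # paper-scale config uses 5e-5
    batch_size: int = 16              # paper-scale config uses 288
    weight_decay: float = 0.01
    max_epochs: int = 30
    patience: int = 3                 # epochs without val improvement
    gain_lr_scale: float = 1.0        # multiplier for gain-parameter steps
    seed: int = 0


@dataclass
class TrainHistory:
    epochs: list = field(default_factory=list)

    def append(self, **row):
        self.epochs.append(row)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.epochs)


class AdamW:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0, decay_mask=None, lr_scale=None):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.wd = weight_decay
        self.decay_mask = decay_mask or [True] * len(params)
        self.lr_scale = lr_scale or [1.0] * len(params)
        self.m = [np.zeros_like(p.data, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p.data, dtype=np.float64) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            upd = (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
            if self.decay_mask[i] and self.wd:
                upd = upd + self.wd * p.data
            p.data = (p.data - self.lr * self.lr_scale[i] * upd).astype(
                p.data.dtype)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


def _decay_mask(model: AttentionModel):
    """Weight decay on conv/fc weights only (not norms, biases or gains)."""
    mask = []
    for b in model.net.blocks:
        mask += [False, False, True]          # gamma, beta, w
    mask += [True, False, True, False]        # w1, b1, w2, b2
    mask += [False] * (3 * len(model.sites))
    return mask


def _batches(n, batch_size, rng):
    idx = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield idx[i:i + batch_size]


def _stack(data, idx):
    cue = Tensor(np.stack([data[i][0] for i in idx]))
    mixc = Tensor(np.stack([data[i][1] for i in idx]))
    labels = np.array([data[i][2] for i in idx])
    return cue, mixc, labels


def _eval_loss_acc(model, data, batch_size=32):
    losses, correct, n = [], 0, 0
    for i in range(0, len(data), batch_size):
        idx = range(i, min(i + batch_size, len(data)))
        cue, mixc, labels = _stack(data, list(idx))
        logits = model.forward_attend(cue, mixc, training=False)
        losses.append(float(cross_entropy(logits, labels).data) * len(labels))
        correct += int((logits.data.argmax(axis=1) == labels).sum())
        n += len(labels)
    return sum(losses) / n, correct / n


def train(model: AttentionModel, train_data, val_data,
          cfg: TrainConfig | None = None, verbose: bool = False):
    """Train on (cue_cochleagram, mixture_cochleagram, label) triples.

    Returns (model, TrainHistory).  Aborts on NaN loss.  Fully seeded:
    batch order and dropout masks derive from cfg.seed.
    """
    cfg = cfg or TrainConfig()
    rng = np.random.default_rng(cfg.seed)
    params = model.parameters()
    n_gain = 3 * len(model.sites)
    lr_scale = [1.0] * (len(params) - n_gain) + [cfg.gain_lr_scale] * n_gain
    opt = AdamW(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay,
                decay_mask=_decay_mask(model) if len(params) else None,
                lr_scale=lr_scale)
    history = TrainHistory()
    best_val, best_state, stale = np.inf, None, 0
    for epoch in range(cfg.max_epochs):
        ep_loss, n_seen = 0.0, 0
        for idx in _batches(len(train_data), cfg.batch_size, rng):
            cue, mixc, labels = _stack(train_data, idx)
            opt.zero_grad()
            logits = model.forward_attend(cue, mixc, training=True, rng=rng)
            loss = cross_entropy(logits, labels)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}; last batch size "
                    f"{len(labels)}")
            loss.backward()
            opt.step()
            ep_loss += float(loss.data) * len(labels)
            n_seen += len(labels)
        gc.collect()   # large per-batch graphs; keep peak memory bounded
        val_loss, val_acc = _eval_loss_acc(model, val_data)
        history.append(epoch=epoch, train_loss=ep_loss / n_seen,
                       val_loss=val_loss, val_acc=val_acc)
        if verbose:
            print(f"epoch {epoch}: train {ep_loss / n_seen:.3f} "
                  f"val {val_loss:.3f} acc {val_acc:.3f}")
        # stop on validation loss: smoother than accuracy at small n_val
        if val_loss < best_val - 1e-6:
            best_val, stale = val_loss, 0
            best_state = {k: v.copy()
                          for k, v in model.net.state_arrays().items()}
            best_gains = {s: [t.data.copy()
                              for t in model.gain_params[s].parameters()]
                          for s in model.sites}
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    if best_state is not None:
        model.net.load_state_arrays(best_state)
        for s in model.sites:
            for t, v in zip(model.gain_params[s].parameters(), best_gains[s]):
                t.data = v
    return model, history


def evaluate(model: AttentionModel, stimuli, batch_size: int = 32):
    """Run inference on a list of stimulus dicts, one TrialRecord each.

    Each stimulus dict must hold `cue_coch`, `mix_coch` (arrays),
    `target_words`, `distractor_words` and arbitrary condition metadata
    under `condition`.
    """
    from .evaluation import TrialRecord
    records = []
    for i in range(0, len(stimuli), batch_size):
        chunk = stimuli[i:i + batch_size]
        cue = Tensor(np.stack([s["cue_coch"] for s in chunk]))
        mixc = Tensor(np.stack([s["mix_coch"] for s in chunk]))
        logits = model.forward_attend(cue, mixc, training=False)
        probs = softmax(logits.data, axis=1)
        resp = probs.argmax(axis=1)
        for s, r in zip(chunk, resp):
            records.append(TrialRecord(
                condition=dict(s.get("condition", {})),
                response=int(r),
                target_words=list(s["target_words"]),
                distractor_words=list(s.get("distractor_words", []))))
    return records
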