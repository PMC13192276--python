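"""Small plotting helpers for behavioural summaries."""

from __future__ import annotations

import numpy as np


def plot_performance_vs_snr(curves: dict, ax=None, title=None):
    """curves: condition label -> PsychometricCurve."""
    import matplotlib.pyplot as plt
    ax = ax or plt.gca()
    for label, c in curves.items():
        ax.plot(c.snr_db, c.proportion_correct, marker="o", label=str(label))
    ax.set_xlabel("SNR (dB)")
    ax.set_ylabel("proportion correct")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    return ax


def plot_spatial_release(srm: dict, ax=None, title=None):
    """srm: offset (deg) -> release from masking (dB)."""
    import matplotlib.pyplot as plt
    ax = ax or plt.gca()
    offsets = sorted(srm)
    ax.plot(offsets, [srm[o] for o in offsets], marker="s")
    ax.set_xlabel("target-distractor offset (deg)")
    ax.set_ylabel("spatial release from masking (dB)")
    if title:
        ax.set_title(title)
    return ax


def plot_stage_selection(per_stage: dict, ax=None, title=None):
    """per_stage: stage name -> {target_r, distractor_r}."""
    import matplotlib.pyplot as plt
    ax = ax or plt.gca()
    names = list(per_stage)
    x = np.arange(len(names))
    ax.plot(x, [per_stage[n]["target_r"] for n in names], marker="o",
            label="target-mixture r")
    ax.plot(x, [per_stage[n]["distractor_r"] for n in names], marker="o",
            label="distractor-mixture r")
    ax.set_xticks(x, names, rotation=30)
    ax.set_ylabel("Pearson r")
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    return ax
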