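"""Hypnogram plotting."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from somnostage.stages import StageLabel

# clinical display order, deepest sleep at the bottom
_DISPLAY_ORDER = [StageLabel.N3, StageLabel.N2, StageLabel.N1, StageLabel.REM, StageLabel.W]
_Y = {stage: i for i, stage in enumerate(_DISPLAY_ORDER)}


def plot_hypnogram(
    truth: np.ndarray,
    predicted: np.ndarray | None = None,
    path: str | Path | None = None,
    title: str = "Hypnogram",
):
    """Step plot of stage vs epoch index; optionally truth and prediction stacked."""
    seqs = [("Ground truth", truth)] + ([("Predicted", predicted)] if predicted is not None else [])
    fig, axes = plt.subplots(len(seqs), 1, figsize=(10, 2.2 * len(seqs)), sharex=True, squeeze=False)
    for ax, (label, seq) in zip(axes[:, 0], seqs):
        y = [_Y[StageLabel(int(s))] for s in seq]
        ax.step(np.arange(len(seq)), y, where="post", linewidth=0.8)
        ax.set_yticks(range(len(_DISPLAY_ORDER)))
        ax.set_yticklabels([s.name for s in _DISPLAY_ORDER])
        ax.set_ylabel(label)
        ax.set_ylim(-0.5, len(_DISPLAY_ORDER) - 0.5)
    axes[-1, 0].set_xlabel("Epoch (30 s)")
    axes[0, 0].set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
        return Path(path)
    return fig
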