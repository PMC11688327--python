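"""Full multimodal sleep-staging network.

Three per-channel branches (two EEG, one EOG) each encode a 29x128
time-frequency image: positional encoding, a stack of N_s causal-attention
encoder layers, then the multi-scale dilated block applied to the encoder
output with a residual sum.  The branch outputs are concatenated along the
feature axis (29 x 384), dropout- and layer-normalized, passed through a
second stack of N_m encoder layers, mean-pooled over time, and mapped to
five stage logits.

Ablation flags reduce the architecture to the basic-transformer baseline:
``use_ccte=False`` swaps the causal Q/K/V convolutions for plain affine
projections and disables CrossNorm; ``use_mfem=False`` removes the
multi-scale block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from somnostage.autodiff import Tensor, concat, softmax
from somnostage.nn.core import Dropout, LayerNorm, Linear, Module
from somnostage.nn.encoder import EncoderConfig, EncoderStack, PositionalEncoding
from somnostage.nn.mfem import Mfem, MfemConfig
from somnostage.stages import N_STAGES, StageLabel


@dataclass
class ModelConfig:
    """Architecture hyperparameters of the full network.

    ``input_dim`` is the spectrogram frequency-bin count F.  When
    ``encoder_single.model_dim`` differs from it (reduced models), each branch
    gets an affine input projection; the full-size model feeds the image in
    directly.
    """

    encoder_single: EncoderConfig = field(default_factory=lambda: EncoderConfig(model_dim=128, n_layers=8))
    encoder_fused: EncoderConfig = field(default_factory=lambda: EncoderConfig(model_dim=384, n_layers=4))
    mfem: MfemConfig = field(default_factory=MfemConfig)
    n_channels: int = 3
    n_classes: int = N_STAGES
    input_dim: int = 128
    fusion_dropout: float = 0.1
    use_ccte: bool = True
    use_mfem: bool = True

    def __post_init__(self):
        if self.encoder_fused.model_dim != self.n_channels * self.encoder_single.model_dim:
            raise ValueError(
                "fused model_dim must equal n_channels * single model_dim: "
                f"{self.encoder_fused.model_dim} != {self.n_channels} * {self.encoder_single.model_dim}"
            )

    @staticmethod
    def reduced(model_dim: int = 32, n_single: int = 2, n_fused: int = 1, n_heads: int = 8) -> "ModelConfig":
        """A small configuration for CPU-scale training runs."""
        return ModelConfig(
            encoder_single=EncoderConfig(model_dim=model_dim, n_layers=n_single, n_heads=n_heads),
            encoder_fused=EncoderConfig(model_dim=3 * model_dim, n_layers=n_fused, n_heads=n_heads),
        )


@dataclass
class StagePrediction:
    """Per-epoch class probabilities and the argmax stage (ties -> lowest index)."""

    probabilities: np.ndarray
    predicted: StageLabel


def _ablated(cfg: EncoderConfig, use_ccte: bool) -> EncoderConfig:
    if use_ccte:
        return cfg
    return EncoderConfig(
        model_dim=cfg.model_dim,
        n_layers=cfg.n_layers,
        n_heads=cfg.n_heads,
        ffn_hidden=cfg.ffn_hidden,
        dropout=cfg.dropout,
        causal_kernel=cfg.causal_kernel,
        crossnorm_mode="off",
        causal_qkv=False,
    )


class SleepStageNet(Module):
    """The assembled network; a deterministic function of (config, seed)."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        single = _ablated(cfg.encoder_single, cfg.use_ccte)
        fused = _ablated(cfg.encoder_fused, cfg.use_ccte)

        dim = single.model_dim
        if dim != cfg.input_dim:
            self.input_proj = [Linear(cfg.input_dim, dim, rng) for _ in range(cfg.n_channels)]
        else:
            self.input_proj = []
        self.pos_single = PositionalEncoding(dim)
        self.stacks = [EncoderStack(single, rng) for _ in range(cfg.n_channels)]
        self.mfems = (
            [Mfem(cfg.mfem, rng) for _ in range(cfg.n_channels)] if cfg.use_mfem else []
        )
        self.fusion_dropout = Dropout(cfg.fusion_dropout)
        self.fusion_norm = LayerNorm(fused.model_dim)
        self.pos_fused = PositionalEncoding(fused.model_dim)
        self.stack_fused = EncoderStack(fused, rng)
        self.head = Linear(fused.model_dim, cfg.n_classes, rng)

    # -- pipeline pieces ------------------------------------------------------
    def channel_branch(self, image: Tensor, channel: int) -> Tensor:
        """Encode one channel's (batch, T, F) image into a (batch, T, dim) map."""
        x = image
        if self.input_proj:
            x = self.input_proj[channel](x)
        x = self.pos_single(x)
        x = self.stacks[channel](x)
        if self.mfems:
            x = self.mfems[channel](x)
        return x

    def fuse_channels(self, branches: list[Tensor]) -> Tensor:
        """Concatenate per-channel maps along the feature axis; dropout + layer norm."""
        if len(branches) != self.cfg.n_channels:
            raise ValueError(f"expected {self.cfg.n_channels} channel maps, got {len(branches)}")
        fused = concat(branches, axis=-1)
        return self.fusion_norm(self.fusion_dropout(fused))

    def classify(self, fused: Tensor) -> Tensor:
        """Fused-sequence encoder, temporal mean pooling, affine head -> logits."""
        x = self.pos_fused(fused)
        x = self.stack_fused(x)
        pooled = x.mean(axis=1)
        return self.head(pooled)

    def forward(self, images) -> Tensor:
        """(batch, n_channels, T, F) image stack -> (batch, n_classes) logits."""
        images = Tensor.as_tensor(images)
        if images.ndim != 4 or images.shape[1] != self.cfg.n_channels:
            raise ValueError(
                f"expected (batch, {self.cfg.n_channels}, T, F) input, got shape {images.shape}"
            )
        branches = []
        for ch in range(self.cfg.n_channels):
            img = Tensor(images.data[:, ch])
            branches.append(self.channel_branch(img, ch))
        return self.classify(self.fuse_channels(branches))

    # -- inference ------------------------------------------------------------
    def predict_proba(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Eval-mode class probabilities, shape (n, n_classes)."""
        was_training = self.training
        self.eval()
        out = []
        for start in range(0, len(images), batch_size):
            logits = self.forward(images[start : start + batch_size])
            out.append(softmax(logits, axis=-1).data)
        if was_training:
            self.train()
        return np.concatenate(out, axis=0)

    def predict(self, images: np.ndarray, batch_size: int = 64) -> list[StagePrediction]:
        probs = self.predict_proba(images, batch_size=batch_size)
        return [
            StagePrediction(probabilities=p, predicted=StageLabel(int(np.argmax(p))))
            for p in probs
        ]
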