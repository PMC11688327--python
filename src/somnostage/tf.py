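"""Time-frequency imaging of 30-s PSG epochs.

Each single-channel epoch (3000 samples at 100 Hz) is turned into a log-scaled,
per-image standardized spectrogram S of shape T x F = 29 x 128: a 2-s Hamming
window slid with 50% overlap (hop 100 samples, no boundary padding) gives
exactly 29 frames, each zero-padded to a 256-point FFT whose one-sided
magnitude spectrum has 129 bins; dropping the DC bin (default policy) leaves
128 bins covering ~0.39-50 Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import hamming


@dataclass
class StftConfig:
    """Spectrogram parameters; defaults give a 29 x 128 image at 100 Hz.

    ``bin_policy`` selects which of the 129 one-sided FFT bins to drop:
    ``"drop_dc"`` removes the 0 Hz bin (EEG carries no DC information),
    ``"drop_nyquist"`` removes the 50 Hz bin.
    """

    window_s: float = 2.0
    overlap_fraction: float = 0.5
    n_fft: int = 256
    sample_rate_hz: float = 100.0
    log_epsilon: float = 1e-6
    bin_policy: str = "drop_dc"

    def __post_init__(self):
        if self.bin_policy not in ("drop_dc", "drop_nyquist"):
            raise ValueError(f"unknown bin_policy {self.bin_policy!r}")
        if self.n_fft < self.window_samples:
            raise ValueError(
                f"n_fft ({self.n_fft}) must be >= window length ({self.window_samples})"
            )
        if self.log_epsilon <= 0:
            raise ValueError("log_epsilon must be positive")

    @property
    def window_samples(self) -> int:
        return int(round(self.window_s * self.sample_rate_hz))

    @property
    def hop_samples(self) -> int:
        return int(round(self.window_samples * (1.0 - self.overlap_fraction)))

    def n_frames(self, n_samples: int) -> int:
        return (n_samples - self.window_samples) // self.hop_samples + 1

    @property
    def n_bins(self) -> int:
        return self.n_fft // 2  # 129 one-sided bins minus the dropped one

    def bin_frequencies(self) -> np.ndarray:
        """Center frequency (Hz) of each retained bin, in output order."""
        freqs = np.fft.rfftfreq(self.n_fft, d=1.0 / self.sample_rate_hz)
        return freqs[1:] if self.bin_policy == "drop_dc" else freqs[:-1]


@dataclass
class SpectroImage:
    """One epoch-channel's normalized log-magnitude spectrogram (T x F)."""

    values: np.ndarray
    channel_id: int = 0

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


def _frame_magnitudes(epoch: np.ndarray, cfg: StftConfig) -> np.ndarray:
    """Windowed one-sided FFT magnitudes per frame, before bin dropping."""
    win = hamming(cfg.window_samples, sym=False)
    n = cfg.n_frames(epoch.shape[-1])
    hop, wlen = cfg.hop_samples, cfg.window_samples
    frames = np.lib.stride_tricks.sliding_window_view(epoch, wlen)[::hop][:n]
    return np.abs(np.fft.rfft(frames * win, n=cfg.n_fft, axis=-1))


def stft_image(epoch: np.ndarray, cfg: StftConfig | None = None) -> SpectroImage:
    """Transform one 30-s single-channel epoch into a SpectroImage.

    Log-scales the magnitude spectrum (log(|S| + epsilon)) and standardizes
    the whole image to zero mean and unit variance.  A zero-variance image
    (e.g. an all-zero epoch) is returned as all zeros with a warning.
    """
    cfg = cfg or StftConfig()
    epoch = np.asarray(epoch, dtype=np.float64)
    expected = int(round(30.0 * cfg.sample_rate_hz))
    if epoch.ndim != 1 or epoch.shape[0] != expected:
        raise ValueError(
            f"epoch must be a 1-D array of {expected} samples "
            f"(30 s at {cfg.sample_rate_hz} Hz); got shape {epoch.shape}"
        )
    mag = _frame_magnitudes(epoch, cfg)
    mag = mag[:, 1:] if cfg.bin_policy == "drop_dc" else mag[:, :-1]
    logmag = np.log(mag + cfg.log_epsilon)
    std = logmag.std()
    if std == 0.0:
        warnings.warn("zero-variance spectrogram (constant input); returning all zeros")
        return SpectroImage(values=np.zeros_like(logmag))
    return SpectroImage(values=(logmag - logmag.mean()) / std)


def batch_transform(epochs, cfg: StftConfig | None = None) -> np.ndarray:
    """Transform an (n, n_channels, n_samples) epoch array to (n, n_channels, T, F).

    Accepts a raw array or an :class:`~somnostage.io.EpochedRecording`.
    Errors from individual epochs are re-raised with epoch/channel context.
    """
    cfg = cfg or StftConfig()
    if hasattr(epochs, "epochs"):
        epochs = epochs.epochs
    epochs = np.asarray(epochs, dtype=np.float64)
    if epochs.ndim != 3:
        raise ValueError(f"expected (n_epochs, n_channels, n_samples), got shape {epochs.shape}")
    n, c, _ = epochs.shape
    t = cfg.n_frames(epochs.shape[-1])
    out = np.empty((n, c, t, cfg.n_bins))
    for i in range(n):
        for ch in range(c):
            try:
                out[i, ch] = stft_image(epochs[i, ch], cfg).values
            except ValueError as exc:
                raise ValueError(f"epoch {i}, channel {ch}: {exc}") from exc
    return out
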