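"""Turn 30-s epochs into the model's 29 x 128 time-frequency images.

Synthesizes one epoch per stage and shows where each stage's spectral energy
concentrates: the frequency bin with the highest mean log power should sit in
the stage's defining band (delta for N3, theta for N1, alpha for wake, ...).
"""

import numpy as np

from somnostage import StageLabel, StftConfig, default_templates, stft_image, synthesize_epoch

cfg = StftConfig()
freqs = cfg.bin_frequencies()
templates = default_templates()

print(f"image geometry: T={cfg.n_frames(3000)} frames x F={cfg.n_bins} bins "
      f"({freqs[0]:.2f}-{freqs[-1]:.1f} Hz)\n")

for stage in StageLabel:
    block = synthesize_epoch(stage, templates[stage], seed=4)
    image = stft_image(block[0], cfg)  # first EEG channel
    peak = freqs[image.values.mean(axis=0).argmax()]
    print(f"{stage.name:3s}: EEG spectral peak at {peak:5.2f} Hz")

# Expected: N3 peaks in the delta band (<4 Hz), N1/REM in theta (4-8 Hz),
# W in alpha (8-12 Hz), N2 low-frequency with spindle-band bursts on top.
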