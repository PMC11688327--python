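"""Statistical and structural properties of the synthetic PSG generator."""

import numpy as np
import pytest
from scipy.signal import welch
from scipy.stats import chi2

from somnostage.stages import StageLabel
from somnostage.synthetic import (
    EPOCH_SAMPLES,
    StageTemplate,
    TransitionModel,
    balanced_epoch_set,
    generate_recording,
    sample_hypnogram,
    synthesize_epoch,
)
from somnostage.tf import StftConfig, stft_image


def stationary_by_power_iteration(matrix, iters=10_000):
    """Independent oracle: left fixed point of the transition matrix."""
    pi = np.full(5, 0.2)
    for _ in range(iters):
        pi = pi @ matrix
    return pi


class TestSampleHypnogram:
    def test_absorbing_chain_stays_in_n2(self):
        tm = TransitionModel(matrix=np.eye(5), initial=np.eye(5)[int(StageLabel.N2)])
        h = sample_hypnogram(tm, 10, seed=0)
        assert np.array_equal(h, np.full(10, int(StageLabel.N2)))

    def test_frequencies_match_stationary_distribution(self):
        tm = TransitionModel.default()
        h = sample_hypnogram(tm, 10_000, seed=1)
        freqs = np.bincount(h, minlength=5) / len(h)
        target = stationary_by_power_iteration(tm.matrix)
        assert np.abs(freqs - target).max() < 0.03

    def test_osa_mode_fragments_sleep(self):
        for seed in range(3):
            h_default = sample_hypnogram(TransitionModel.default(), 10_000, seed=seed)
            h_osa = sample_hypnogram(TransitionModel.osa(), 10_000, seed=seed)
            assert (np.diff(h_osa) != 0).sum() > (np.diff(h_default) != 0).sum()
            assert (h_osa == int(StageLabel.N1)).mean() > (h_default == int(StageLabel.N1)).mean()

    @pytest.mark.parametrize("seed", range(5))
    def test_transition_frequencies_fit_the_chain(self, seed):
        """Pooled per-row chi-square goodness of fit, alpha = 0.01."""
        tm = TransitionModel.default()
        h = sample_hypnogram(tm, 5_000, seed=seed)
        counts = np.zeros((5, 5))
        np.add.at(counts, (h[:-1], h[1:]), 1)
        stat, dof = 0.0, 0
        for row in range(5):
            n_row = counts[row].sum()
            if n_row == 0:
                continue
            expected = n_row * tm.matrix[row]
            stat += ((counts[row] - expected) ** 2 / expected).sum()
            dof += 4
        assert stat < chi2.ppf(0.99, dof)

    def test_rejects_non_stochastic_matrix(self):
        bad = np.full((5, 5), 0.3)
        with pytest.raises(ValueError, match="sum to 1"):
            TransitionModel(matrix=bad, initial=np.full(5, 0.2))

    def test_rejects_empty_hypnogram(self):
        with pytest.raises(ValueError, match="n_epochs"):
            sample_hypnogram(TransitionModel.default(), 0, seed=0)


class TestSynthesizeEpoch:
    def test_n3_is_delta_dominated(self, templates):
        block = synthesize_epoch(StageLabel.N3, templates[StageLabel.N3], seed=0)
        f, p = welch(block[0], fs=100.0, nperseg=512)
        delta = p[(f >= 0.5) & (f <= 4)].mean()
        spindle = p[(f >= 12) & (f <= 16)].mean()
        assert delta / spindle >= 4.0

    @pytest.mark.parametrize("seed", range(3))
    def test_n2_spindle_bursts_visible_in_spectrogram(self, templates, seed):
        block = synthesize_epoch(StageLabel.N2, templates[StageLabel.N2], seed=seed)
        image = stft_image(block[0]).values
        freqs = StftConfig().bin_frequencies()
        series = image[:, (freqs >= 12) & (freqs <= 16)].mean(axis=1)
        med = np.median(series)
        mad = np.median(np.abs(series - med))
        assert (series > med + 3 * mad).any()

    def test_zero_amplitude_template_yields_silence(self):
        silent = StageTemplate(
            stage=StageLabel.W, band_powers={(0.5, 45.0): 0.0}, eog_amplitude=0.0, rms_uv=0.0
        )
        block = synthesize_epoch(StageLabel.W, silent, seed=3)
        assert block.shape == (3, EPOCH_SAMPLES)
        assert np.all(block == 0.0)

    def test_template_stage_mismatch_rejected(self, templates):
        with pytest.raises(ValueError, match="template"):
            synthesize_epoch(StageLabel.W, templates[StageLabel.N3], seed=0)

    def test_deterministic_given_seed(self, templates):
        a = synthesize_epoch(StageLabel.REM, templates[StageLabel.REM], seed=11)
        b = synthesize_epoch(StageLabel.REM, templates[StageLabel.REM], seed=11)
        assert np.array_equal(a, b)


class TestGenerateRecording:
    def test_bitwise_reproducible(self, small_recording):
        again = generate_recording(n_epochs=40, seed=7)
        assert np.array_equal(small_recording.signals, again.signals)
        assert np.array_equal(small_recording.hypnogram, again.hypnogram)

    def test_shapes_follow_epoch_count(self):
        rec = generate_recording(n_epochs=100, seed=0)
        assert rec.signals.shape == (3, 100 * EPOCH_SAMPLES)
        assert len(rec.hypnogram) == 100

    def test_missing_template_rejected(self, templates):
        partial = {k: v for k, v in templates.items() if k != StageLabel.REM}
        with pytest.raises(ValueError, match="REM"):
            generate_recording(templates=partial, n_epochs=5, seed=0)

    def test_stage_band_powers_nearest_centroid_separable(self):
        """Generated stages are separable by band-power centroids (>= 90%)."""
        epochs, labels = balanced_epoch_set(40, seed=5)
        bands = [(0.5, 4), (4, 8), (8, 12), (12, 16), (16, 30)]
        feats = []
        for block in epochs:
            row = []
            for ch in range(3):
                f, p = welch(block[ch], fs=100.0, nperseg=512)
                row.extend(np.log(p[(f >= lo) & (f < hi)].mean() + 1e-12) for lo, hi in bands)
            feats.append(row)
        x = np.asarray(feats)
        centroids = np.stack([x[labels == s].mean(axis=0) for s in range(5)])
        pred = ((x[:, None, :] - centroids[None]) ** 2).sum(-1).argmin(axis=1)
        assert (pred == labels).mean() >= 0.90
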