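"""Synthetic polysomnography generator.

Produces multi-channel recordings (two EEG surrogates, one EOG surrogate at
100 Hz, µV scale) whose per-stage spectral content follows the canonical AASM
picture: alpha/beta wake, theta-dominant N1, spindle-band (12-16 Hz) bursts
over a mixed background in N2, high-amplitude 0.5-4 Hz delta in N3, and
mixed-frequency EEG with large slow EOG deflections in REM.  Stage sequences
come from a first-order Markov chain; an OSA mode emulates the fragmented
sleep of obstructive sleep apnea — more frequent stage transitions, inflated
N1 occupancy, reduced N3 and REM.

Every generated object is a pure function of (configuration, seed).

The default transition models are parameterized as ``P = s*I + (1-s) * 1·piᵀ``
with persistence ``s`` and target occupancy ``pi``; the stationary
distribution of such a chain is exactly ``pi``.  Default occupancies follow
standard sleep architecture (N1 2-5%, N2 45-55%, N3 15-25%, REM 20-25% of
sleep, the remainder wake); OSA mode doubles the off-diagonal transition mass
(``1-s``) and triples the N1 occupancy at the expense of N3 and REM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import firwin, lfilter

from somnostage.edf import write_edf_annotations, write_edf_signals
from somnostage.stages import N_STAGES, STAGE_NAMES, StageLabel

SAMPLE_RATE_HZ = 100.0
EPOCH_S = 30.0
EPOCH_SAMPLES = int(EPOCH_S * SAMPLE_RATE_HZ)

#: Default channel labels of written EDF files (Sleep-EDF convention).
DEFAULT_CHANNEL_LABELS = ("EEG Fpz-Cz", "EEG Pz-Oz", "EOG horizontal")

#: Stage-run annotation texts in the Sleep-EDF hypnogram dialect.
SLEEP_EDF_STAGE_TEXT = {
    StageLabel.W: "Sleep stage W",
    StageLabel.N1: "Sleep stage 1",
    StageLabel.N2: "Sleep stage 2",
    StageLabel.N3: "Sleep stage 3",
    StageLabel.REM: "Sleep stage R",
}


# ---------------------------------------------------------------------------
# stage templates
# ---------------------------------------------------------------------------


@dataclass
class BurstSpec:
    """A transient oscillation (spindle or K-complex surrogate).

    ``amplitude`` is relative to the template's RMS; ``rate_per_epoch`` is the
    expected number of events per 30-s epoch (Poisson-distributed).
    """

    center_hz: float
    duration_s: float
    rate_per_epoch: float
    amplitude: float

    def __post_init__(self):
        if not 0.0 < self.duration_s < EPOCH_S:
            raise ValueError(f"burst duration must lie in (0, {EPOCH_S:g}) s, got {self.duration_s}")
        if self.rate_per_epoch < 0 or self.amplitude < 0:
            raise ValueError("burst rate and amplitude must be non-negative")


@dataclass
class StageTemplate:
    """Spectral recipe of one stage.

    ``band_powers`` maps (f_lo, f_hi) Hz intervals to non-negative relative
    amplitudes; the summed band-filtered noise is rescaled to ``rms_uv``.
    ``eog_amplitude`` scales the slow (<1.5 Hz) deflections on the EOG
    surrogate, in µV RMS.
    """

    stage: StageLabel
    band_powers: dict[tuple[float, float], float]
    burst_events: list[BurstSpec] = field(default_factory=list)
    eog_amplitude: float = 0.0
    rms_uv: float = 20.0

    def __post_init__(self):
        for (lo, hi), w in self.band_powers.items():
            if w < 0:
                raise ValueError(f"band power for ({lo}, {hi}) must be non-negative, got {w}")
            if not 0 <= lo < hi <= SAMPLE_RATE_HZ / 2:
                raise ValueError(f"band ({lo}, {hi}) outside (0, Nyquist]")
        if self.eog_amplitude < 0 or self.rms_uv < 0:
            raise ValueError("amplitudes must be non-negative")


def default_templates() -> dict[StageLabel, StageTemplate]:
    """The generator's default per-stage recipes (amplitudes in µV)."""
    return {
        StageLabel.W: StageTemplate(
            stage=StageLabel.W,
            band_powers={(8.0, 12.0): 1.0, (16.0, 30.0): 0.7, (0.5, 45.0): 0.3},
            eog_amplitude=30.0,
            rms_uv=15.0,
        ),
        StageLabel.N1: StageTemplate(
            stage=StageLabel.N1,
            band_powers={(4.0, 8.0): 1.0, (0.5, 45.0): 0.4},
            eog_amplitude=15.0,
            rms_uv=20.0,
        ),
        StageLabel.N2: StageTemplate(
            stage=StageLabel.N2,
            band_powers={(4.0, 8.0): 0.6, (0.5, 45.0): 0.5, (12.0, 16.0): 0.2},
            burst_events=[
                BurstSpec(center_hz=14.0, duration_s=1.0, rate_per_epoch=4.0, amplitude=2.5),
                BurstSpec(center_hz=1.0, duration_s=1.0, rate_per_epoch=1.0, amplitude=2.0),
            ],
            eog_amplitude=5.0,
            rms_uv=25.0,
        ),
        StageLabel.N3: StageTemplate(
            stage=StageLabel.N3,
            band_powers={(0.5, 4.0): 1.0, (0.5, 45.0): 0.15},
            eog_amplitude=5.0,
            rms_uv=40.0,
        ),
        StageLabel.REM: StageTemplate(
            stage=StageLabel.REM,
            band_powers={(4.0, 8.0): 0.7, (16.0, 30.0): 0.5, (0.5, 45.0): 0.5},
            eog_amplitude=80.0,
            rms_uv=20.0,
        ),
    }


# ---------------------------------------------------------------------------
# transition model
# ---------------------------------------------------------------------------


@dataclass
class TransitionModel:
    """First-order Markov chain over the five stages."""

    matrix: np.ndarray
    initial: np.ndarray
    osa_mode: bool = False

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.initial = np.asarray(self.initial, dtype=np.float64)
        if self.matrix.shape != (N_STAGES, N_STAGES):
            raise ValueError(f"transition matrix must be 5x5, got {self.matrix.shape}")
        if (self.matrix < 0).any() or (self.initial < 0).any():
            raise ValueError("transition probabilities must be non-negative")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"transition matrix rows must sum to 1, got {self.matrix.sum(axis=1)}")
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-9):
            raise ValueError(f"initial distribution must sum to 1, got {self.initial.sum()}")

    @staticmethod
    def _from_occupancy(pi: np.ndarray, persistence: float, osa_mode: bool) -> "TransitionModel":
        pi = np.asarray(pi, dtype=np.float64)
        matrix = persistence * np.eye(N_STAGES) + (1.0 - persistence) * pi[None, :]
        return TransitionModel(matrix=matrix, initial=pi.copy(), osa_mode=osa_mode)

    @staticmethod
    def default() -> "TransitionModel":
        """Standard sleep architecture: W 6%, N1 4%, N2 48%, N3 20%, REM 22%."""
        return TransitionModel._from_occupancy(
            np.array([0.06, 0.04, 0.48, 0.20, 0.22]), persistence=0.9, osa_mode=False
        )

    @staticmethod
    def osa() -> "TransitionModel":
        """Fragmented OSA sleep: doubled transition mass, tripled N1, reduced N3/REM."""
        return TransitionModel._from_occupancy(
            np.array([0.16, 0.12, 0.50, 0.10, 0.12]), persistence=0.8, osa_mode=True
        )

    def stationary_distribution(self) -> np.ndarray:
        """Left eigenvector of the transition matrix for eigenvalue 1."""
        vals, vecs = np.linalg.eig(self.matrix.T)
        idx = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, idx])
        return pi / pi.sum()


def sample_hypnogram(transitions: TransitionModel, n_epochs: int, seed: int) -> np.ndarray:
    """Sample a stage-label sequence (integer-coded, one label per 30-s epoch)."""
    if n_epochs < 1:
        raise ValueError(f"n_epochs must be >= 1, got {n_epochs}")
    rng = np.random.default_rng(seed)
    labels = np.empty(n_epochs, dtype=np.int64)
    labels[0] = rng.choice(N_STAGES, p=transitions.initial)
    for i in range(1, n_epochs):
        labels[i] = rng.choice(N_STAGES, p=transitions.matrix[labels[i - 1]])
    return labels


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------

_FIR_TAPS = 301
_filter_cache: dict[tuple[float, float], np.ndarray] = {}


def _bandpass(lo: float, hi: float) -> np.ndarray:
    key = (lo, hi)
    if key not in _filter_cache:
        _filter_cache[key] = firwin(
            _FIR_TAPS, [lo, hi], pass_zero=False, fs=SAMPLE_RATE_HZ
        )
    return _filter_cache[key]


def _shaped_noise(template: StageTemplate, rng: np.random.Generator) -> np.ndarray:
    """Band-weighted filtered noise over a 1/f colored base, RMS-normalized."""
    total = sum(template.band_powers.values())
    if total == 0.0:
        return np.zeros(EPOCH_SAMPLES)
    pad = _FIR_TAPS  # discard filter warm-up
    x = np.zeros(EPOCH_SAMPLES + pad)
    for (lo, hi), w in template.band_powers.items():
        if w == 0.0:
            continue
        band_white = rng.standard_normal(EPOCH_SAMPLES + pad)
        band = lfilter(_bandpass(lo, hi), [1.0], band_white)
        # 1/f-flavored overall color: down-weight bands by their center frequency
        x += w * band / max(np.sqrt((lo + hi) / 2.0), 1.0) ** 0.5
    x = x[pad:]
    rms = x.std()
    if rms > 0:
        x = x * (template.rms_uv / rms)
    return x


def _add_bursts(x: np.ndarray, template: StageTemplate, rng: np.random.Generator) -> np.ndarray:
    for burst in template.burst_events:
        n_events = rng.poisson(burst.rate_per_epoch)
        n_burst = int(burst.duration_s * SAMPLE_RATE_HZ)
        for _ in range(n_events):
            start = rng.integers(0, EPOCH_SAMPLES - n_burst)
            t = np.arange(n_burst) / SAMPLE_RATE_HZ
            phase = rng.uniform(0, 2 * np.pi)
            envelope = np.hanning(n_burst)
            tone = np.sin(2 * np.pi * burst.center_hz * t + phase)
            x[start : start + n_burst] += burst.amplitude * template.rms_uv * np.sqrt(2) * envelope * tone
    return x


def _eog_channel(template: StageTemplate, rng: np.random.Generator) -> np.ndarray:
    if template.eog_amplitude == 0.0 and template.rms_uv == 0.0:
        return np.zeros(EPOCH_SAMPLES)
    pad = _FIR_TAPS
    slow = lfilter(
        firwin(_FIR_TAPS, 1.5, fs=SAMPLE_RATE_HZ), [1.0], rng.standard_normal(EPOCH_SAMPLES + pad)
    )[pad:]
    rms = slow.std()
    if rms > 0 and template.eog_amplitude > 0:
        slow = slow * (template.eog_amplitude / rms)
    else:
        slow = np.zeros(EPOCH_SAMPLES)
    # EEG crosstalk picked up by the periorbital electrodes
    crosstalk = 0.2 * _shaped_noise(template, rng)
    return slow + crosstalk


def synthesize_epoch(stage: StageLabel, template: StageTemplate, seed) -> np.ndarray:
    """Synthesize one 30-s, 3-channel (EEG, EEG, EOG) epoch in µV.

    ``seed`` may be an integer or a ``numpy.random.SeedSequence``.  A template
    with all amplitudes zero yields an all-zero block.
    """
    if template.stage != stage:
        raise ValueError(f"template is for stage {template.stage.name}, not {StageLabel(stage).name}")
    rng = np.random.default_rng(seed)
    eeg1 = _add_bursts(_shaped_noise(template, rng), template, rng)
    eeg2 = _add_bursts(_shaped_noise(template, rng), template, rng)
    eog = _eog_channel(template, rng)
    return np.stack([eeg1, eeg2, eog])


# ---------------------------------------------------------------------------
# whole recordings
# ---------------------------------------------------------------------------


@dataclass
class SyntheticRecording:
    """A generated night: (3, n_epochs*3000) µV signals + integer hypnogram."""

    signals: np.ndarray
    hypnogram: np.ndarray
    seed: int
    sample_rate_hz: float = SAMPLE_RATE_HZ

    @property
    def n_epochs(self) -> int:
        return len(self.hypnogram)


def generate_recording(
    transitions: TransitionModel | None = None,
    templates: dict[StageLabel, StageTemplate] | None = None,
    n_epochs: int = 100,
    seed: int = 0,
) -> SyntheticRecording:
    """Sample a hypnogram and synthesize the matching signals, bit-reproducibly."""
    transitions = transitions or TransitionModel.default()
    templates = templates if templates is not None else default_templates()
    missing = [STAGE_NAMES[s] for s in StageLabel if s not in templates]
    if missing:
        raise ValueError(f"templates missing for stages: {missing}")
    root = np.random.SeedSequence(seed)
    hyp_seed, epoch_root = root.spawn(2)
    hypnogram = sample_hypnogram(transitions, n_epochs, hyp_seed)
    epoch_seeds = epoch_root.spawn(n_epochs)
    signals = np.concatenate(
        [
            synthesize_epoch(StageLabel(int(s)), templates[StageLabel(int(s))], es)
            for s, es in zip(hypnogram, epoch_seeds)
        ],
        axis=1,
    )
    return SyntheticRecording(signals=signals, hypnogram=hypnogram, seed=seed)


def balanced_epoch_set(
    n_per_stage: int,
    seed: int = 0,
    templates: dict[StageLabel, StageTemplate] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Stage-balanced epochs for classifier experiments.

    Returns ``(epochs, labels)`` with epochs of shape
    (5*n_per_stage, 3, 3000), interleaved by stage and seed-reproducible.
    """
    templates = templates if templates is not None else default_templates()
    root = np.random.SeedSequence(seed)
    stage_roots = root.spawn(N_STAGES)
    blocks, labels = [], []
    for s in StageLabel:
        for es in stage_roots[int(s)].spawn(n_per_stage):
            blocks.append(synthesize_epoch(s, templates[s], es))
            labels.append(int(s))
    order = np.random.default_rng(root.spawn(1)[0]).permutation(len(blocks))
    epochs = np.stack(blocks)[order]
    return epochs, np.asarray(labels, dtype=np.int64)[order]


def hypnogram_runs(hypnogram: np.ndarray) -> list[tuple[float, float, str]]:
    """Collapse a per-epoch hypnogram into (onset_s, duration_s, text) stage runs."""
    runs = []
    start = 0
    for i in range(1, len(hypnogram) + 1):
        if i == len(hypnogram) or hypnogram[i] != hypnogram[start]:
            runs.append(
                (start * EPOCH_S, (i - start) * EPOCH_S, SLEEP_EDF_STAGE_TEXT[StageLabel(int(hypnogram[start]))])
            )
            start = i
    return runs


def write_edf(
    recording: SyntheticRecording,
    path: str | Path,
    annotation_path: str | Path | None = None,
    channel_labels: tuple[str, str, str] = DEFAULT_CHANNEL_LABELS,
) -> tuple[Path, Path]:
    """Write a recording as EDF plus an EDF+ hypnogram sidecar.

    The sidecar defaults to ``<stem>-Hypnogram.edf`` next to the signal file.
    Returns (signal_path, annotation_path).
    """
    if recording.n_epochs == 0:
        raise ValueError("cannot write a recording with zero epochs")
    path = Path(path)
    if annotation_path is None:
        annotation_path = path.with_name(path.stem + "-Hypnogram.edf")
    # EOG gets a wider physical range: REM deflections exceed the EEG's ±250 µV
    sig_path = write_edf_signals(
        path,
        recording.signals,
        recording.sample_rate_hz,
        list(channel_labels),
        physical_range_uv=[250.0, 250.0, 500.0],
    )
    ann_path = write_edf_annotations(Path(annotation_path), hypnogram_runs(recording.hypnogram))
    return sig_path, ann_path
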