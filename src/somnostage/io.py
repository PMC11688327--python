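"""Reading PSG recordings into per-subject epoched arrays.

EDF signals are read through ``mne``, resampled to the target rate, segmented
into 30-s epochs aligned to the hypnogram annotation onsets, and paired with
stage labels harmonized to the five-class AASM scheme (the older R&K stages 3
and 4 both map to N3; movement-time and unscored epochs are dropped).
Hypnograms may come from an EDF+ annotation sidecar in the Sleep-EDF dialect
or from a CSV with ``epoch_index,stage`` rows.
"""

from __future__ import annotations

import csv
import importlib.resources
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.signal import resample_poly

from somnostage.stages import N_STAGES, StageLabel

EPOCH_S = 30.0

#: Sentinel for annotation labels excluded from training/evaluation.
EXCLUDED = "EXCLUDED"

_LABEL_MAP = {
    "W": StageLabel.W,
    "1": StageLabel.N1,
    "2": StageLabel.N2,
    "3": StageLabel.N3,
    "4": StageLabel.N3,  # R&K stage 4 merges into N3
    "R": StageLabel.REM,
    "N1": StageLabel.N1,
    "N2": StageLabel.N2,
    "N3": StageLabel.N3,
    "N4": StageLabel.N3,
    "REM": StageLabel.REM,
}
_EXCLUDED_LABELS = {"?", "MOVEMENT", "MOVEMENT TIME"}


def map_label(raw_label: str):
    """Harmonize an annotation string to a StageLabel or ``EXCLUDED``.

    Accepts the Sleep-EDF dialect ("Sleep stage W", "Sleep stage 4", ...) and
    bare stage names.  Unknown strings raise, naming the offending label.
    """
    text = raw_label.strip()
    key = text.upper()
    if key.startswith("SLEEP STAGE"):
        key = key[len("SLEEP STAGE") :].strip()
    if key in _EXCLUDED_LABELS:
        return EXCLUDED
    if key in _LABEL_MAP:
        return _LABEL_MAP[key]
    raise ValueError(f"unknown sleep-stage annotation {raw_label!r}")


# ---------------------------------------------------------------------------
# channel selection
# ---------------------------------------------------------------------------


def _load_alias_groups() -> list[list[str]]:
    ref = importlib.resources.files("somnostage").joinpath("data/channel_aliases.yaml")
    return yaml.safe_load(ref.read_text())


@dataclass
class ChannelSpec:
    """Which three channels (2 EEG + 1 EOG) to extract, and the target rate."""

    names: tuple[str, str, str] = ("EEG Fpz-Cz", "EEG Pz-Oz", "EOG horizontal")
    resample_hz: float = 100.0
    aliases: list[list[str]] = field(default_factory=_load_alias_groups)

    def __post_init__(self):
        if len(self.names) != 3:
            raise ValueError(f"exactly 3 channels required, got {len(self.names)}")
        if self.resample_hz <= 0:
            raise ValueError(f"resample_hz must be positive, got {self.resample_hz}")

    def _equivalents(self, name: str) -> set[str]:
        out = {name.strip().upper()}
        for group in self.aliases:
            if any(g.strip().upper() in out for g in group):
                out.update(g.strip().upper() for g in group)
        return out

    def resolve(self, available: list[str]) -> list[str]:
        """Match the requested names against available channel labels."""
        chosen = []
        for want in self.names:
            eq = self._equivalents(want)
            hits = [ch for ch in available if ch.strip().upper() in eq]
            if not hits:
                raise ValueError(
                    f"channel {want!r} not found; available channels: {available}"
                )
            chosen.append(hits[0])
        return chosen


# ---------------------------------------------------------------------------
# epoched container
# ---------------------------------------------------------------------------


@dataclass
class EpochedRecording:
    """Per-subject array of 30-s, 3-channel epochs with stage labels (µV)."""

    subject_id: str
    epochs: np.ndarray  # (n, 3, samples_per_epoch)
    labels: np.ndarray  # (n,) integer StageLabel codes
    source_rate_hz: float

    def __post_init__(self):
        if self.epochs.shape[0] != len(self.labels):
            raise ValueError(
                f"epoch count {self.epochs.shape[0]} != label count {len(self.labels)}"
            )

    @property
    def n_epochs(self) -> int:
        return len(self.labels)


def _read_annotation_list(annotation_path: Path) -> list[tuple[float, float, str]]:
    if annotation_path.suffix.lower() == ".csv":
        out = []
        with open(annotation_path, newline="") as fh:
            for row in csv.DictReader(fh):
                idx = int(row["epoch_index"])
                out.append((idx * EPOCH_S, EPOCH_S, row["stage"]))
        return out
    import mne

    anns = mne.read_annotations(str(annotation_path))
    return [(float(a["onset"]), float(a["duration"]), str(a["description"])) for a in anns]


def read_recording(
    edf_path: str | Path,
    annotation_path: str | Path,
    spec: ChannelSpec | None = None,
    subject_id: str | None = None,
) -> EpochedRecording:
    """Read an EDF + hypnogram pair into an epoched, label-aligned array.

    Signals are converted to µV, resampled to ``spec.resample_hz``, and cut
    into half-open 30-s windows starting at each annotated epoch onset.
    Epochs with excluded labels (movement time, unscored) are dropped.
    """
    import mne

    spec = spec or ChannelSpec()
    edf_path, annotation_path = Path(edf_path), Path(annotation_path)
    raw = mne.io.read_raw_edf(str(edf_path), preload=True, verbose="error")
    picks = spec.resolve(raw.ch_names)
    data = raw.get_data(picks=picks, units="uV")
    source_rate = float(raw.info["sfreq"])
    if source_rate != spec.resample_hz:
        up, down = (np.array([spec.resample_hz, source_rate]) * 1000).astype(int)
        data = resample_poly(data, up, down, axis=-1)

    samples_per_epoch = int(round(EPOCH_S * spec.resample_hz))
    n_available = data.shape[1]
    epochs, labels = [], []
    for onset, duration, text in _read_annotation_list(annotation_path):
        label = map_label(text)
        n_sub = max(1, int(round(duration / EPOCH_S)))
        for k in range(n_sub):
            start = int(round((onset + k * EPOCH_S) * spec.resample_hz))
            stop = start + samples_per_epoch
            if stop > n_available:
                raise ValueError(
                    f"annotation at {onset + k * EPOCH_S:g} s overruns the signal: "
                    f"needs samples [{start}, {stop}) of {n_available}"
                )
            if label is EXCLUDED:
                continue
            epochs.append(data[:, start:stop])
            labels.append(int(label))
    if not epochs:
        raise ValueError(f"no scorable epochs found in {annotation_path}")
    return EpochedRecording(
        subject_id=subject_id or edf_path.stem,
        epochs=np.stack(epochs),
        labels=np.asarray(labels, dtype=np.int64),
        source_rate_hz=source_rate,
    )


def trim_wake_margins(rec: EpochedRecording, margin_minutes: float | None) -> EpochedRecording:
    """Reduce leading/trailing wake runs to at most ``margin_minutes`` each side.

    ``None`` disables trimming.  An all-wake recording is returned unchanged
    with a warning.
    """
    if margin_minutes is None:
        return rec
    if margin_minutes < 0:
        raise ValueError(f"margin must be >= 0 minutes, got {margin_minutes}")
    non_wake = np.flatnonzero(rec.labels != int(StageLabel.W))
    if non_wake.size == 0:
        warnings.warn(f"recording {rec.subject_id} is all wake; margins not trimmed")
        return rec
    margin_epochs = int(round(margin_minutes * 60.0 / EPOCH_S))
    lo = max(0, non_wake[0] - margin_epochs)
    hi = min(rec.n_epochs, non_wake[-1] + 1 + margin_epochs)
    return EpochedRecording(
        subject_id=rec.subject_id,
        epochs=rec.epochs[lo:hi],
        labels=rec.labels[lo:hi],
        source_rate_hz=rec.source_rate_hz,
    )


def stage_counts(labels: np.ndarray) -> dict[str, int]:
    """Per-stage epoch counts keyed by stage name."""
    from somnostage.stages import STAGE_NAMES

    counts = np.bincount(np.asarray(labels, dtype=np.int64), minlength=N_STAGES)
    return {STAGE_NAMES[i]: int(counts[i]) for i in range(N_STAGES)}
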