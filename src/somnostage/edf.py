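"""Minimal EDF / EDF+ writing.

Two writers cover what the synthetic generator needs: a plain EDF file with
16-bit signal records, and an EDF+C annotation-only sidecar holding a
hypnogram as timestamped annotation lists (TALs) in the Sleep-EDF dialect
("Sleep stage W", "Sleep stage 1", ...).  Reading goes through ``mne``.

No installed package writes EDF, hence the hand-rolled encoder; the format is
a fixed-width ASCII header followed by little-endian int16 data records.
"""

from __future__ import annotations

import datetime
from pathlib import Path

import numpy as np

_HEADER_DATE = "01.01.00"
_HEADER_TIME = "00.00.00"


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"header field {s!r} exceeds {width} ascii bytes")
    return s.ljust(width).encode("ascii")


def _signal_header(
    labels: list[str],
    transducers: list[str],
    phys_dims: list[str],
    phys_min: list[float],
    phys_max: list[float],
    dig_min: list[int],
    dig_max: list[int],
    samples_per_record: list[int],
) -> bytes:
    ns = len(labels)
    parts = []
    for values, width in [
        (labels, 16),
        (transducers, 80),
        (phys_dims, 8),
        (phys_min, 8),
        (phys_max, 8),
        (dig_min, 8),
        (dig_max, 8),
        (["" for _ in range(ns)], 80),  # prefiltering
        (samples_per_record, 8),
        (["" for _ in range(ns)], 32),  # reserved
    ]:
        for v in values:
            parts.append(_field(v, width))
    return b"".join(parts)


def _main_header(
    n_records: int,
    record_duration: float,
    n_signals: int,
    reserved: str = "",
    start_date: str = _HEADER_DATE,
    start_time: str = _HEADER_TIME,
) -> bytes:
    header_bytes = 256 * (1 + n_signals)
    dur = f"{record_duration:g}"
    return b"".join(
        [
            _field("0", 8),
            _field("X X X X", 80),
            _field("Startdate X X X X", 80),
            _field(start_date, 8),
            _field(start_time, 8),
            _field(header_bytes, 8),
            _field(reserved, 44),
            _field(n_records, 8),
            _field(dur, 8),
            _field(n_signals, 4),
        ]
    )


def write_edf_signals(
    path: str | Path,
    signals: np.ndarray,
    sample_rate_hz: float,
    channel_labels: list[str],
    physical_range_uv: float | list[float] = 250.0,
    record_duration_s: float = 30.0,
) -> Path:
    """Write a (n_channels, n_samples) µV array as 16-bit EDF.

    ``physical_range_uv`` may be a scalar or per-channel list; samples outside
    ±range are clipped.  The total duration must be a whole number of records.
    """
    path = Path(path)
    signals = np.asarray(signals, dtype=np.float64)
    if signals.ndim != 2 or signals.shape[0] != len(channel_labels):
        raise ValueError(
            f"signals must be (n_channels={len(channel_labels)}, n_samples); got {signals.shape}"
        )
    spr = int(round(record_duration_s * sample_rate_hz))
    n_samples = signals.shape[1]
    if n_samples == 0 or n_samples % spr != 0:
        raise ValueError(
            f"signal length {n_samples} is not a positive multiple of "
            f"{spr} samples ({record_duration_s:g} s records at {sample_rate_hz:g} Hz)"
        )
    n_records = n_samples // spr
    ns = signals.shape[0]
    ranges = np.broadcast_to(np.asarray(physical_range_uv, dtype=np.float64), (ns,))
    dig_max, dig_min = 32767, -32768
    # exact inverse of the standard EDF decode: phys = slope * (dig - dig_min) + phys_min
    slope = 2 * ranges[:, None] / (dig_max - dig_min)
    digital = np.clip(
        np.round((signals + ranges[:, None]) / slope) + dig_min, dig_min, dig_max
    ).astype("<i2")

    header = _main_header(n_records, record_duration_s, ns) + _signal_header(
        labels=channel_labels,
        transducers=["" for _ in range(ns)],
        phys_dims=["uV"] * ns,
        phys_min=[-r for r in ranges],
        phys_max=[r for r in ranges],
        dig_min=[dig_min] * ns,
        dig_max=[dig_max] * ns,
        samples_per_record=[spr] * ns,
    )
    try:
        with open(path, "wb") as fh:
            fh.write(header)
            for r in range(n_records):
                block = digital[:, r * spr : (r + 1) * spr]
                fh.write(block.tobytes())  # channel-major within each record
    except OSError as exc:
        raise OSError(f"failed to write EDF to {path}: {exc}") from exc
    return path


def _tal(onset_s: float, duration_s: float | None, text: str) -> bytes:
    onset = f"+{onset_s:g}".encode("ascii")
    out = onset
    if duration_s is not None:
        out += b"\x15" + f"{duration_s:g}".encode("ascii")
    out += b"\x14" + text.encode("ascii") + b"\x14\x00"
    return out


def write_edf_annotations(
    path: str | Path,
    annotations: list[tuple[float, float, str]],
    record_duration_s: float = 30.0,
) -> Path:
    """Write (onset_s, duration_s, text) annotations as an EDF+C sidecar.

    One annotation per data record; each record starts with its timekeeping
    TAL as the EDF+ spec requires.  ``mne.read_annotations`` reads it back.
    """
    path = Path(path)
    if not annotations:
        raise ValueError("cannot write an empty annotation list")
    records = []
    for i, (onset, duration, text) in enumerate(annotations):
        records.append(_tal(i * record_duration_s, None, "") + _tal(onset, duration, text))
    spr = (max(len(r) for r in records) + 2) // 2 + 1  # samples are 2-byte units
    header = _main_header(
        len(records), record_duration_s, 1, reserved="EDF+C"
    ) + _signal_header(
        labels=["EDF Annotations"],
        transducers=[""],
        phys_dims=[""],
        phys_min=[-1.0],
        phys_max=[1.0],
        dig_min=[-32768],
        dig_max=[32767],
        samples_per_record=[spr],
    )
    try:
        with open(path, "wb") as fh:
            fh.write(header)
            for rec in records:
                fh.write(rec + b"\x00" * (2 * spr - len(rec)))
    except OSError as exc:
        raise OSError(f"failed to write EDF+ annotations to {path}: {exc}") from exc
    return path


def edf_quantization_step_uv(physical_range_uv: float = 250.0) -> float:
    """Worst-case amplitude error of the 16-bit encoding (half a digital step)."""
    return physical_range_uv / 32767.0


def _now_header_fields() -> tuple[str, str]:  # pragma: no cover - unused default hook
    now = datetime.datetime.now()
    return now.strftime("%d.%m.%y"), now.strftime("%H.%M.%S")
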