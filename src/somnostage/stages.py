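"""AASM five-class sleep-stage vocabulary and its fixed integer encoding."""

from __future__ import annotations

from enum import IntEnum


class StageLabel(IntEnum):
    """The five AASM scoring classes with a fixed integer encoding.

    W (wake) = 0, N1 = 1, N2 = 2, N3 = 3 (slow-wave sleep, merging the older
    R&K stages 3 and 4), REM = 4.  The encoding is part of the package contract:
    model outputs, confusion-matrix axes and checkpoint headers all use it.
    """

    W = 0
    N1 = 1
    N2 = 2
    N3 = 3
    REM = 4


N_STAGES = 5

#: Display order and names, index-aligned with the integer encoding.
STAGE_NAMES = ("W", "N1", "N2", "N3", "REM")


def stage_from_name(name: str) -> StageLabel:
    """Look up a stage by its short name (case-insensitive; "R" == "REM")."""
    key = name.strip().upper()
    if key == "R":
        key = "REM"
    try:
        return StageLabel[key]
    except KeyError:
        raise ValueError(f"unknown stage name {name!r}; expected one of {STAGE_NAMES}") from None
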