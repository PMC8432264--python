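"""Cervical disc-level segment labels and ordering.

Six disc levels are analyzed per subject, ordered cranial to caudal:
C2/C3, C3/C4, C4/C5, C5/C6, C6/C7, C7/T1.  For anatomy (the adapted
maximum canal compromise needs one level above and below) the grid is
extended by C1/C2 cranially and T1/T2 caudally.
"""

from __future__ import annotations

SEGMENTS: tuple[str, ...] = ("C2/C3", "C3/C4", "C4/C5", "C5/C6", "C6/C7", "C7/T1")
EXTENDED_LEVELS: tuple[str, ...] = ("C1/C2",) + SEGMENTS + ("T1/T2",)

_SEG_INDEX = {s: i for i, s in enumerate(SEGMENTS)}
_LEVEL_INDEX = {s: i for i, s in enumerate(EXTENDED_LEVELS)}


def segment_index(segment: str) -> int:
    """0-based cranial->caudal index of one of the six analyzed segments."""
    try:
        return _SEG_INDEX[segment]
    except KeyError:
        raise ValueError(f"unknown segment {segment!r}; expected one of {SEGMENTS}") from None


def level_index(level: str) -> int:
    """Index on the extended C1/C2..T1/T2 grid."""
    try:
        return _LEVEL_INDEX[level]
    except KeyError:
        raise ValueError(f"unknown level {level!r}; expected one of {EXTENDED_LEVELS}") from None


def segment_at_offset(stenosis: str, offset: int) -> str | None:
    """Segment `offset` levels caudal (positive) / cranial (negative) of `stenosis`.

    Returns None if the offset falls outside the six analyzed segments.
    """
    i = segment_index(stenosis) + offset
    if 0 <= i < len(SEGMENTS):
        return SEGMENTS[i]
    return None


def flanking_levels(level: str) -> tuple[str, str]:
    """Adjacent disc levels (one cranial, one caudal) on the extended grid."""
    i = level_index(level)
    if i == 0 or i == len(EXTENDED_LEVELS) - 1:
        raise ValueError(f"level {level!r} has no flanking pair on the extended grid")
    return EXTENDED_LEVELS[i - 1], EXTENDED_LEVELS[i + 1]
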