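"""Core data records: velocity curves, subjects, per-segment metric rows."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segments import SEGMENTS

# whole-scan exclusion reasons; segment-level flags use flow_artifact_flag()
MOVEMENT_ARTIFACT = "movement_artifact"
DROPOUT = "dropout"
WITHDRAWAL = "withdrawal"
MULTISEGMENTAL = "multisegmental"
WHOLE_SCAN_FLAGS = (MOVEMENT_ARTIFACT, DROPOUT, WITHDRAWAL, MULTISEGMENTAL)


def flow_artifact_flag(segment: str) -> str:
    """Segment-level flag: that segment's dynamic data is unusable."""
    return f"flow_artifact@{segment}"


def flagged_segments(flags: set[str]) -> set[str]:
    return {f.split("@", 1)[1] for f in flags if f.startswith("flow_artifact@")}


@dataclass
class VelocityCurve:
    """One segment's craniocaudal velocity waveform over one heartbeat.

    ``t`` in ms within [0, hb), ``v`` in cm/s (positive = caudal), ``hb`` the
    heartbeat duration in ms.
    """

    segment: str
    t: np.ndarray
    v: np.ndarray
    hb: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.shape != self.v.shape or self.t.ndim != 1:
            raise ValueError("t and v must be 1-D arrays of equal length")
        if self.n < 8:
            raise ValueError("a velocity curve needs at least 8 timepoints")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if self.t[-1] >= self.hb or self.t[0] < 0:
            raise ValueError("timepoints must lie within [0, hb)")

    @property
    def n(self) -> int:
        return self.t.size


@dataclass
class AnatomyRaw:
    """Measured cross-sectional areas (mm^2) at one disc level."""

    cord_csa: float
    canal_csa: float

    def __post_init__(self) -> None:
        if not (0 < self.cord_csa < self.canal_csa):
            raise ValueError(
                f"need 0 < cord_csa < canal_csa, got {self.cord_csa} / {self.canal_csa}")


@dataclass
class SubjectRecord:
    """One participant: demographics, per-segment curves and anatomy.

    ``anatomy`` is keyed over the extended level grid C1/C2..T1/T2 so that
    canal-compromise neighbors always exist; ``curves`` over the six analyzed
    segments (missing segments simply absent).  The mJOA score is carried as
    inert metadata.
    """

    id: str
    role: str  # "patient" | "control"
    stenosis_level: str | None
    gender: str  # "male" | "female"
    age: float
    hb_duration: float  # ms
    mjoa: int | None = None
    curves: dict[str, VelocityCurve] = field(default_factory=dict)
    anatomy: dict[str, AnatomyRaw] = field(default_factory=dict)
    matched_to: str | None = None
    exclusion_flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.role not in ("patient", "control"):
            raise ValueError(f"role must be patient|control, got {self.role!r}")
        if self.role == "control" and self.stenosis_level is not None:
            raise ValueError("controls must have stenosis_level = None")
        if self.role == "patient" and self.stenosis_level not in SEGMENTS:
            raise ValueError("patients need a stenosis_level among the six segments")
        if self.gender not in ("male", "female"):
            raise ValueError(f"gender must be male|female, got {self.gender!r}")

    @property
    def excluded(self) -> bool:
        """Whole-scan exclusion (segment-level flags do not exclude the subject)."""
        return any(f in self.exclusion_flags for f in WHOLE_SCAN_FLAGS)


@dataclass
class MotionMetrics:
    """The three curve summaries for one segment.

    ``total_displacement`` is None where suppressed for reporting (C2/C3,
    known moderate test-retest reliability there).
    """

    segment: str
    max_velocity: float  # cm/s
    ptp_amplitude: float  # mm/s
    total_displacement: float | None  # mm


@dataclass
class AnatomyMetrics:
    """Anatomical scores for one segment."""

    segment: str
    cord_csa: float
    canal_csa: float
    amcc: float | None
    ascor: float


@dataclass
class IndexSet:
    """Intra-individual ptp-amplitude indices (C2-pAI, C7-pAI) per segment.

    Values are None where the segment's or the reference segment's ptp is
    missing or non-positive.
    """

    c2_pai: dict[str, float | None]
    c7_pai: dict[str, float | None]
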