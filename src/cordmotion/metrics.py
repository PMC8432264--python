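"""Per-curve motion parameters and intra-individual ptp-amplitude indices.

Three parameters summarize one segment's velocity waveform over one
heartbeat: the maximum (caudal) velocity in cm/s, the peak-to-peak amplitude
in mm/s (max minus min velocity, times 10), and the total displacement in mm
(time-integral of the rectified velocity).  Peaks are taken over the sampled
points only — no interpolation — matching the ~40-point acquisition.

The indices reference each segment's ptp-amplitude to the subject's own
value at C2/C3 (C2-pAI) or C7/T1 (C7-pAI); a rise toward the stenotic level
indicates stretching of the interjacent cord tissue, the subsequent drop a
compression.  Total displacement is suppressed at C2/C3 in reports (the
curve value is computable but has known moderate test-retest reliability).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .records import IndexSet, MotionMetrics, SubjectRecord, VelocityCurve
from .segments import SEGMENTS

#: reporting of total displacement is suppressed at this segment
DISPLACEMENT_SUPPRESSED = "C2/C3"

C2_REFERENCE = "C2/C3"
C7_REFERENCE = "C7/T1"


def max_velocity(curve: VelocityCurve) -> float:
    """Highest (signed) craniocaudal velocity among the samples, cm/s."""
    return float(np.max(curve.v))


def ptp_amplitude(curve: VelocityCurve) -> float:
    """Peak-to-peak amplitude in mm/s: 10 * (max - min velocity in cm/s)."""
    return 10.0 * float(np.max(curve.v) - np.min(curve.v))


def total_displacement(curve: VelocityCurve, rule: str = "trapezoid") -> float:
    """Total displacement in mm: integral of |v| over one heartbeat.

    Negative-lobe area is added (not subtracted).  The cardiac cycle is
    closed periodically (the sample at t=hb repeats the first sample) and
    integrated with the trapezoidal rule by default; ``rule="rectangle"``
    uses a plain sample-sum times the sampling interval instead.
    """
    v_mm = 10.0 * np.abs(curve.v)
    if rule == "rectangle":
        return float(np.sum(v_mm) * (curve.hb / curve.n) / 1000.0)
    if rule != "trapezoid":
        raise ValueError(f"unknown integration rule {rule!r}")
    t_s = np.append(curve.t, curve.hb) / 1000.0
    v_closed = np.append(v_mm, v_mm[0])
    return float(np.trapezoid(v_closed, t_s))


def curve_metrics(curve: VelocityCurve, rule: str = "trapezoid") -> MotionMetrics:
    disp = total_displacement(curve, rule)
    return MotionMetrics(
        segment=curve.segment,
        max_velocity=max_velocity(curve),
        ptp_amplitude=ptp_amplitude(curve),
        total_displacement=None if curve.segment == DISPLACEMENT_SUPPRESSED else disp)


def compute_indices(ptp: dict[str, float | None]) -> IndexSet:
    """C2-pAI and C7-pAI from a per-segment ptp-amplitude map (mm/s).

    Missing (None/NaN) or non-positive reference values make the whole index
    family missing, with a warning rather than a division error; a missing
    numerator segment leaves only that entry missing.
    """
    def valid(x):
        return x is not None and np.isfinite(x) and x > 0

    out = {}
    for name, ref, members in (("c2_pai", C2_REFERENCE, SEGMENTS[1:]),
                               ("c7_pai", C7_REFERENCE, SEGMENTS[:-1])):
        ref_val = ptp.get(ref)
        if not valid(ref_val):
            if ref_val is not None and not (isinstance(ref_val, float) and np.isnan(ref_val)):
                warnings.warn(f"reference segment {ref} has non-positive "
                              "ptp-amplitude; index undefined", stacklevel=2)
            out[name] = {s: None for s in members}
            continue
        out[name] = {s: (ptp[s] / ref_val
                         if s in ptp and ptp[s] is not None and np.isfinite(ptp[s])
                         else None)
                     for s in members}
    return IndexSet(c2_pai=out["c2_pai"], c7_pai=out["c7_pai"])


def subject_metrics(subject: SubjectRecord, rule: str = "trapezoid") -> pd.DataFrame:
    """Tidy per-segment metrics for one subject (one row per segment)."""
    rows = []
    ptp_map: dict[str, float | None] = {}
    for seg in SEGMENTS:
        curve = subject.curves.get(seg)
        if curve is None:
            ptp_map[seg] = None
            rows.append({"id": subject.id, "segment": seg,
                         "max_velocity_cm_s": np.nan, "ptp_mm_s": np.nan,
                         "total_displacement_mm": np.nan})
            continue
        m = curve_metrics(curve, rule)
        ptp_map[seg] = m.ptp_amplitude
        rows.append({"id": subject.id, "segment": seg,
                     "max_velocity_cm_s": m.max_velocity,
                     "ptp_mm_s": m.ptp_amplitude,
                     "total_displacement_mm": (np.nan if m.total_displacement is None
                                               else m.total_displacement)})
    idx = compute_indices(ptp_map)
    df = pd.DataFrame(rows)
    df["c2_pai"] = [np.nan if (x := idx.c2_pai.get(s)) is None else x
                    for s in df["segment"]]
    df["c7_pai"] = [np.nan if (x := idx.c7_pai.get(s)) is None else x
                    for s in df["segment"]]
    return df


def cohort_metrics(cohort: list[SubjectRecord], rule: str = "trapezoid") -> pd.DataFrame:
    """Tidy metrics table for a whole cohort, with subject annotations."""
    parts = []
    for subj in cohort:
        df = subject_metrics(subj, rule)
        df.insert(1, "role", subj.role)
        df.insert(2, "stenosis_level", subj.stenosis_level)
        df.insert(3, "gender", subj.gender)
        parts.append(df)
    if not parts:
        return pd.DataFrame(columns=["id", "role", "stenosis_level", "gender",
                                     "segment", "max_velocity_cm_s", "ptp_mm_s",
                                     "total_displacement_mm", "c2_pai", "c7_pai"])
    return pd.concat(parts, ignore_index=True)
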