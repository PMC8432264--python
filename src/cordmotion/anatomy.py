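"""Segmental anatomical scores: CSAs, canal compromise, cord occupation.

The adapted maximum canal compromise (aMCC) at a disc level is the mean of
the two flanking canal cross-sectional areas divided by the canal CSA at the
level itself — ~1 in a uniform canal, >1 at a stenosis, and invariant to
overall body size.  The adapted spinal cord occupation ratio (aSCOR) is the
cord CSA as a percentage of the canal CSA at the same level.  "One segment
above/below" means the adjacent disc levels on the extended C1/C2..T1/T2
grid, so both boundary segments have well-defined neighbors.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .records import AnatomyMetrics, SubjectRecord
from .segments import SEGMENTS, flanking_levels


def compute_amcc(canal_profile: dict[str, float], level: str) -> float | None:
    """(canal CSA one level above + one level below) / (2 * canal CSA at level).

    Returns None with a warning when a flanking level is missing.
    """
    above, below = flanking_levels(level)
    if above not in canal_profile or below not in canal_profile:
        warnings.warn(f"missing neighbor canal CSA for {level}; aMCC undefined",
                      stacklevel=2)
        return None
    at = canal_profile[level]
    if at <= 0:
        raise ValueError(f"canal CSA at {level} must be > 0")
    return (canal_profile[above] + canal_profile[below]) / (2.0 * at)


def compute_ascor(cord_csa: float, canal_csa: float) -> float:
    """Cord CSA as a percentage of canal CSA at the same level."""
    if cord_csa <= 0 or canal_csa <= 0:
        raise ValueError("CSAs must be > 0")
    if cord_csa > canal_csa:
        raise ValueError("cord CSA exceeds canal CSA (segmentation inconsistency)")
    return cord_csa * 100.0 / canal_csa


def subject_anatomy_metrics(subject: SubjectRecord) -> list[AnatomyMetrics]:
    """aMCC/aSCOR for each analyzed segment of one subject."""
    canal = {lvl: a.canal_csa for lvl, a in subject.anatomy.items()}
    out = []
    for seg in SEGMENTS:
        if seg not in subject.anatomy:
            continue
        raw = subject.anatomy[seg]
        out.append(AnatomyMetrics(
            segment=seg, cord_csa=raw.cord_csa, canal_csa=raw.canal_csa,
            amcc=compute_amcc(canal, seg),
            ascor=compute_ascor(raw.cord_csa, raw.canal_csa)))
    return out


def cohort_anatomy_metrics(cohort: list[SubjectRecord]) -> pd.DataFrame:
    """Tidy anatomy-score table for a whole cohort."""
    rows = []
    for subj in cohort:
        for m in subject_anatomy_metrics(subj):
            rows.append({
                "id": subj.id, "role": subj.role,
                "stenosis_level": subj.stenosis_level, "gender": subj.gender,
                "segment": m.segment, "cord_csa_mm2": m.cord_csa,
                "canal_csa_mm2": m.canal_csa,
                "amcc": np.nan if m.amcc is None else m.amcc,
                "ascor_pct": m.ascor})
    return pd.DataFrame(rows, columns=["id", "role", "stenosis_level", "gender",
                                       "segment", "cord_csa_mm2", "canal_csa_mm2",
                                       "amcc", "ascor_pct"])
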