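"""ROI construction, phase-drift correction and curve extraction.

ROIs cover the central third of the craniocaudal span between two
consecutive vertebral-body mid-height rows, intersected with the cord label;
the drift model is linear in time (optionally with a linear spatial
modulation), estimated from static-tissue pixels and subtracted from every
pixel, so corrected static tissue has ~zero temporal slope.
"""

from __future__ import annotations

import numpy as np

from .config import PhantomGeometry
from .records import VelocityCurve
from .segments import SEGMENTS


def build_rois(labels: np.ndarray, landmark_rows: np.ndarray,
               cord_label: int = PhantomGeometry.LABEL_CORD
               ) -> dict[str, np.ndarray | None]:
    """Central-third ROI mask per disc segment.

    For the interval [a, b) between consecutive landmark rows the ROI rows
    are [a + L/3, a + 2L/3) with L = b - a, intersected with the cord mask.
    An empty intersection yields None (missing segment), not an exception.
    """
    lm = np.asarray(landmark_rows)
    if lm.size < len(SEGMENTS) + 1:
        raise ValueError("need at least 7 landmark rows")
    if np.any(np.diff(lm) <= 0):
        raise ValueError("landmark rows must be strictly increasing")
    cord = labels == cord_label
    rows = np.arange(labels.shape[0])
    rois: dict[str, np.ndarray | None] = {}
    for i, seg in enumerate(SEGMENTS):
        a, b = lm[i], lm[i + 1]
        span = b - a
        band = (rows >= a + span / 3.0) & (rows < a + 2.0 * span / 3.0)
        mask = cord & band[:, np.newaxis]
        rois[seg] = mask if mask.any() else None
    return rois


def correct_drift(data: np.ndarray, static_mask: np.ndarray,
                  t: np.ndarray | None = None,
                  spatial: bool = False) -> np.ndarray:
    """Subtract a linear-in-time drift fitted to static-tissue pixels.

    The fitted model is ``b0 + b1*t`` (plus ``t*row`` and ``t*col`` terms
    when ``spatial=True``), estimated by least squares on all static-pixel
    samples and subtracted from every pixel of every frame.
    """
    if not static_mask.any():
        raise ValueError("static-tissue mask is empty; drift not estimable")
    n_t = data.shape[0]
    if t is None:
        t = np.arange(n_t, dtype=float)
    t = np.asarray(t, dtype=float)

    rows, cols = np.nonzero(static_mask)
    y = data[:, rows, cols].ravel()  # frame-major
    tt = np.repeat(t, rows.size)
    design = [np.ones_like(y), tt]
    if spatial:
        design += [tt * np.tile(rows, n_t), tt * np.tile(cols, n_t)]
    X = np.column_stack(design)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)

    r_grid, c_grid = np.meshgrid(np.arange(data.shape[1]),
                                 np.arange(data.shape[2]), indexing="ij")
    drift = beta[0] + beta[1] * t[:, None, None]
    if spatial:
        drift = drift + t[:, None, None] * (beta[2] * r_grid + beta[3] * c_grid)
    return data - drift


def extract_curve(data: np.ndarray, roi: np.ndarray, hb: float,
                  t: np.ndarray | None = None,
                  segment: str = "C2/C3") -> VelocityCurve:
    """Mean ROI velocity per timepoint as a VelocityCurve."""
    if roi is None or not roi.any():
        raise ValueError("ROI is empty")
    if t is None:
        t = np.arange(data.shape[0]) * (hb / data.shape[0])
    return VelocityCurve(segment=segment, t=np.asarray(t, dtype=float),
                         v=data[:, roi].mean(axis=1), hb=hb)


def curves_from_phantom(phantom, spatial_drift: bool = False,
                        static_label: int = PhantomGeometry.LABEL_STATIC
                        ) -> dict[str, VelocityCurve]:
    """Full extraction stage: ROIs -> drift correction -> one curve per segment.

    Segments whose ROI is empty are simply absent from the result.
    """
    rois = build_rois(phantom.labels, phantom.landmark_rows)
    corrected = correct_drift(phantom.data, phantom.labels == static_label,
                              t=phantom.t, spatial=spatial_drift)
    out = {}
    for seg, roi in rois.items():
        if roi is None:
            continue
        out[seg] = extract_curve(corrected, roi, phantom.hb, t=phantom.t,
                                 segment=seg)
    return out
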