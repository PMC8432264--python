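"""Synthetic sagittal phase-image series ("phantom") for one subject.

The phantom emulates a velocity-encoded sagittal acquisition: cord pixels in
each disc interval carry that segment's velocity waveform, CSF and static
tissue are at rest, a global linear phase drift is added to every pixel and
white pixel noise on top.  Image row 0 is cranial.  The label map marks
cord, CSF and static tissue; vertebral-body landmark rows are carried
alongside (the stand-in for an automated anatomical segmentation).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import PhantomGeometry
from .records import SubjectRecord
from .segments import SEGMENTS


@dataclass
class Phantom:
    data: np.ndarray          # (n_timepoints, n_rows, n_cols), cm/s
    labels: np.ndarray        # (n_rows, n_cols), int label map
    landmark_rows: np.ndarray  # vertebral-body mid-height rows, cranial->caudal
    t: np.ndarray             # ms
    hb: float                 # ms
    drift_slope: float        # injected drift, cm/s per ms (ground truth)

    def save_npz(self, path: str | Path) -> None:
        np.savez_compressed(path, data=self.data, labels=self.labels,
                            landmark_rows=self.landmark_rows, t=self.t,
                            hb=np.array([self.hb]),
                            drift_slope=np.array([self.drift_slope]))

    @classmethod
    def load_npz(cls, path: str | Path) -> "Phantom":
        with np.load(path) as z:
            return cls(data=z["data"], labels=z["labels"],
                       landmark_rows=z["landmark_rows"], t=z["t"],
                       hb=float(z["hb"][0]), drift_slope=float(z["drift_slope"][0]))

    def to_nifti(self, image_path: str | Path, label_path: str | Path,
                 geometry: PhantomGeometry | None = None) -> None:
        """Write the series and label map as NIfTI pairs (rows/cols/1/time)."""
        import nibabel as nib

        vox = geometry.voxel_mm if geometry is not None else (0.62, 0.62)
        affine = np.diag([vox[0], vox[1], 1.0, 1.0])
        img = np.transpose(self.data, (1, 2, 0))[:, :, np.newaxis, :]
        nib.save(nib.Nifti1Image(img.astype(np.float32), affine), str(image_path))
        nib.save(nib.Nifti1Image(self.labels[:, :, np.newaxis].astype(np.int16),
                                 affine), str(label_path))


def build_label_map(geometry: PhantomGeometry) -> np.ndarray:
    """Static/cord/CSF label map for the configured geometry."""
    g = geometry
    labels = np.full((g.n_rows, g.n_cols), g.LABEL_STATIC, dtype=np.int16)
    top, bottom = g.landmark_rows[0], g.landmark_rows[-1]
    lo, hi = g.cord_cols
    labels[top:bottom, max(lo - g.csf_width, 0):lo] = g.LABEL_CSF
    labels[top:bottom, hi:min(hi + g.csf_width, g.n_cols)] = g.LABEL_CSF
    labels[top:bottom, lo:hi] = g.LABEL_CORD
    return labels


def generate_phantom(subject: SubjectRecord, geometry: PhantomGeometry,
                     drift_slope_sd: float = 0.0,
                     noise_sd: float | None = None,
                     rng: np.random.Generator | int | None = None,
                     ) -> Phantom:
    """Render a subject's six segment waveforms into a phase-image series.

    ``drift_slope_sd`` is in cm/s per cardiac cycle; the realized slope is
    drawn once per phantom and applied to every pixel.  Raises if any
    segment's curve is missing.
    """
    g = geometry
    g.validate()
    missing = [s for s in SEGMENTS if s not in subject.curves]
    if missing:
        raise ValueError(f"subject {subject.id} is missing curves for {missing}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if noise_sd is None:
        noise_sd = g.pixel_noise_sd

    curves = [subject.curves[s] for s in SEGMENTS]
    n_t = curves[0].n
    hb = curves[0].hb
    t = curves[0].t
    if any(c.n != n_t or c.hb != hb for c in curves):
        raise ValueError("all segment curves must share timing")

    lm = np.asarray(g.landmark_rows)
    if lm.size != len(SEGMENTS) + 1:
        raise ValueError("need exactly 7 landmark rows for 6 disc intervals")
    labels = build_label_map(g)
    data = np.zeros((n_t, g.n_rows, g.n_cols))
    cord = labels == g.LABEL_CORD
    for i, seg in enumerate(SEGMENTS):
        band = np.zeros(g.n_rows, dtype=bool)
        band[lm[i]:lm[i + 1]] = True
        mask = cord & band[:, np.newaxis]
        data[:, mask] = curves[i].v[:, np.newaxis]

    slope = 0.0
    if drift_slope_sd > 0:
        slope = float(rng.normal(0.0, drift_slope_sd)) / hb  # cm/s per ms
        data += slope * t[:, np.newaxis, np.newaxis]
    if noise_sd > 0:
        data += noise_sd * rng.standard_normal(data.shape)
    return Phantom(data=data, labels=labels, landmark_rows=lm, t=t, hb=hb,
                   drift_slope=slope)
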