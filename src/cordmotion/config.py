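"""Cohort and phantom configuration, with defaults calibrated to the
matched-pair DCM study conditions (group sizes, gender mix, per-segment
peak-to-peak amplitude targets, canal/cord CSA profiles).

Amplitude targets are *mean pipeline-measured* peak-to-peak amplitudes in
mm/s.  Patient targets are keyed by segment offset from the stenotic level
(0 = at stenosis, +1 = one caudal, -1 = one cranial, ...); a target may be a
single number or a ``{"male": x, "female": y}`` split.  Segments without an
entry fall back to the control profile, which carries the mild physiological
mid-cervical bump of healthy cords.  Reference-segment targets encode the
intra-individual index means (C2-pAI / C7-pAI) of each group, including the
atypically reduced cranial cord motion of men with a C6/C7 stenosis.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .segments import SEGMENTS, EXTENDED_LEVELS, segment_index

GroupTargets = dict[int, float | dict[str, float]]


def _default_amplitude_profile() -> dict[str, GroupTargets]:
    return {
        "C2/C3": {0: 10.0, 1: 9.0},
        "C3/C4": {-1: 7.5, 0: 11.0, 1: 9.2},
        "C4/C5": {
            -2: {"male": 9.94, "female": 5.98},
            -1: {"male": 11.80, "female": 8.15},
            0: {"male": 15.5, "female": 10.7},
            1: {"male": 14.01, "female": 9.67},
            2: {"male": 10.7, "female": 7.4},
            3: {"male": 8.66, "female": 6.95},
        },
        "C5/C6": {
            -3: {"male": 5.91, "female": 4.65},
            -2: {"male": 10.0, "female": 7.4},
            -1: {"male": 13.06, "female": 9.13},
            0: {"male": 16.3, "female": 11.4},
            1: {"male": 12.03, "female": 8.41},
            2: {"male": 7.38, "female": 5.82},
        },
        "C6/C7": {
            -4: {"male": 4.71, "female": 10.49},
            -3: {"male": 5.8, "female": 11.0},
            -2: {"male": 7.0, "female": 11.5},
            -1: {"male": 9.0, "female": 14.0},
            0: {"male": 15.2, "female": 21.5},
            1: {"male": 8.89, "female": 15.93},
        },
    }


def _default_control_profile() -> dict[str, float]:
    return {"C2/C3": 7.2, "C3/C4": 7.5, "C4/C5": 7.94,
            "C5/C6": 7.89, "C6/C7": 7.2, "C7/T1": 6.6}


@dataclass
class AnatomyConfig:
    """Cross-sectional-area generation: canal baseline plus focal calibration.

    The canal baseline is linear over the extended level grid, so its
    intrinsic canal-compromise score is exactly 1 at every interior level;
    per-group compromise targets then scale the canal at the designated level.
    Controls carry their matched group's (mild) target so that group-wise
    control scores reproduce the study's control columns.
    """

    canal_baseline: dict[str, float] = field(default_factory=lambda: {
        lvl: 255.0 - 10.0 * i for i, lvl in enumerate(EXTENDED_LEVELS)})
    amcc_patient: dict[str, float] = field(default_factory=lambda: {
        "C2/C3": 2.24, "C3/C4": 1.96, "C4/C5": 2.97, "C5/C6": 2.28, "C6/C7": 2.20})
    amcc_control: dict[str, float] = field(default_factory=lambda: {
        "C2/C3": 0.95, "C3/C4": 1.12, "C4/C5": 1.13, "C5/C6": 1.21, "C6/C7": 1.15})
    #: control cord/canal occupation (%) per extended level
    ascor_profile: dict[str, float] = field(default_factory=lambda: dict(zip(
        EXTENDED_LEVELS, (28.0, 30.0, 36.0, 37.0, 41.0, 37.0, 35.0, 33.0))))
    ascor_patient: dict[str, float] = field(default_factory=lambda: {
        "C2/C3": 60.0, "C3/C4": 74.0, "C4/C5": 84.0, "C5/C6": 83.0, "C6/C7": 79.0})
    sigma_severity_patient: float = 0.35
    sigma_severity_control: float = 0.08
    sigma_ascor: float = 0.08
    sigma_size: float = 0.06   # overall body-size scaling of all CSAs
    sigma_level: float = 0.02  # independent per-level canal jitter
    max_occupation: float = 0.97  # hard cap, keeps cord_csa < canal_csa

    def validate(self) -> None:
        for name in ("sigma_severity_patient", "sigma_severity_control",
                     "sigma_ascor", "sigma_size", "sigma_level"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.max_occupation < 1:
            raise ValueError("max_occupation must be in (0, 1)")


@dataclass
class PhantomGeometry:
    """Sagittal phase-image grid.  Row 0 is cranial; rows advance caudally.

    ``landmark_rows`` are the mid-height rows of vertebral bodies C2..T1;
    disc intervals run between consecutive landmarks.  The cord occupies a
    fixed column band flanked by CSF; everything else is static tissue.
    """

    n_rows: int = 120
    n_cols: int = 48
    landmark_rows: tuple[int, ...] = (12, 28, 44, 60, 76, 92, 108)
    cord_cols: tuple[int, int] = (20, 28)
    csf_width: int = 4
    pixel_noise_sd: float = 0.15  # cm/s
    voxel_mm: tuple[float, float] = (0.62, 0.62)

    LABEL_STATIC = 0
    LABEL_CORD = 1
    LABEL_CSF = 2

    def validate(self) -> None:
        if len(self.landmark_rows) < 7:
            raise ValueError("need >= 7 vertebral landmark rows (C2..T1)")
        if any(b <= a for a, b in zip(self.landmark_rows, self.landmark_rows[1:])):
            raise ValueError("landmark rows must be strictly increasing (cranial->caudal)")
        if not (0 <= self.landmark_rows[0] and self.landmark_rows[-1] < self.n_rows):
            raise ValueError("landmark rows must lie inside the image grid")
        lo, hi = self.cord_cols
        if not (0 <= lo < hi <= self.n_cols):
            raise ValueError("cord column band must lie inside the image grid")


@dataclass
class CohortConfig:
    """Everything the synthetic-cohort generator needs."""

    group_sizes: dict[str, int] = field(default_factory=lambda: {
        "C2/C3": 2, "C3/C4": 6, "C4/C5": 14, "C5/C6": 33, "C6/C7": 10})
    gender_fractions: dict[str, float] = field(default_factory=lambda: {
        "C2/C3": 0.5, "C3/C4": 1.0, "C4/C5": 9 / 14, "C5/C6": 14 / 33, "C6/C7": 0.6})
    age_means_sd: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "C2/C3": (57.0, 8.0), "C3/C4": (64.0, 10.0), "C4/C5": (65.0, 9.0),
        "C5/C6": (53.0, 12.0), "C6/C7": (54.0, 12.0)})
    mjoa_means_sd: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "C2/C3": (18.0, 0.5), "C3/C4": (14.5, 3.2), "C4/C5": (15.85, 2.2),
        "C5/C6": (16.47, 1.8), "C6/C7": (15.4, 2.1)})
    hb_mean_sd: tuple[float, float] = (920.0, 140.0)
    n_timepoints: int = 40
    amplitude_profile: dict[str, GroupTargets] = field(
        default_factory=_default_amplitude_profile)
    control_profile: dict[str, float] = field(default_factory=_default_control_profile)
    #: peak-sharpness factor per gender (>=1 men: sharper; <1 women: flattened,
    #: prolonged sinusoid at equal displacement)
    gender_shape: dict[str, float] = field(default_factory=lambda: {
        "male": 1.3, "female": 0.8})
    base_exponent: float = 7.0
    asymmetry: float = 0.65
    sigma_subject: float = 0.42   # log-SD of the shared per-subject motion scale
    sigma_segment: float = 0.02   # log-SD of independent per-segment jitter
    noise_sd: float = 0.05        # cm/s, additive sample noise on curves
    drift_slope_sd: float = 0.2   # cm/s per cardiac cycle, phantom phase drift
    age_match_tol: float = 3.0    # years, |patient age - control age| bound
    anatomy: AnatomyConfig = field(default_factory=AnatomyConfig)
    phantom: PhantomGeometry = field(default_factory=PhantomGeometry)
    seed: int | None = None

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in SEGMENTS:
                raise ValueError(f"unknown stenosis group {g!r}")
            if n <= 0:
                raise ValueError(f"group size for {g} must be > 0, got {n}")
        for g, f in self.gender_fractions.items():
            if not 0 <= f <= 1:
                raise ValueError(f"gender fraction for {g} must be in [0,1]")
        if self.n_timepoints < 8:
            raise ValueError("n_timepoints must be >= 8")
        for name in ("sigma_subject", "sigma_segment", "noise_sd",
                     "drift_slope_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.hb_mean_sd[0] <= 0 or self.hb_mean_sd[1] < 0:
            raise ValueError("heartbeat mean must be > 0 and SD >= 0")
        for g in self.group_sizes:
            if g not in self.gender_fractions or g not in self.age_means_sd:
                raise ValueError(f"group {g} missing gender fraction or age parameters")
        self.anatomy.validate()
        self.phantom.validate()

    # -- target resolution --------------------------------------------------

    def target_ptp(self, role: str, group: str | None, gender: str, segment: str) -> float:
        """Mean measured ptp-amplitude target (mm/s) for one subject/segment."""
        if role == "patient":
            offset = segment_index(segment) - segment_index(group)
            entry = self.amplitude_profile.get(group, {}).get(offset)
            if entry is not None:
                return entry[gender] if isinstance(entry, dict) else float(entry)
        return float(self.control_profile[segment])

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        # JSON object keys must be strings; offsets are ints
        d["amplitude_profile"] = {
            g: {str(off): v for off, v in prof.items()}
            for g, prof in d["amplitude_profile"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "anatomy" in d and isinstance(d["anatomy"], dict):
            d["anatomy"] = AnatomyConfig(**d["anatomy"])
        if "phantom" in d and isinstance(d["phantom"], dict):
            d["phantom"] = PhantomGeometry(
                **{k: tuple(v) if isinstance(v, list) else v
                   for k, v in d["phantom"].items()})
        if "amplitude_profile" in d:
            d["amplitude_profile"] = {
                g: {int(off): v for off, v in prof.items()}
                for g, prof in d["amplitude_profile"].items()}
        for key in ("hb_mean_sd",):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        for key in ("age_means_sd", "mjoa_means_sd"):
            if key in d:
                d[key] = {g: tuple(v) for g, v in d[key].items()}
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (json.dumps(self.to_dict(), indent=2) if path.suffix == ".json"
                else yaml.safe_dump(self.to_dict(), sort_keys=False))
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "CohortConfig":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)

    def hash(self) -> str:
        """Stable short digest of the full configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def default_config(seed: int | None = None) -> CohortConfig:
    """The calibrated study-condition configuration (full five-group cohort)."""
    cfg = CohortConfig(seed=seed)
    cfg.validate()
    return cfg
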