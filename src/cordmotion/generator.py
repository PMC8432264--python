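"""Synthetic matched-pair cohort generation and exclusion handling.

Each patient gets one age- and gender-matched control.  Per-segment velocity
waveforms are drawn from the single-oscillation family with a shared
log-normal per-subject motion scale (so segments co-vary within a subject,
which is what makes the intra-individual indices tight) plus a small
independent per-segment jitter; amplitudes are calibrated in
waveform-parameter space so that the *pipeline-measured* group means land on
the configured targets.  Cross-sectional-area profiles are drawn around a
linear canal baseline with a focal compromise at the designated level.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np

from .config import CohortConfig, default_config
from .records import (AnatomyRaw, SubjectRecord, MOVEMENT_ARTIFACT, DROPOUT,
                      WITHDRAWAL, MULTISEGMENTAL, WHOLE_SCAN_FLAGS,
                      flow_artifact_flag, flagged_segments)
from .segments import SEGMENTS, EXTENDED_LEVELS, flanking_levels
from .waveforms import (calibrated_mean_ptp, generate_waveform, shape_exponent)


def _lognormal(rng: np.random.Generator, sigma: float, size=None):
    """Log-normal factor(s) with mean exactly 1."""
    if sigma == 0:
        return 1.0 if size is None else np.ones(size)
    return np.exp(sigma * rng.standard_normal(size) - sigma ** 2 / 2.0)


def _draw_heartbeat(rng: np.random.Generator, cfg: CohortConfig) -> float:
    mean, sd = cfg.hb_mean_sd
    return float(np.clip(rng.normal(mean, sd), 500.0, 1600.0))


def _draw_mjoa(rng: np.random.Generator, cfg: CohortConfig, group: str) -> int:
    mean, sd = cfg.mjoa_means_sd.get(group, (16.0, 2.0))
    return int(np.clip(round(rng.normal(mean, sd)), 0, 18))


def _draw_anatomy(rng: np.random.Generator, cfg: CohortConfig, role: str,
                  group: str) -> dict[str, AnatomyRaw]:
    """CSA profile over the extended level grid with focal canal compromise."""
    ana = cfg.anatomy
    size = float(_lognormal(rng, ana.sigma_size))
    canal = {lvl: ana.canal_baseline[lvl] * size * float(_lognormal(rng, ana.sigma_level))
             for lvl in EXTENDED_LEVELS}
    if role == "patient":
        target = ana.amcc_patient.get(group, 1.0)
        sev_sigma = ana.sigma_severity_patient
    else:
        target = ana.amcc_control.get(group, 1.0)
        sev_sigma = ana.sigma_severity_control
    severity = target * float(_lognormal(rng, sev_sigma))
    canal[group] = canal[group] / max(severity, 1e-6)
    profile: dict[str, AnatomyRaw] = {}
    for lvl in EXTENDED_LEVELS:
        occ = ana.ascor_profile[lvl] / 100.0
        if role == "patient" and lvl == group:
            occ = ana.ascor_patient.get(group, ana.ascor_profile[lvl]) / 100.0
        occ = min(occ * float(_lognormal(rng, ana.sigma_ascor)), ana.max_occupation)
        profile[lvl] = AnatomyRaw(cord_csa=canal[lvl] * occ, canal_csa=canal[lvl])
    return profile


def _draw_curves(rng: np.random.Generator, cfg: CohortConfig, role: str,
                 group: str, gender: str, hb: float) -> dict:
    shape = cfg.gender_shape[gender]
    exponent = shape_exponent(shape, cfg.base_exponent)
    sigma_total = math.hypot(cfg.sigma_subject, cfg.sigma_segment)
    subject_scale = float(_lognormal(rng, cfg.sigma_subject))
    curves = {}
    for seg in SEGMENTS:
        target = cfg.target_ptp(role, group, gender, seg)
        mean_amp = calibrated_mean_ptp(target, exponent, cfg.asymmetry,
                                       cfg.n_timepoints, 10.0 * cfg.noise_sd,
                                       sigma_total)
        ptp0 = mean_amp * subject_scale * float(_lognormal(rng, cfg.sigma_segment))
        curves[seg] = generate_waveform(
            ptp0, hb, shape_factor=shape, n_timepoints=cfg.n_timepoints,
            noise_sd=cfg.noise_sd, rng=rng, segment=seg,
            base_exponent=cfg.base_exponent, asymmetry=cfg.asymmetry)
    return curves


def generate_cohort(config: CohortConfig | None = None,
                    seed: int | None = None) -> list[SubjectRecord]:
    """Generate patients per configured group plus one matched control each.

    Deterministic under a fixed (config, seed); ``seed`` overrides
    ``config.seed``.
    """
    cfg = config if config is not None else default_config()
    cfg.validate()
    if seed is None:
        seed = cfg.seed
    if seed is None:
        raise ValueError("a seed is required (pass seed= or set config.seed)")
    rng = np.random.default_rng(seed)

    cohort: list[SubjectRecord] = []
    counter = 0
    groups = [g for g in SEGMENTS if g in cfg.group_sizes]
    for group in groups:
        n = cfg.group_sizes[group]
        n_male = int(round(n * cfg.gender_fractions[group]))
        age_mean, age_sd = cfg.age_means_sd[group]
        for k in range(n):
            counter += 1
            gender = "male" if k < n_male else "female"
            age = float(np.clip(rng.normal(age_mean, age_sd), 18.0, 90.0))
            hb = _draw_heartbeat(rng, cfg)
            patient = SubjectRecord(
                id=f"P{counter:03d}", role="patient", stenosis_level=group,
                gender=gender, age=age, hb_duration=hb,
                mjoa=_draw_mjoa(rng, cfg, group),
                curves=_draw_curves(rng, cfg, "patient", group, gender, hb),
                anatomy=_draw_anatomy(rng, cfg, "patient", group),
                matched_to=f"K{counter:03d}")
            ctrl_age = float(np.clip(
                age + rng.uniform(-cfg.age_match_tol, cfg.age_match_tol), 18.0, 90.0))
            ctrl_hb = _draw_heartbeat(rng, cfg)
            control = SubjectRecord(
                id=f"K{counter:03d}", role="control", stenosis_level=None,
                gender=gender, age=ctrl_age, hb_duration=ctrl_hb,
                curves=_draw_curves(rng, cfg, "control", group, gender, ctrl_hb),
                anatomy=_draw_anatomy(rng, cfg, "control", group),
                matched_to=patient.id)
            cohort.extend([patient, control])
    return cohort


# ---------------------------------------------------------------------------
# the recorded exclusion flow: 80 consecutive patients -> 65 included

_EXTRA_FLAGS = ([MOVEMENT_ARTIFACT] * 9 + [DROPOUT] + [WITHDRAWAL]
                + [MULTISEGMENTAL] * 4)
_EXTRA_GROUPS = ("C5/C6", "C4/C5", "C6/C7", "C3/C4", "C2/C3")
#: (group, flagged segments): one flow-artifact case at C2/C3 per listed
#: group, and one case with artifacts at both C2/C3 and C3/C4.
_SEGMENT_ARTIFACTS = (
    ("C3/C4", ("C2/C3",)),
    ("C5/C6", ("C2/C3",)),
    ("C6/C7", ("C2/C3",)),
    ("C4/C5", ("C2/C3", "C3/C4")),
)


def study_cohort(config: CohortConfig | None = None,
                 seed: int | None = None) -> list[SubjectRecord]:
    """The 80-patient consecutive-recruitment fixture with recorded flags.

    The 65 includable patients (plus matched controls) follow the configured
    group sizes; 15 additional patients carry whole-scan exclusion flags
    (9 overall MRI artifact, 1 scan dropout, 1 consent withdrawal, 4
    multisegmental stenosis) and four included patients carry segment-level
    flow-artifact flags.
    """
    cfg = config if config is not None else default_config()
    cohort = generate_cohort(cfg, seed=seed)
    rng = np.random.default_rng((seed if seed is not None else cfg.seed or 0) + 86_028_157)

    extras: list[SubjectRecord] = []
    for i, flag in enumerate(_EXTRA_FLAGS):
        group = _EXTRA_GROUPS[i % len(_EXTRA_GROUPS)]
        hb = _draw_heartbeat(rng, cfg)
        age_mean, age_sd = cfg.age_means_sd.get(group, (58.0, 10.0))
        extras.append(SubjectRecord(
            id=f"X{i + 1:03d}", role="patient", stenosis_level=group,
            gender="male" if i % 2 == 0 else "female",
            age=float(np.clip(rng.normal(age_mean, age_sd), 18.0, 90.0)),
            hb_duration=hb, mjoa=_draw_mjoa(rng, cfg, group),
            exclusion_flags={flag}))

    for group, segs in _SEGMENT_ARTIFACTS:
        for subj in cohort:
            if (subj.role == "patient" and subj.stenosis_level == group
                    and not subj.exclusion_flags):
                subj.exclusion_flags.update(flow_artifact_flag(s) for s in segs)
                break
    return cohort + extras


def apply_exclusions(cohort: list[SubjectRecord]
                     ) -> tuple[list[SubjectRecord], dict]:
    """Apply whole-scan and segment-level exclusion flags.

    Subjects with a whole-scan flag are removed; a segment-level
    flow-artifact flag only drops that segment's curve (records are copied,
    the input cohort is untouched).  Returns the included subjects and a
    report with per-reason counts and the per-segment missing markers.
    """
    included: list[SubjectRecord] = []
    reason_counts = {f: 0 for f in WHOLE_SCAN_FLAGS}
    missing_segments: list[tuple[str, str]] = []
    for subj in cohort:
        whole = [f for f in WHOLE_SCAN_FLAGS if f in subj.exclusion_flags]
        if whole:
            for f in whole:
                reason_counts[f] += 1
            continue
        bad = flagged_segments(subj.exclusion_flags)
        if bad:
            keep = {s: c for s, c in subj.curves.items() if s not in bad}
            subj = replace(subj, curves=keep)
            missing_segments.extend((subj.id, s) for s in sorted(bad))
        included.append(subj)
    report = {
        "n_input": len(cohort),
        "n_included": len(included),
        "n_patients_included": sum(1 for s in included if s.role == "patient"),
        "reason_counts": reason_counts,
        "missing_segments": missing_segments,
    }
    return included, report
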