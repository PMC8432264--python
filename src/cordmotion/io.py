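"""CSV serialization of cohorts, curves, anatomy and metrics.

One subjects table (id, role, stenosis_level, gender, age_years, hb_ms,
mjoa, matched_to, flags), one long-format curves table (id, segment, t_ms,
v_cm_s) and one anatomy table (id, level, cord_csa_mm2, canal_csa_mm2).
The same dialects are written by the generator and read by the downstream
stages, so measured and synthetic inputs are interchangeable.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .records import AnatomyRaw, SubjectRecord, VelocityCurve


def subjects_frame(cohort: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "id": s.id, "role": s.role,
        "stenosis_level": s.stenosis_level or "",
        "gender": s.gender, "age_years": s.age, "hb_ms": s.hb_duration,
        "mjoa": "" if s.mjoa is None else s.mjoa,
        "matched_to": s.matched_to or "",
        "flags": ";".join(sorted(s.exclusion_flags)),
    } for s in cohort])


def curves_frame(cohort: list[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for s in cohort:
        for seg, c in s.curves.items():
            rows.append(pd.DataFrame({"id": s.id, "segment": seg,
                                      "t_ms": c.t, "v_cm_s": c.v}))
    if not rows:
        return pd.DataFrame(columns=["id", "segment", "t_ms", "v_cm_s"])
    return pd.concat(rows, ignore_index=True)


def anatomy_frame(cohort: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "id": s.id, "level": lvl,
        "cord_csa_mm2": a.cord_csa, "canal_csa_mm2": a.canal_csa,
    } for s in cohort for lvl, a in s.anatomy.items()])


def write_cohort(cohort: list[SubjectRecord], outdir: str | Path) -> dict[str, Path]:
    """Write the three cohort tables; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"subjects": outdir / "subjects.csv",
             "curves": outdir / "curves.csv",
             "anatomy": outdir / "anatomy.csv"}
    subjects_frame(cohort).to_csv(paths["subjects"], index=False)
    curves_frame(cohort).to_csv(paths["curves"], index=False)
    anatomy_frame(cohort).to_csv(paths["anatomy"], index=False)
    return paths


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{name} table is missing columns {missing}")


def read_cohort(subjects_csv: str | Path, curves_csv: str | Path | None = None,
                anatomy_csv: str | Path | None = None) -> list[SubjectRecord]:
    """Assemble SubjectRecords back from the cohort tables."""
    subjects = pd.read_csv(subjects_csv, keep_default_na=False)
    _require_columns(subjects, ("id", "role", "stenosis_level", "gender",
                                "age_years", "hb_ms"), "subjects")
    curves_by_id: dict[str, dict[str, VelocityCurve]] = {}
    if curves_csv is not None:
        curves = pd.read_csv(curves_csv)
        _require_columns(curves, ("id", "segment", "t_ms", "v_cm_s"), "curves")
        hb_of = dict(zip(subjects["id"], subjects["hb_ms"]))
        for (sid, seg), part in curves.groupby(["id", "segment"], sort=False):
            if sid not in hb_of:
                raise ValueError(f"curves table references unknown subject {sid!r}")
            part = part.sort_values("t_ms")
            curves_by_id.setdefault(sid, {})[seg] = VelocityCurve(
                segment=seg, t=part["t_ms"].to_numpy(),
                v=part["v_cm_s"].to_numpy(), hb=float(hb_of[sid]))
    anatomy_by_id: dict[str, dict[str, AnatomyRaw]] = {}
    if anatomy_csv is not None:
        anatomy = pd.read_csv(anatomy_csv)
        _require_columns(anatomy, ("id", "level", "cord_csa_mm2",
                                   "canal_csa_mm2"), "anatomy")
        for row in anatomy.itertuples(index=False):
            anatomy_by_id.setdefault(row.id, {})[row.level] = AnatomyRaw(
                cord_csa=float(row.cord_csa_mm2), canal_csa=float(row.canal_csa_mm2))
    out = []
    for row in subjects.itertuples(index=False):
        mjoa = row.mjoa if "mjoa" in subjects.columns else ""
        flags = row.flags if "flags" in subjects.columns else ""
        out.append(SubjectRecord(
            id=row.id, role=row.role,
            stenosis_level=row.stenosis_level or None,
            gender=row.gender, age=float(row.age_years),
            hb_duration=float(row.hb_ms),
            mjoa=int(float(mjoa)) if str(mjoa) != "" else None,
            curves=curves_by_id.get(row.id, {}),
            anatomy=anatomy_by_id.get(row.id, {}),
            matched_to=(row.matched_to or None) if "matched_to" in subjects.columns else None,
            exclusion_flags=set(str(flags).split(";")) if str(flags) else set()))
    return out


def canal_profiles(cohort: list[SubjectRecord]) -> dict[str, dict[str, float]]:
    """Per-subject canal CSA profile maps (level -> mm^2)."""
    return {s.id: {lvl: a.canal_csa for lvl, a in s.anatomy.items()}
            for s in cohort}
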