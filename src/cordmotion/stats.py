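"""Cohort statistics: distribution-gated two-group tests, within-subject
segment contrasts, multi-group comparisons, and regression with
dual-criterion outlier exclusion.

Two-group comparisons are gated by Shapiro-Wilk normality on each group
(default alpha 0.05): both normal -> t-test, otherwise Mann-Whitney U (or
their paired analogues).  Within-subject segment profiles use a
repeated-measures ANOVA with a sphericity check (Greenhouse-Geisser
correction when violated; outliers are not excluded) followed by
Bonferroni-adjusted paired contrasts cranial-vs-stenosis and
stenosis-vs-caudal.  Regression models (motion parameter at stenosis on
severity score, age and gender) are ordinary least squares; a point is
excluded only when flagged by BOTH Cook's distance (> 4/n) and leverage
(> 2(k+1)/n), and the fit is repeated once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .records import SubjectRecord
from .segments import SEGMENTS, segment_index

DEFAULT_ALPHA_NORMALITY = 0.05


@dataclass
class TestResult:
    label: str
    test_used: str  # t | mann_whitney | rm_anova | kruskal_wallis | descriptive
    statistic: float | None
    p_value: float | None
    groups: list[dict] = field(default_factory=list)  # name, n, mean, sd
    gate: dict = field(default_factory=dict)          # normality / sphericity record
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RegressionResult:
    outcome: str
    predictors: list[str]
    params: dict[str, float]
    pvalues: dict[str, float]
    r_squared: float
    excluded_points: list
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def _summary(name: str, x: np.ndarray) -> dict:
    return {"name": name, "n": int(x.size),
            "mean": float(np.mean(x)) if x.size else np.nan,
            "sd": float(np.std(x, ddof=1)) if x.size > 1 else np.nan}


def _shapiro_gate(x: np.ndarray, alpha: float) -> dict:
    if np.ptp(x) == 0:  # degenerate constant sample: clearly non-normal gate
        return {"W": np.nan, "p": 0.0, "normal": False}
    w, p = sps.shapiro(x)
    return {"W": float(w), "p": float(p), "normal": bool(p > alpha)}


def compare_two_groups(a, b, alpha_normality: float = DEFAULT_ALPHA_NORMALITY,
                       paired: bool = False, label: str = "",
                       names: tuple[str, str] = ("a", "b")) -> TestResult:
    """Shapiro-Wilk-gated unpaired t / Mann-Whitney comparison of two samples.

    With fewer than 3 values in either group only descriptives are returned.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    groups = [_summary(names[0], a), _summary(names[1], b)]
    if min(a.size, b.size) < 3 or (paired and a.size != b.size):
        return TestResult(label=label, test_used="descriptive", statistic=None,
                          p_value=None, groups=groups,
                          gate={"reason": "insufficient n"})
    gate = {names[0]: _shapiro_gate(a, alpha_normality),
            names[1]: _shapiro_gate(b, alpha_normality),
            "alpha": alpha_normality, "paired": paired}
    normal = gate[names[0]]["normal"] and gate[names[1]]["normal"]
    if normal:
        stat, p = (sps.ttest_rel(a, b) if paired else sps.ttest_ind(a, b))[:2]
        used = "t"
    elif paired:
        if np.ptp(a - b) == 0:
            return TestResult(label=label, test_used="wilcoxon", statistic=0.0,
                              p_value=1.0, groups=groups, gate=gate,
                              extra={"all_tied": True})
        stat, p = sps.wilcoxon(a, b)
        used = "wilcoxon"
    else:
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        used = "mann_whitney"
    return TestResult(label=label, test_used=used, statistic=float(stat),
                      p_value=float(p), groups=groups, gate=gate)


def within_subject_segments(wide: pd.DataFrame, stenosis: str,
                            alpha: float = 0.05) -> dict:
    """Repeated-measures segment comparison with cranial/caudal contrasts.

    ``wide`` has one row per subject and one (ordered) column per segment;
    rows with any missing segment are dropped (complete-case).  Returns the
    omnibus rm-ANOVA plus Bonferroni-adjusted paired contrasts between the
    most cranial column and the stenotic column, and between the stenotic
    and the most caudal column.
    """
    import pingouin as pg

    wide = wide.dropna(axis=0)
    if len(wide) < 3:
        raise ValueError("need at least 3 complete cases for the "
                         "repeated-measures comparison")
    if stenosis not in wide.columns:
        raise ValueError(f"stenosis column {stenosis!r} not among segments")
    long = wide.reset_index(names="subject").melt(
        id_vars="subject", var_name="segment", value_name="value")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.rm_anova(data=long, dv="value", within="segment",
                          subject="subject", correction="auto", detailed=False)
    row = aov.iloc[0]
    cols = {c.replace("-", "_"): c for c in aov.columns}
    gg_col = cols.get("p_GG_corr")
    corrected = gg_col is not None and not np.isnan(row[gg_col])
    gate = {"sphericity_checked": "sphericity" in cols,
            "gg_correction_applied": bool(corrected)}
    if "sphericity" in cols:
        gate["sphericity"] = bool(row[cols["sphericity"]])
    p_omni = float(row[gg_col]) if corrected else float(row[cols["p_unc"]])
    anova = TestResult(
        label="segments rm-anova", test_used="rm_anova",
        statistic=float(row["F"]), p_value=p_omni,
        groups=[_summary(c, wide[c].to_numpy()) for c in wide.columns],
        gate=gate, extra={"n_subjects": int(len(wide))})

    contrasts = []
    pairs = []
    if wide.columns[0] != stenosis:
        pairs.append((wide.columns[0], stenosis, "cranial_vs_stenosis"))
    if wide.columns[-1] != stenosis:
        pairs.append((stenosis, wide.columns[-1], "stenosis_vs_caudal"))
    m = len(pairs)
    for c1, c2, name in pairs:
        stat, p = sps.ttest_rel(wide[c1], wide[c2])
        contrasts.append(TestResult(
            label=name, test_used="t",
            statistic=float(stat), p_value=min(1.0, float(p) * m),
            groups=[_summary(c1, wide[c1].to_numpy()),
                    _summary(c2, wide[c2].to_numpy())],
            gate={"paired": True, "bonferroni_m": m, "p_unadjusted": float(p)}))
    return {"anova": anova, "contrasts": contrasts, "n_contrasts": m}


def compare_multi_groups(samples: dict[str, np.ndarray],
                         label: str = "") -> TestResult:
    """Kruskal-Wallis comparison of two or more unrelated samples."""
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
    for k, v in arrays.items():
        if v.size == 0:
            raise ValueError(f"group {k!r} is empty")
    groups = [_summary(k, v) for k, v in arrays.items()]
    pooled = np.concatenate(list(arrays.values()))
    if np.ptp(pooled) == 0:
        return TestResult(label=label, test_used="kruskal_wallis",
                          statistic=None, p_value=None, groups=groups,
                          extra={"all_tied": True})
    stat, p = sps.kruskal(*arrays.values())
    return TestResult(label=label, test_used="kruskal_wallis",
                      statistic=float(stat), p_value=float(p), groups=groups)


def predict_motion(data: pd.DataFrame, outcome: str, severity: str,
                   age: str = "age", gender: str = "gender",
                   cooks_threshold: float = 1.0,
                   leverage_factor: float = 2.0) -> RegressionResult:
    """OLS prediction of a motion parameter with dual-criterion outlier rule.

    ``gender`` may be a male/female string column (encoded male=1).  Points
    flagged by BOTH Cook's distance > cooks_threshold and leverage >
    leverage_factor*(k+1)/n are removed and the model refitted once.  The
    absolute Cook's cut-off of 1 (rather than the looser 4/n rule of thumb)
    keeps false exclusions on clean data — and hence the procedure's type-I
    error — at the nominal level while still catching gross outliers.
    """
    import statsmodels.api as sm

    df = data[[outcome, severity, age, gender]].copy()
    if df[gender].dtype == object:
        df[gender] = (df[gender] == "male").astype(float)
    df = df.dropna()
    if len(df) < 8:
        raise ValueError("need at least 8 complete observations")
    predictors = []
    for col in (severity, age, gender):
        if np.ptp(df[col].to_numpy(dtype=float)) == 0:
            warnings.warn(f"predictor {col!r} is constant and was dropped",
                          stacklevel=2)
        else:
            predictors.append(col)
    if not predictors:
        raise ValueError("all predictors are constant")

    def _fit(frame):
        X = sm.add_constant(frame[predictors].astype(float))
        return sm.OLS(frame[outcome].astype(float), X).fit()

    res = _fit(df)
    n, k = len(df), len(predictors)
    infl = res.get_influence()
    cooks = infl.cooks_distance[0]
    lev = infl.hat_matrix_diag
    cooks_thr = cooks_threshold
    lev_thr = leverage_factor * (k + 1) / n
    both = (cooks > cooks_thr) & (lev > lev_thr)
    excluded = list(df.index[both])
    if excluded:
        res = _fit(df.drop(index=excluded))
    resid = np.asarray(res.resid)
    diagnostics = {
        "n_used": int(res.nobs), "cooks_threshold": cooks_thr,
        "leverage_threshold": lev_thr,
        "resid_shapiro_p": float(sps.shapiro(resid)[1]) if np.ptp(resid) > 0 else np.nan,
        "condition_number": float(np.linalg.cond(res.model.exog)),
    }
    return RegressionResult(
        outcome=outcome, predictors=predictors,
        params={k_: float(v) for k_, v in res.params.items()},
        pvalues={k_: float(v) for k_, v in res.pvalues.items()},
        r_squared=float(res.rsquared), excluded_points=excluded,
        diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# cohort tables

MOTION_COLUMNS = ("ptp_mm_s", "max_velocity_cm_s", "total_displacement_mm",
                  "c2_pai", "c7_pai")


def _group_of(cohort: list[SubjectRecord]) -> dict[str, str | None]:
    """Subject id -> stenosis group (controls take their matched patient's)."""
    stenosis = {s.id: s.stenosis_level for s in cohort}
    out = {}
    for s in cohort:
        out[s.id] = (s.stenosis_level if s.role == "patient"
                     else stenosis.get(s.matched_to))
    return out


def annotate_groups(metrics: pd.DataFrame, cohort: list[SubjectRecord]) -> pd.DataFrame:
    """Copy of a tidy metrics table with a stenosis-group column (controls
    inherit their matched patient's group)."""
    out = metrics.copy()
    out["group"] = out["id"].map(_group_of(cohort))
    return out


def build_tables(cohort: list[SubjectRecord], metrics: pd.DataFrame,
                 anatomy: pd.DataFrame | None = None, paired: bool = False,
                 alpha_normality: float = DEFAULT_ALPHA_NORMALITY) -> dict:
    """Per-group, per-segment summary tables with gated comparisons.

    Returns ``motion`` (patients vs matched controls per segment and metric,
    with stenosis-relative offsets), ``gender`` (men vs women among patients
    per segment and metric) and, when anatomy scores are given, ``anatomy``
    (aMCC/aSCOR at the stenotic level, patients vs controls).  Empty cohort
    -> empty tables.
    """
    if not len(metrics):
        return {"motion": pd.DataFrame(), "gender": pd.DataFrame(),
                "anatomy": pd.DataFrame(), "tests": []}
    group_of = _group_of(cohort)
    metrics = metrics.copy()
    metrics["group"] = metrics["id"].map(group_of)
    tests: list[TestResult] = []

    def compare(label, a, b, names):
        res = compare_two_groups(a, b, alpha_normality=alpha_normality,
                                 paired=False, label=label, names=names)
        tests.append(res)
        return res

    motion_rows = []
    for group in sorted(metrics["group"].dropna().unique(), key=segment_index):
        gm = metrics[metrics["group"] == group]
        for seg in SEGMENTS:
            sm_ = gm[gm["segment"] == seg]
            pat = sm_[sm_["role"] == "patient"]
            ctl = sm_[sm_["role"] == "control"]
            for metric in MOTION_COLUMNS:
                a = pat[metric].dropna().to_numpy()
                b = ctl[metric].dropna().to_numpy()
                if a.size == 0 and b.size == 0:
                    continue
                res = compare(f"{group} {seg} {metric} patients-vs-controls",
                              a, b, ("patients", "controls"))
                motion_rows.append({
                    "group": group, "segment": seg,
                    "offset": segment_index(seg) - segment_index(group),
                    "metric": metric,
                    "patient_mean": res.groups[0]["mean"],
                    "patient_sd": res.groups[0]["sd"], "patient_n": res.groups[0]["n"],
                    "control_mean": res.groups[1]["mean"],
                    "control_sd": res.groups[1]["sd"], "control_n": res.groups[1]["n"],
                    "test_used": res.test_used, "p_value": res.p_value})
        # men vs women among patients, per segment/metric
    gender_rows = []
    for group in sorted(metrics["group"].dropna().unique(), key=segment_index):
        gm = metrics[(metrics["group"] == group) & (metrics["role"] == "patient")]
        single_gender = gm["gender"].nunique() < 2
        for seg in SEGMENTS:
            sm_ = gm[gm["segment"] == seg]
            for metric in MOTION_COLUMNS:
                men = sm_[sm_["gender"] == "male"][metric].dropna().to_numpy()
                women = sm_[sm_["gender"] == "female"][metric].dropna().to_numpy()
                if men.size + women.size == 0:
                    continue
                if single_gender:
                    row_p, used = np.nan, "not_applicable"
                else:
                    res = compare(f"{group} {seg} {metric} men-vs-women",
                                  men, women, ("men", "women"))
                    row_p, used = res.p_value, res.test_used
                gender_rows.append({
                    "group": group, "segment": seg, "metric": metric,
                    "offset": segment_index(seg) - segment_index(group),
                    "male_mean": float(np.mean(men)) if men.size else np.nan,
                    "male_sd": float(np.std(men, ddof=1)) if men.size > 1 else np.nan,
                    "male_n": men.size,
                    "female_mean": float(np.mean(women)) if women.size else np.nan,
                    "female_sd": float(np.std(women, ddof=1)) if women.size > 1 else np.nan,
                    "female_n": women.size,
                    "test_used": used, "p_value": row_p})

    anatomy_rows = []
    if anatomy is not None and len(anatomy):
        anatomy = anatomy.copy()
        anatomy["group"] = anatomy["id"].map(group_of)
        for group in sorted(anatomy["group"].dropna().unique(), key=segment_index):
            at = anatomy[(anatomy["group"] == group) & (anatomy["segment"] == group)]
            for metric in ("amcc", "ascor_pct"):
                a = at[at["role"] == "patient"][metric].dropna().to_numpy()
                b = at[at["role"] == "control"][metric].dropna().to_numpy()
                if a.size == 0 and b.size == 0:
                    continue
                res = compare(f"{group} {metric} at stenosis patients-vs-controls",
                              a, b, ("patients", "controls"))
                anatomy_rows.append({
                    "group": group, "metric": metric,
                    "patient_mean": res.groups[0]["mean"],
                    "patient_sd": res.groups[0]["sd"], "patient_n": res.groups[0]["n"],
                    "control_mean": res.groups[1]["mean"],
                    "control_sd": res.groups[1]["sd"], "control_n": res.groups[1]["n"],
                    "test_used": res.test_used, "p_value": res.p_value})

    return {"motion": pd.DataFrame(motion_rows),
            "gender": pd.DataFrame(gender_rows),
            "anatomy": pd.DataFrame(anatomy_rows),
            "tests": tests}
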