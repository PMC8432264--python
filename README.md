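# cordmotion

Segment-wise analysis of craniocaudal cervical spinal cord motion from
phase-contrast MRI (PC-MRI) velocimetry, for degenerative cervical
myelopathy (DCM) research.

In DCM, a stenotic disc segment focally amplifies the cord's oscillatory
motion over the cardiac cycle. This package quantifies that motion from
per-segment velocity waveforms, scores the anatomical canal compromise, and
runs the matched-pair cohort statistics that such studies report. Because
clinical PC-MRI data of this kind is not publicly deposited, the package
ships a calibrated synthetic-cohort generator (tabular waveforms *and*
2-D sagittal phase-image phantoms) that reproduces the statistical structure
of a matched-pair DCM cohort, so the full pipeline can be exercised,
validated and benchmarked end to end.

## What it computes

For each disc segment C2/C3 … C7/T1 and each subject, from the velocity
curve v(t) (cm/s, positive = caudal) over one heartbeat of duration T:

- **maximum velocity** — max v(t) (cm/s);
- **ptp-amplitude** — 10 · (max v − min v) (mm/s);
- **total displacement** — ∫₀ᵀ |v(t)| dt (mm), negative-lobe area added,
  trapezoidal rule with periodic closure (suppressed in reports at C2/C3);
- **C2-pAI / C7-pAI** — ptp(segment) / ptp(C2/C3 or C7/T1), the
  intra-individual strain indices: a rise toward the stenosis indicates
  tissue stretch, the subsequent fall a compression;
- **aMCC** — (canal CSA one level above + one below) / (2 · canal CSA at
  level), the adapted maximum canal compromise;
- **aSCOR** — cord CSA · 100 / canal CSA (%), the cord occupation ratio.

Image-based inputs go through ROI construction (central third of each
intervertebral interval intersected with the cord mask), static-tissue
phase-drift correction, and ROI-mean curve extraction. Cohort statistics
follow the field's conventions: Shapiro-Wilk-gated t / Mann-Whitney
comparisons, repeated-measures ANOVA with sphericity check and
Bonferroni-adjusted segment contrasts, Kruskal-Wallis for multi-group
comparisons, and OLS prediction models with a conjunctive Cook's-distance +
leverage outlier rule.

## Worked example

```python
import cordmotion as cm

cfg = cm.default_config()               # the calibrated five-group cohort
cfg.group_sizes = {"C5/C6": 33}         # one stenosis group + matched controls

# generate, render phantoms, re-measure through the imaging stage
cohort, metrics = cm.simulate_and_measure(cfg, seed=1, through_images=True)
metrics = cm.annotate_groups(metrics, cohort)

at = metrics[metrics.segment == "C5/C6"]
print("patients:", round(at[at.role == "patient"].ptp_mm_s.mean(), 2), "mm/s")
print("controls:", round(at[at.role == "control"].ptp_mm_s.mean(), 2), "mm/s")

tables = cm.build_tables(cohort, metrics)
row = tables["motion"]
row = row[(row.segment == "C5/C6") & (row.metric == "ptp_mm_s")].iloc[0]
print("test:", row.test_used, "p =", f"{row.p_value:.2e}")
```

prints (seed 1):

```
patients: 12.78 mm/s
controls: 8.06 mm/s
test: mann_whitney p = 1.08e-04
```

i.e. this single simulated cohort shows the focal motion increase at the
stenotic segment (patient mean ptp-amplitude well above the matched
controls' ~8 mm/s), detected here by the rank test because the gate judged
the patient sample non-normal. Across replicate cohorts the patient mean
converges to the configured 13.4 mm/s target.

The same pipeline runs from the shell:

```sh
cordmotion all --seed 1 --outdir out/    # simulate -> measure -> metrics -> stats -> figures
```

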